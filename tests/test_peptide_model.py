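"""Peptide stage: tokenizer, channel oracles, head behaviour, training."""

import numpy as np
import pytest

from orf2pep import nn
from orf2pep.peptide_model import (BiLstmChannel, CnnChannel, ExternalProvider,
                                   PeptideModelConfig, PeptideNet,
                                   TokenVocabulary, TrainableLookupProvider,
                                   TrainedPeptideModel, classify, detokenize,
                                   predict_peptides, tokenize,
                                   train_peptide_model)
from orf2pep.seqio import PeptideRecord

from conftest import random_peptide
from oracles import direct_conv1d, reference_lstm


@pytest.fixture(scope="module")
def vocab():
    return TokenVocabulary()


def test_vocabulary_is_26_tokens_bijective(vocab):
    assert len(vocab) == 26
    assert sorted(vocab.id_of.values()) == list(range(26))
    for aa in "ACDEFGHIKLMNPQRSTVWYX":
        assert vocab.tokens[vocab.id_of[aa]] == aa


def test_tokenize_layout(vocab):
    tok = tokenize(PeptideRecord(id="p", sequence="ACD"), vocab, max_len=6)
    assert tok.ids[0] == vocab.cls_id
    assert tok.ids[4] == vocab.sep_id
    assert tok.ids[5] == vocab.pad_id
    assert tok.attention_mask.tolist() == [1, 1, 1, 1, 1, 0]
    assert tok.n_residues == 3


def test_tokenize_truncates_and_round_trips(vocab, rng):
    long = PeptideRecord(id="p", sequence="A" * 100)
    tok = tokenize(long, vocab, max_len=20)
    assert tok.n_residues == 18
    for _ in range(100):
        seq = random_peptide(rng, int(rng.integers(1, 40)))
        rec = PeptideRecord(id="r", sequence=seq)
        tok = tokenize(rec, vocab, max_len=52)
        assert detokenize(tok, vocab) == seq[:50]


def test_unknown_residue_maps_to_x(vocab):
    assert vocab.residue_id("B") == vocab.id_of["X"]


def _embeddings(rng, B, L, D):
    return rng.standard_normal((B, L, D))


def test_cnn_channel_matches_direct_convolution(rng):
    cfg = PeptideModelConfig.desk(cnn_filters=(5, 4, 3), embed_dim=4)
    for _ in range(50):
        chan_rng = np.random.default_rng(int(rng.integers(0, 2 ** 31)))
        chan = CnnChannel(4, cfg, chan_rng)
        for conv in (chan.conv1, chan.conv2, chan.conv3):
            conv.weight.data = conv.weight.data.astype(np.float64)
            conv.bias.data = rng.standard_normal(conv.bias.shape)
        L = int(rng.integers(10, 20))
        emb = _embeddings(rng, 1, L, 4)
        mask = np.ones((1, L), dtype=np.int64)
        got = chan(nn.Tensor(emb), mask).data[0]
        # oracle: three direct convolutions + ReLU, then plain average
        h = emb[0].T
        for conv in (chan.conv1, chan.conv2, chan.conv3):
            h = np.maximum(direct_conv1d(h, conv.weight.data, conv.bias.data), 0.0)
        assert np.allclose(got, h.mean(axis=1), atol=1e-5)


def test_cnn_channel_pad_invariance(rng):
    cfg = PeptideModelConfig.desk()
    chan = CnnChannel(8, cfg, np.random.default_rng(0))
    emb = _embeddings(rng, 1, 15, 8).astype(np.float32)
    mask = np.ones((1, 15), dtype=np.int64)
    out1 = chan(nn.Tensor(emb), mask).data
    padded = np.concatenate([emb, np.zeros((1, 5, 8), dtype=np.float32)], axis=1)
    mask2 = np.concatenate([mask, np.zeros((1, 5), dtype=np.int64)], axis=1)
    out2 = chan(nn.Tensor(padded), mask2).data
    assert np.allclose(out1, out2, atol=1e-5)


def test_cnn_channel_too_short_instructs_padding():
    cfg = PeptideModelConfig.desk()
    chan = CnnChannel(8, cfg, np.random.default_rng(0))
    emb = nn.Tensor(np.zeros((1, 8, 8), dtype=np.float32))
    mask = np.zeros((1, 8), dtype=np.int64)
    mask[0, :4] = 1
    with pytest.raises(ValueError, match="pad"):
        chan(emb, mask)


def test_bilstm_matches_unrolled_recurrence(rng):
    cfg = PeptideModelConfig.desk(lstm_hidden=5, embed_dim=3)
    for _ in range(50):
        chan = BiLstmChannel(3, cfg, np.random.default_rng(int(rng.integers(0, 2 ** 31))))
        for l in (chan.fwd, chan.bwd):
            l.wx.data = l.wx.data.astype(np.float64)
            l.wh.data = l.wh.data.astype(np.float64)
            l.bias.data = l.bias.data.astype(np.float64)
        L = int(rng.integers(1, 12))
        emb = _embeddings(rng, 1, L, 3)
        mask = np.ones((1, L), dtype=np.int64)
        got = chan(nn.Tensor(emb), mask).data[0]
        hs_f = reference_lstm(emb[0], chan.fwd.wx.data, chan.fwd.wh.data,
                              chan.fwd.bias.data)
        hs_b = reference_lstm(emb[0][::-1], chan.bwd.wx.data, chan.bwd.wh.data,
                              chan.bwd.bias.data)
        expected = np.concatenate([hs_f[-1], hs_b[-1]])
        assert np.allclose(got, expected, atol=1e-5)


def test_bilstm_single_step_boundary(rng):
    cfg = PeptideModelConfig.desk(lstm_hidden=4, embed_dim=3)
    chan = BiLstmChannel(3, cfg, np.random.default_rng(1))
    emb = _embeddings(rng, 2, 1, 3).astype(np.float32)
    mask = np.ones((2, 1), dtype=np.int64)
    out = chan(nn.Tensor(emb), mask)
    assert out.shape == (2, 8)
    assert np.all(np.isfinite(out.data))


def test_classify_head_properties(vocab, rng):
    cfg = PeptideModelConfig.desk()
    provider = TrainableLookupProvider(vocab, dim=cfg.embed_dim, seed=1)
    net = PeptideNet(cfg, provider, vocab)
    net.eval()
    cnn_vec = nn.Tensor(rng.standard_normal((4, cfg.cnn_filters[2])).astype(np.float32))
    lstm_vec = nn.Tensor(rng.standard_normal((4, 2 * cfg.lstm_hidden)).astype(np.float32))
    p = classify(cnn_vec, lstm_vec, net)
    assert np.all((p.data > 0) & (p.data < 1))
    # zero final-layer weights -> sigmoid(0) = 0.5 exactly
    net.mlp3.weight.data[...] = 0.0
    net.mlp3.bias.data[...] = 0.0
    assert np.allclose(classify(cnn_vec, lstm_vec, net).data, 0.5)
    # width mismatch rejected
    with pytest.raises(ValueError):
        classify(cnn_vec, nn.Tensor(np.zeros((4, 3), dtype=np.float32)), net)


def test_external_provider_contract(vocab):
    provider = ExternalProvider(lambda ids: np.ones(ids.shape + (8,)), dim=8)
    out = provider(np.zeros((2, 5), dtype=np.int64))
    assert out.shape == (2, 5, 8)
    bad = ExternalProvider(lambda ids: np.full(ids.shape + (8,), np.nan), dim=8)
    with pytest.raises(ValueError):
        bad(np.zeros((1, 3), dtype=np.int64))


def test_training_determinism_and_single_class_rejected(peptide_set):
    records, labels = peptide_set
    cfg = PeptideModelConfig.desk(seed=702, max_epochs=1)
    m1 = train_peptide_model(records, labels, "ACP", cfg)
    m2 = train_peptide_model(records, labels, "ACP", cfg)
    assert m1.training_history[0]["loss"] == m2.training_history[0]["loss"]
    with pytest.raises(ValueError):
        train_peptide_model(records, np.ones_like(labels), "ACP", cfg)
    with pytest.raises(ValueError):
        train_peptide_model(records, labels, "XXX", cfg)


def test_prediction_batch_order_invariant(peptide_set):
    records, labels = peptide_set
    cfg = PeptideModelConfig.desk(seed=702, max_epochs=2)
    model = train_peptide_model(records, labels, "ACP", cfg)
    s1 = {s.peptide_id: s.probability for s in predict_peptides(model, records)}
    perm = list(records[::-1])
    s2 = {s.peptide_id: s.probability for s in predict_peptides(model, perm)}
    for k in s1:
        assert s1[k] == pytest.approx(s2[k], abs=1e-5)


def test_checkpoint_round_trip(tmp_path, peptide_set):
    records, labels = peptide_set
    cfg = PeptideModelConfig.desk(seed=702, max_epochs=1)
    model = train_peptide_model(records, labels, "AMP", cfg)
    path = tmp_path / "pep.ckpt"
    model.save(path)
    back = TrainedPeptideModel.load(path)
    assert back.task == "AMP"
    p1 = [s.probability for s in predict_peptides(model, records[:20])]
    p2 = [s.probability for s in predict_peptides(back, records[:20])]
    assert np.allclose(p1, p2)


def test_training_recording_and_early_stopping(peptide_set):
    records, labels = peptide_set
    cfg = PeptideModelConfig.desk(seed=702, max_epochs=20, patience=2)
    model = train_peptide_model(records, labels, "ACP", cfg)
    hist = model.training_history
    assert len(hist) <= 20
    for entry in hist:
        assert {"loss", "val_loss", "val_accuracy", "val_f1", "val_mcc"} <= set(entry)


def test_auc_monotone_in_class_separation():
    """Held-out AUC does not decrease as the positive-class enrichment
    grows from none through mild to the default (three settings)."""
    from orf2pep.metrics import auc
    from orf2pep.synthetic_data import PeptideSimSpec, simulate_peptides, stratified_split
    enrichments = [
        {aa: 1.0 for aa in "KRWF"},                      # no signal
        {"K": 2.0, "R": 2.0, "W": 1.5, "F": 1.5},        # mild
        {"K": 5.0, "R": 5.0, "W": 3.0, "F": 3.0},        # default
    ]
    aucs = []
    for enr in enrichments:
        recs, labels = simulate_peptides(
            PeptideSimSpec(n_pos=200, n_neg=200, seed=11, enrichment=enr))
        tr, te = stratified_split(recs, labels, 0.8, 702)
        cfg = PeptideModelConfig.desk(seed=702, max_epochs=6, patience=6)
        model = train_peptide_model([recs[i] for i in tr], labels[tr], "ACP", cfg)
        p = np.array([s.probability for s in
                      predict_peptides(model, [recs[i] for i in te])])
        aucs.append(auc(p, labels[te]))
    assert aucs[0] <= aucs[1] + 0.05 and aucs[1] <= aucs[2] + 0.02
    assert aucs[2] > aucs[0]
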