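"""Gene-stage classifier: architecture, training behaviour, GC buckets,
greedy overlap resolution and call evaluation."""

import numpy as np
import pytest

from orf2pep.gene_model import (GcBucketLibrary, GeneModelConfig, GeneNet,
                                ScoredOrf, TrainedGeneModel, evaluate_calls,
                                greedy_resolve, predict_orfs, predict_proba,
                                select_bucket, train_gene_model)
from orf2pep.seqio import GeneCall

from oracles import greedy_oracle

DESK = dict(conv1_filters=4, conv2_filters=8, fc1_out=64, encoder_tokens=4,
            attn_heads=4, encoder_ff=32, fc2_out=16)


def _separable(n=300, dim=120, seed=0):
    """Synthetic fused-vector stand-in: two Gaussian classes."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.standard_normal((n, dim)).astype(np.float32)
    X[y == 1, :10] += 2.0
    return X, y


def test_forward_shapes_and_range():
    cfg = GeneModelConfig.desk(seed=1, **DESK)
    net = GeneNet(cfg, input_len=200)
    net.eval()
    from orf2pep import nn
    p = net(nn.Tensor(np.random.default_rng(0).standard_normal((5, 200)).astype(np.float32)))
    assert p.shape == (5,)
    assert np.all((p.data >= 0) & (p.data <= 1))


def test_same_seed_same_initial_outputs():
    cfg = GeneModelConfig.desk(seed=42, **DESK)
    from orf2pep import nn
    x = nn.Tensor(np.random.default_rng(1).standard_normal((3, 150)).astype(np.float32))
    a, b = GeneNet(cfg, 150), GeneNet(cfg, 150)
    a.eval(), b.eval()
    assert np.array_equal(a(x).data, b(x).data)


def test_input_too_short_for_pooling_rejected():
    cfg = GeneModelConfig.desk(seed=0, **DESK)
    with pytest.raises(ValueError):
        GeneNet(cfg, input_len=6)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneModelConfig(attn_heads=7)          # must divide encoder width
    with pytest.raises(ValueError):
        GeneModelConfig(dropout_cnn=1.5)


def test_training_learns_separable_data_and_null_does_not():
    X, y = _separable(seed=3)
    cfg = GeneModelConfig.desk(seed=5, max_epochs=8, **DESK)
    model = train_gene_model(X[:240], y[:240], cfg)
    p = predict_proba(model.net, X[240:])
    assert ((p >= 0.5) == (y[240:] >= 0.5)).mean() >= 0.9
    assert p[y[240:] == 1].mean() > p[y[240:] == 0].mean()
    assert len(model.training_history) == 8

    rng = np.random.default_rng(0)
    ysh = y.copy()
    rng.shuffle(ysh)
    null = train_gene_model(X[:240], ysh[:240], cfg)
    pn = predict_proba(null.net, X[240:])
    assert abs(((pn >= 0.5) == (ysh[240:] >= 0.5)).mean() - 0.5) < 0.15


def test_training_is_reproducible_with_fixed_seed():
    X, y = _separable(n=120, seed=9)
    cfg = GeneModelConfig.desk(seed=7, max_epochs=3, **DESK)
    h1 = train_gene_model(X, y, cfg).training_history
    h2 = train_gene_model(X, y, cfg).training_history
    assert h1 == h2


def test_single_class_rejected():
    X, y = _separable(n=60, seed=1)
    cfg = GeneModelConfig.desk(seed=0, max_epochs=1, **DESK)
    with pytest.raises(ValueError):
        train_gene_model(X, np.ones_like(y), cfg)


def test_prediction_is_permutation_invariant_and_deterministic():
    X, y = _separable(n=80, seed=2)
    cfg = GeneModelConfig.desk(seed=4, max_epochs=2, **DESK)
    model = train_gene_model(X, y, cfg)
    p1 = predict_proba(model.net, X)
    perm = np.random.default_rng(0).permutation(len(X))
    p2 = predict_proba(model.net, X[perm])
    assert np.allclose(p1[perm], p2, atol=1e-6)
    assert np.array_equal(p1, predict_proba(model.net, X))


def test_checkpoint_round_trip_preserves_predictions(tmp_path):
    X, y = _separable(n=80, seed=6)
    cfg = GeneModelConfig.desk(seed=8, max_epochs=2, **DESK)
    model = train_gene_model(X, y, cfg)
    path = tmp_path / "gene.ckpt"
    model.save(path)
    back = TrainedGeneModel.load(path)
    assert np.allclose(predict_proba(back.net, X), predict_proba(model.net, X))


# -- GC buckets -------------------------------------------------------------

def test_select_bucket_deciles():
    lib = GcBucketLibrary()
    assert select_bucket(0.05, lib) == 0
    assert select_bucket(0.30, lib) == 3   # left-closed
    assert select_bucket(1.0, lib) == 9    # right-closed last bucket
    lo, hi = lib.bucket_range(3)
    assert (lo, hi) == (pytest.approx(0.3), pytest.approx(0.4))


# -- greedy resolution ------------------------------------------------------

def _scored(seq_id, start, end, prob, strand="+"):
    from orf2pep.orf_scanner import OrfCandidate
    cand = OrfCandidate(seq_id=seq_id, start=start, end=end, strand=strand,
                        frame=start % 3, completeness="complete",
                        nt_seq="A" * (end - start), upstream_window="")
    return ScoredOrf(candidate=cand, probability=prob)


def test_greedy_examples():
    # 61 bp overlap: lower-probability call discarded
    calls = greedy_resolve([_scored("s", 0, 100, 0.9), _scored("s", 39, 139, 0.8)])
    assert [(c.start, c.end) for c in calls] == [(0, 100)]
    # exactly 60 bp overlap: both retained (strictly more-than rule)
    calls = greedy_resolve([_scored("s", 0, 100, 0.9), _scored("s", 40, 140, 0.8)])
    assert len(calls) == 2
    # below min_prob removed
    calls = greedy_resolve([_scored("s", 0, 100, 0.4)])
    assert calls == []


def test_greedy_opposite_strands_still_compete():
    calls = greedy_resolve([_scored("s", 0, 100, 0.9),
                            _scored("s", 10, 110, 0.8, strand="-")])
    assert len(calls) == 1


def test_greedy_matches_quadratic_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(5, 200))
        scored = []
        for i in range(n):
            start = int(rng.integers(0, 3_000))
            length = int(rng.integers(60, 500))
            prob = float(np.round(rng.random(), 3))
            strand = "+" if rng.random() < 0.5 else "-"
            scored.append(_scored("s", start, start + length, prob, strand))
        got = [(c.seq_id, c.start, c.end, c.strand, c.probability)
               for c in greedy_resolve(scored)]
        exp = greedy_oracle([(s.candidate.seq_id, s.candidate.start,
                              s.candidate.end, s.candidate.strand, s.probability)
                             for s in scored])
        exp = [(a, b, c, d, e) for a, b, c, d, e in
               ((iv[0], iv[1], iv[2], iv[3], iv[4]) for iv in exp)]
        assert got == exp
        # invariant: no retained pair overlaps by more than 60 bp
        for i, a in enumerate(got):
            for b in got[i + 1:]:
                assert min(a[2], b[2]) - max(a[1], b[1]) <= 60


def test_evaluate_calls_three_prime_matching(small_genome):
    _, truth = small_genome
    counts = evaluate_calls(truth, truth, all_candidates=truth)
    assert counts.fp == counts.fn == 0
    assert counts.tp == len(truth)
    from orf2pep.metrics import sensitivity
    assert sensitivity(counts) == 1.0
    empty = evaluate_calls([], truth)
    assert empty.tp == 0 and empty.fn == len(truth)
    with pytest.raises(ValueError):
        evaluate_calls(truth, [])
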