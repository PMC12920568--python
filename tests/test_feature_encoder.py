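"""Feature blocks vs independent counting oracles; fusion round trips."""

import numpy as np
import pytest

from orf2pep.feature_encoder import (FeatureBundle, FeatureEncoder, TisPwm,
                                     base_composition, block_offsets,
                                     dicodon_usage, fuse, fused_length,
                                     gc_content, length_feature,
                                     monocodon_usage, one_hot, tis_score,
                                     train_tis_pwm)
from orf2pep.orf_scanner import PAD_SYMBOL

from conftest import random_dna


def test_one_hot_basic_rows():
    m = one_hot("A" + PAD_SYMBOL * 699)
    assert m.shape == (700, 4)
    assert m[0].tolist() == [1, 0, 0, 0]
    assert m[1:].sum() == 0
    m = one_hot("ACGT" + PAD_SYMBOL * 696)
    assert np.array_equal(m[:4], np.eye(4))


def test_one_hot_column_sums_equal_base_counts(rng):
    seq = random_dna(rng, 700)
    m = one_hot(seq)
    for j, b in enumerate("ACGT"):
        assert m[:, j].sum() == seq.count(b)
    assert np.all(m.sum(axis=1) <= 1)


def test_one_hot_rejects_wrong_length():
    with pytest.raises(ValueError):
        one_hot("ACGT")


def test_monocodon_examples():
    v = monocodon_usage("ATGATGTAA")
    from orf2pep.feature_encoder import CODON_INDEX
    assert v[CODON_INDEX["ATG"]] == pytest.approx(2 / 3)
    assert v[CODON_INDEX["TAA"]] == pytest.approx(1 / 3)
    assert v.sum() == pytest.approx(1.0)
    v = monocodon_usage("AAAAAA")
    assert v[CODON_INDEX["AAA"]] == 1.0


def test_monocodon_matches_brute_tally(rng):
    seq = random_dna(rng, 999)
    v = monocodon_usage(seq)
    codons = [seq[i:i + 3] for i in range(0, 999, 3)]
    for c in set(codons):
        from orf2pep.feature_encoder import CODON_INDEX
        assert v[CODON_INDEX[c]] == pytest.approx(codons.count(c) / len(codons))


def test_dicodon_examples_and_tally(rng):
    from orf2pep.feature_encoder import DICODON_INDEX
    v = dicodon_usage("ATGAAATAA")
    assert v[DICODON_INDEX["ATGAAA"]] == pytest.approx(0.5)
    assert v[DICODON_INDEX["AAATAA"]] == pytest.approx(0.5)
    assert dicodon_usage("AAAAAAAAA")[DICODON_INDEX["AAAAAA"]] == 1.0

    seq = random_dna(rng, 3_000)
    v = dicodon_usage(seq)
    pairs = [seq[i:i + 6] for i in range(0, 3_000 - 3, 3)]
    for h in set(pairs):
        assert v[DICODON_INDEX[h]] == pytest.approx(pairs.count(h) / len(pairs))


def test_n_codons_excluded_from_denominators():
    v = monocodon_usage("ATGNNNTAA")
    assert v.sum() == pytest.approx(1.0)
    from orf2pep.feature_encoder import CODON_INDEX
    assert v[CODON_INDEX["ATG"]] == pytest.approx(0.5)


def test_degenerate_short_sequences_give_zero_vectors():
    assert monocodon_usage("AT").sum() == 0
    assert dicodon_usage("ATGAA").sum() == 0


def test_tis_pwm_degenerate_and_null_cases(rng):
    pwm = train_tis_pwm(["A" * 30] * 20)
    assert np.all(pwm.weights[:, 0] > 0)
    # positives drawn from the background distribution -> weights ~ 0
    windows = [random_dna(rng, 30) for _ in range(2_000)]
    pwm = train_tis_pwm(windows, background_seqs=["".join(windows)])
    assert np.abs(pwm.weights).max() < 0.15


def test_tis_pwm_parameter_recovery(rng):
    """Windows simulated from a known PWM recover its weights closely."""
    true_p = rng.uniform(0.15, 0.55, size=(30, 4))
    true_p /= true_p.sum(axis=1, keepdims=True)
    windows = ["".join("ACGT"[rng.choice(4, p=true_p[i])] for i in range(30))
               for _ in range(1_000)]
    pwm = train_tis_pwm(windows, background_seqs=None)
    true_w = np.log2(true_p / 0.25)
    err = np.abs(pwm.weights - true_w)
    assert np.sqrt((err ** 2).mean()) < 0.1
    assert err.max() < 0.35


def test_tis_score_table_sum_and_boundaries(rng):
    pwm = train_tis_pwm(["ACGTACGTACGTACGTACGTACGTACGTAC"] * 15)
    assert tis_score("", pwm) == 0.0
    win = random_dna(rng, 22)
    expected = sum(pwm.weights[30 - 22 + i, "ACGT".index(ch)]
                   for i, ch in enumerate(win))
    assert tis_score(win, pwm) == pytest.approx(expected)
    # consensus maximizes score among same-length windows
    consensus = "".join("ACGT"[j] for j in pwm.weights[-10:].argmax(axis=1))
    assert tis_score(consensus, pwm) >= tis_score(random_dna(rng, 10), pwm)


def test_scalar_features():
    assert gc_content("ATGC") == 0.5
    assert base_composition("AACG").tolist() == [0.5, 0.25, 0.25, 0.0]
    assert length_feature(1400, cap=700) == 1.0
    assert length_feature(350, cap=700) == 0.5
    with pytest.warns(UserWarning):
        assert gc_content("NNN") == 0.0


def test_fuse_layout_and_round_trip(rng):
    seq = random_dna(rng, 700)
    oh = one_hot(seq)
    bundle = FeatureBundle(monocodon=monocodon_usage(seq),
                           dicodon=dicodon_usage(seq), tis=1.25,
                           orf_length=0.9, gc=gc_content(seq),
                           base_comp=base_composition(seq))
    fv = fuse(oh, bundle)
    assert fv.values.shape == (6_967,)
    assert np.allclose(fv.block("onehot"), oh.ravel())
    assert np.allclose(fv.block("monocodon"), bundle.monocodon, atol=1e-7)
    assert np.allclose(fv.block("dicodon"), bundle.dicodon, atol=1e-7)
    assert fv.block("tis")[0] == pytest.approx(1.25)
    assert fv.block("base_comp") == pytest.approx(bundle.base_comp, abs=1e-7)
    offs = block_offsets()
    assert offs["base_comp"][1] == fused_length() == 6_967


def test_fuse_missing_block_is_named():
    with pytest.raises(ValueError, match="dicodon"):
        fuse(one_hot("A" * 700), FeatureBundle(
            monocodon=np.zeros(64), dicodon=None, tis=0.0, orf_length=0.0,
            gc=0.0, base_comp=np.zeros(4)))


def test_encoder_matrix_shapes_consistent(small_genome):
    from orf2pep.orf_scanner import scan_orfs
    rec, _ = small_genome
    cands = scan_orfs(rec)[:40]
    enc = FeatureEncoder()
    X = enc.encode_matrix(cands)
    assert X.shape == (len(cands), 6_967)
    sums = X[:, block_offsets()["monocodon"][0]:block_offsets()["monocodon"][1]].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-5)
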