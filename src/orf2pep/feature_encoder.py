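"""One-hot encoding, handcrafted ORF features, and their fusion.

Each candidate ORF is represented by the concatenation (in this fixed
order) of:

1. the flattened one-hot matrix of its length-standardized sequence
   (700 x 4 = 2800 entries; N and pad positions encode as all-zero rows),
2. monocodon usage (64 relative frequencies over in-frame codons),
3. dicodon usage (4096 relative frequencies over overlapping in-frame
   codon pairs, step one codon),
4. a scalar translation-initiation-site (TIS) log-odds score from a
   position weight matrix over the 30 bp upstream window,
5. ORF length normalized by the 700 bp cap,
6. GC content, and
7. base composition (4 frequencies over non-N bases).

Frequencies, not counts, are used throughout so the blocks are comparable
across ORFs of different length; N-containing codons/bases are excluded
from numerators and denominators alike.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np

from .orf_scanner import DEFAULT_FIXED_LEN, PAD_SYMBOL, OrfCandidate, standardize_length

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
DICODONS = ["".join(c) for c in itertools.product(BASES, repeat=6)]
DICODON_INDEX = {c: i for i, c in enumerate(DICODONS)}

TIS_WINDOW = 30

BLOCK_NAMES = ("onehot", "monocodon", "dicodon", "tis", "orf_length", "gc", "base_comp")


def one_hot(fixed_seq: str, expected_len: int = DEFAULT_FIXED_LEN) -> np.ndarray:
    """One-hot encode a length-standardized sequence into an (L, 4) matrix."""
    if len(fixed_seq) != expected_len:
        raise ValueError(f"expected length {expected_len}, got {len(fixed_seq)}")
    mat = np.zeros((expected_len, 4), dtype=np.float32)
    for i, ch in enumerate(fixed_seq):
        j = BASE_INDEX.get(ch)
        if j is not None:
            mat[i, j] = 1.0
    return mat


def monocodon_usage(nt_seq: str) -> np.ndarray:
    """Relative frequency of the 64 codons over non-overlapping in-frame codons."""
    out = np.zeros(64, dtype=np.float64)
    usable = len(nt_seq) - len(nt_seq) % 3
    for i in range(0, usable, 3):
        idx = CODON_INDEX.get(nt_seq[i:i + 3])
        if idx is not None:
            out[idx] += 1
    total = out.sum()
    return out / total if total > 0 else out


def dicodon_usage(nt_seq: str) -> np.ndarray:
    """Relative frequency of hexamers over overlapping in-frame codon pairs."""
    out = np.zeros(4096, dtype=np.float64)
    usable = len(nt_seq) - len(nt_seq) % 3
    for i in range(0, usable - 3, 3):
        idx = DICODON_INDEX.get(nt_seq[i:i + 6])
        if idx is not None:
            out[idx] += 1
    total = out.sum()
    return out / total if total > 0 else out


@dataclasses.dataclass
class TisPwm:
    """Log2-odds position weight matrix over the 30 bp upstream window.

    Windows shorter than 30 bp are right-aligned to the start codon, i.e.
    they occupy the matrix rows closest to position 30.
    """

    weights: np.ndarray          # (30, 4) log2-odds, bits
    background: np.ndarray       # (4,) base frequencies

    def __post_init__(self):
        if self.weights.shape != (TIS_WINDOW, 4):
            raise ValueError("TIS PWM must be 30 x 4")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite PWM weights")

    @classmethod
    def null(cls) -> "TisPwm":
        return cls(weights=np.zeros((TIS_WINDOW, 4)), background=np.full(4, 0.25))


def train_tis_pwm(positive_windows, background_seqs=None, pseudocount: float = 1.0) -> TisPwm:
    """Fit the TIS PWM from upstream windows of known coding starts."""
    positive_windows = [w for w in positive_windows if w]
    if not positive_windows:
        raise ValueError("no positive upstream windows supplied")
    counts = np.full((TIS_WINDOW, 4), pseudocount, dtype=np.float64)
    for win in positive_windows:
        win = win[-TIS_WINDOW:]
        offset = TIS_WINDOW - len(win)
        for i, ch in enumerate(win):
            j = BASE_INDEX.get(ch)
            if j is not None:
                counts[offset + i, j] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    if background_seqs:
        bg_counts = np.full(4, pseudocount, dtype=np.float64)
        for seq in background_seqs:
            for ch in seq:
                j = BASE_INDEX.get(ch)
                if j is not None:
                    bg_counts[j] += 1.0
        background = bg_counts / bg_counts.sum()
    else:
        background = np.full(4, 0.25)
    weights = np.log2(freqs / background)
    return TisPwm(weights=weights, background=background)


def tis_score(upstream_window: str, pwm: TisPwm) -> float:
    """Sum of per-position log-odds; N contributes 0; empty window scores 0."""
    if len(upstream_window) > TIS_WINDOW:
        raise ValueError("upstream window longer than 30 bp")
    win = upstream_window
    offset = TIS_WINDOW - len(win)
    score = 0.0
    for i, ch in enumerate(win):
        j = BASE_INDEX.get(ch)
        if j is not None:
            score += pwm.weights[offset + i, j]
    return float(score)


def length_feature(length_bp: int, cap: int = DEFAULT_FIXED_LEN) -> float:
    return min(length_bp, cap) / cap


def gc_content(nt_seq: str) -> float:
    counted = sum(nt_seq.count(b) for b in BASES)
    if counted == 0:
        warnings.warn("sequence has no unambiguous bases; GC set to 0")
        return 0.0
    return (nt_seq.count("G") + nt_seq.count("C")) / counted


def base_composition(nt_seq: str) -> np.ndarray:
    counts = np.array([nt_seq.count(b) for b in BASES], dtype=np.float64)
    total = counts.sum()
    if total == 0:
        warnings.warn("sequence has no unambiguous bases; base composition set to 0")
        return counts
    return counts / total


@dataclasses.dataclass
class FeatureBundle:
    monocodon: np.ndarray
    dicodon: np.ndarray
    tis: float
    orf_length: float
    gc: float
    base_comp: np.ndarray


@dataclasses.dataclass
class FusedVector:
    """The model input: all feature blocks concatenated in fixed order."""

    values: np.ndarray
    offsets: dict

    def block(self, name: str) -> np.ndarray:
        a, b = self.offsets[name]
        return self.values[a:b]


def block_offsets(fixed_len: int = DEFAULT_FIXED_LEN) -> dict:
    sizes = [("onehot", fixed_len * 4), ("monocodon", 64), ("dicodon", 4096),
             ("tis", 1), ("orf_length", 1), ("gc", 1), ("base_comp", 4)]
    offsets, pos = {}, 0
    for name, size in sizes:
        offsets[name] = (pos, pos + size)
        pos += size
    return offsets


def fused_length(fixed_len: int = DEFAULT_FIXED_LEN) -> int:
    return fixed_len * 4 + 64 + 4096 + 3 + 4


def fuse(onehot: np.ndarray, bundle: FeatureBundle) -> FusedVector:
    """Concatenate the one-hot matrix and handcrafted features."""
    for name in ("monocodon", "dicodon", "tis", "orf_length", "gc", "base_comp"):
        if getattr(bundle, name) is None:
            raise ValueError(f"missing feature block: {name}")
    if onehot is None:
        raise ValueError("missing feature block: onehot")
    values = np.concatenate([
        onehot.astype(np.float32).ravel(),
        np.asarray(bundle.monocodon, dtype=np.float32),
        np.asarray(bundle.dicodon, dtype=np.float32),
        np.array([bundle.tis, bundle.orf_length, bundle.gc], dtype=np.float32),
        np.asarray(bundle.base_comp, dtype=np.float32),
    ])
    return FusedVector(values=values, offsets=block_offsets(onehot.shape[0]))


class FeatureEncoder:
    """Stateful encoder bundling the fixed length and a fitted TIS PWM."""

    def __init__(self, fixed_len: int = DEFAULT_FIXED_LEN, pwm: TisPwm | None = None,
                 use_tis: bool = True):
        self.fixed_len = fixed_len
        self.pwm = pwm if pwm is not None else TisPwm.null()
        self.use_tis = use_tis

    def fit_tis(self, candidates, background_seqs=None):
        windows = [c.upstream_window for c in candidates if c.upstream_window]
        if len(windows) >= 10:
            self.pwm = train_tis_pwm(windows, background_seqs)
        return self

    def encode(self, candidate: OrfCandidate) -> FusedVector:
        fixed = standardize_length(candidate, self.fixed_len).fixed_seq
        bundle = FeatureBundle(
            monocodon=monocodon_usage(candidate.nt_seq),
            dicodon=dicodon_usage(candidate.nt_seq),
            tis=tis_score(candidate.upstream_window, self.pwm) if self.use_tis else 0.0,
            orf_length=length_feature(candidate.length, self.fixed_len),
            gc=gc_content(candidate.nt_seq),
            base_comp=base_composition(candidate.nt_seq),
        )
        return fuse(one_hot(fixed, self.fixed_len), bundle)

    def encode_matrix(self, candidates) -> np.ndarray:
        return np.stack([self.encode(c).values for c in candidates])

    def export_tsv(self, candidates, path):
        """Dense TSV, one row per candidate, header of block:index names."""
        offsets = block_offsets(self.fixed_len)
        header = []
        for name in BLOCK_NAMES:
            a, b = offsets[name]
            if b - a == 1:
                header.append(name)
            else:
                header.extend(f"{name}_{i}" for i in range(b - a))
        with open(path, "w") as fh:
            fh.write("candidate\t" + "\t".join(header) + "\n")
            for i, c in enumerate(candidates):
                vec = self.encode(c).values
                row = "\t".join(np.format_float_positional(v, precision=6, trim="-")
                                for v in vec)
                fh.write(f"orf{i + 1}\t{row}\n")
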