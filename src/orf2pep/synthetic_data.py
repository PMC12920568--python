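"""Synthetic genomes and peptide sets for offline training and testing.

Genomes are iid backgrounds of configurable GC into which codon-biased
genes are embedded on both strands: each gene is a start codon, a body
drawn codon-by-codon from a biased (stop-free) codon table, and a random
stop codon.  The codon table is drawn once per specification from a
Dirichlet centered on a fixed asymmetric reference profile;
``codon_bias_strength`` scales the concentration, so strength 0 gives a
near-uniform table (little contrast against a GC=0.5 background) and large
strengths give strongly biased, easily learnable genes.

Peptide sets contrast an iid-uniform negative class with a positive class
whose residue composition is reweighted toward cationic/aromatic residues
(K, R, W, F by default), the compositional signature that distinguishes
anticancer/antimicrobial peptides.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .feature_encoder import CODONS
from .seqio import GeneCall, GenomeRecord, PeptideRecord, STOP_CODONS, reverse_complement

BASES = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


@dataclasses.dataclass
class GenomeSimSpec:
    length: int = 50_000
    gc_background: float = 0.5
    n_genes: int = 40
    gene_len_range: tuple = (90, 450)       # bp, multiples of 3, stop included
    codon_bias_strength: float = 20.0
    strand_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.gene_len_range
        if lo < 60 or lo % 3 or hi % 3 or lo > hi:
            raise ValueError("gene lengths must be >= 60 bp, multiples of 3, lo <= hi")
        if not 0.0 < self.gc_background < 1.0:
            raise ValueError("gc_background must be in (0, 1)")
        if self.codon_bias_strength < 0:
            raise ValueError("codon_bias_strength must be >= 0")


@dataclasses.dataclass
class PeptideSimSpec:
    n_pos: int = 500
    n_neg: int = 500
    len_range: tuple = (12, 50)
    enrichment: dict = dataclasses.field(
        default_factory=lambda: {"K": 5.0, "R": 5.0, "W": 3.0, "F": 3.0})
    seed: int = 0

    def __post_init__(self):
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("class counts must be positive")
        if any(m <= 0 for m in self.enrichment.values()):
            raise ValueError("enrichment multipliers must be positive")


def _reference_codon_profile() -> np.ndarray:
    """Fixed asymmetric profile over the 61 sense codons (unit sum)."""
    w = np.exp(-np.arange(len(SENSE_CODONS)) / 12.0)
    return w / w.sum()


def _biased_codon_table(rng: np.random.Generator, strength: float) -> np.ndarray:
    ref = _reference_codon_profile()
    alpha = 2.0 + strength * len(SENSE_CODONS) * ref
    table = rng.dirichlet(alpha)
    return table / table.sum()


def simulate_genome(spec: GenomeSimSpec):
    """Generate (GenomeRecord, truth gene calls) per the specification.

    Truth annotations are GeneCall objects with probability 1.0, 0-based
    half-open forward-strand coordinates, one per embedded gene.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_background
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = list("".join(rng.choice(list(BASES), size=spec.length, p=base_p)))

    codon_p = _biased_codon_table(rng, spec.codon_bias_strength)
    stops = sorted(STOP_CODONS)
    lo, hi = spec.gene_len_range
    lengths = rng.integers(lo // 3, hi // 3 + 1, size=spec.n_genes) * 3

    occupied = []

    def overlaps(s, e):
        return any(not (e + 1 <= a or s >= b + 1) for a, b in occupied)

    truth = []
    for gi, glen in enumerate(lengths):
        placed = False
        for _ in range(10_000):
            s = int(rng.integers(0, spec.length - int(glen) + 1))
            e = s + int(glen)
            if not overlaps(s, e):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place all genes without overlap; use a longer genome")
        occupied.append((s, e))
        n_body = int(glen) // 3 - 2
        body = "".join(rng.choice(SENSE_CODONS, size=n_body, p=codon_p))
        gene = "ATG" + body + str(rng.choice(stops))
        strand = "+" if rng.random() < spec.strand_prob else "-"
        inserted = gene if strand == "+" else reverse_complement(gene)
        genome[s:e] = list(inserted)
        truth.append(GeneCall(seq_id=f"synth_{spec.seed}", start=s, end=e,
                              strand=strand, probability=1.0))
    record = GenomeRecord(id=f"synth_{spec.seed}", sequence="".join(genome),
                          description="synthetic genome with embedded codon-biased genes")
    truth.sort(key=lambda c: c.start)
    return record, truth


def truth_stop_set(truth) -> set:
    """The (stop coordinate, strand) identifiers of the true genes."""
    return {(t.stop_coordinate, t.strand) for t in truth}


def make_orf_dataset(candidates, truth):
    """Label scanned candidates against truth by 3'-end (stop+strand) match.

    Returns (candidates, labels) with labels as an int array; raises when no
    candidate recovers any true gene.
    """
    stops = truth_stop_set(truth)
    labels = np.array(
        [1 if (c.stop_coordinate, c.strand) in stops else 0 for c in candidates],
        dtype=np.int64)
    if labels.sum() == 0:
        raise ValueError("no positive candidates: scanner did not recover any true gene")
    return list(candidates), labels


def simulate_peptides(spec: PeptideSimSpec):
    """Generate labeled peptides: returns (records, labels 0/1)."""
    rng = np.random.default_rng(spec.seed)
    base = np.full(len(AA20), 1.0 / len(AA20))
    pos_w = base.copy()
    for aa, mult in spec.enrichment.items():
        pos_w[AA20.index(aa)] *= mult
    pos_w /= pos_w.sum()

    records, labels = [], []
    aa_list = list(AA20)

    def draw(n, weights, label, prefix):
        lengths = rng.integers(spec.len_range[0], spec.len_range[1] + 1, size=n)
        for i, L in enumerate(lengths):
            seq = "".join(rng.choice(aa_list, size=int(L), p=weights))
            records.append(PeptideRecord(id=f"{prefix}{i + 1}", sequence=seq))
            labels.append(label)

    draw(spec.n_pos, pos_w, 1, "pos")
    draw(spec.n_neg, base, 0, "neg")
    return records, np.array(labels, dtype=np.int64)


def stratified_split(items, labels, ratio: float = 0.8, seed: int = 702):
    """Class-stratified shuffle split; returns index arrays (train, test)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        rng.shuffle(idx)
        cut = int(round(idx.size * ratio))
        cut = min(max(cut, 1), idx.size - 1)
        train_idx.append(idx[:cut])
        test_idx.append(idx[cut:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return train, test


def write_labels_tsv(records, labels, path):
    with open(path, "w") as fh:
        for rec, lab in zip(records, labels):
            fh.write(f"{rec.id}\t{int(lab)}\n")


def read_labels_tsv(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rid, lab = line.split("\t")
                out[rid] = int(lab)
    return out
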