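"""Physicochemical profiling of predicted peptides.

Eight properties per peptide: GRAVY (Kyte-Doolittle mean hydropathy),
molecular weight (average residue masses), aromaticity (F+W+Y fraction),
instability index (Guruprasad dipeptide weights), isoelectric point,
net charge at pH 7 (Henderson-Hasselbalch), Boman interaction index, and
tryptophan content.  GRAVY, molecular weight, aromaticity and instability
are delegated to Biopython's ProtParam; charge, pI and the Boman index are
computed here with a selectable pKa set (EMBOSS default, Bjellqvist
alternative) because pI is pKa-set dependent.

Properties defined by residue tables are undefined for X residues and
raise rather than silently imputing.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

# Mean residue interaction (solubility) values, kcal/mol; hydrophobic
# residues are negative, strongly solvated ones positive.  The peptide
# index is the plain mean over residues.
BOMAN_SCALE = {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35, "W": -2.33,
    "A": -1.81, "C": -1.28, "G": -0.94, "Y": 0.14, "P": 0.0, "T": 2.57,
    "S": 3.40, "H": 4.66, "Q": 5.54, "K": 5.55, "N": 6.64, "E": 6.81,
    "D": 8.72, "R": 14.92,
}

# Ionizable-group pKa sets.  'nterm'/'cterm' are the backbone termini.
PKA_SETS = {
    "emboss": {
        "nterm": 8.6, "cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    "bjellqvist": {
        "nterm": 7.5, "cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
}

POSITIVE_GROUPS = ("K", "R", "H")
NEGATIVE_GROUPS = ("D", "E", "C", "Y")

PROPERTY_NAMES = ("gravy", "mol_weight", "aromaticity", "instability",
                  "isoelectric_point", "net_charge_pH7", "boman", "w_content")


def _reject_x(seq: str, prop: str):
    positions = [i for i, ch in enumerate(seq) if ch == "X"]
    if positions:
        raise ValueError(f"{prop} is undefined for X residues (positions {positions})")


def gravy(seq: str) -> float:
    _reject_x(seq, "GRAVY")
    return ProteinAnalysis(seq).gravy()


def molecular_weight(seq: str) -> float:
    _reject_x(seq, "molecular weight")
    return ProteinAnalysis(seq).molecular_weight()


def aromaticity(seq: str) -> float:
    return (seq.count("F") + seq.count("W") + seq.count("Y")) / len(seq)


def trp_content(seq: str) -> float:
    return seq.count("W") / len(seq)


def instability_index(seq: str) -> float:
    if len(seq) < 2:
        raise ValueError("instability index needs at least 2 residues")
    _reject_x(seq, "instability index")
    return ProteinAnalysis(seq).instability_index()


def boman_index(seq: str) -> float:
    _reject_x(seq, "Boman index")
    return sum(BOMAN_SCALE[ch] for ch in seq) / len(seq)


def net_charge(seq: str, pH: float, pka_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge over termini and ionizable side chains."""
    _reject_x(seq, "net charge")
    pka = PKA_SETS[pka_set]

    def pos(pk):
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def neg(pk):
        return -1.0 / (1.0 + 10.0 ** (pk - pH))

    charge = pos(pka["nterm"]) + neg(pka["cterm"])
    for aa in POSITIVE_GROUPS:
        n = seq.count(aa)
        if n:
            charge += n * pos(pka[aa])
    for aa in NEGATIVE_GROUPS:
        n = seq.count(aa)
        if n:
            charge += n * neg(pka[aa])
    return charge


def isoelectric_point(seq: str, pka_set: str = "emboss", tol: float = 1e-4,
                      max_iter: int = 200) -> float:
    """pH at which net charge vanishes, found by bisection on (0, 14)."""
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka_set)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"pI bisection did not converge within {max_iter} iterations")


def profile(seq: str, pka_set: str = "emboss") -> dict:
    return {
        "gravy": gravy(seq),
        "mol_weight": molecular_weight(seq),
        "aromaticity": aromaticity(seq),
        "instability": instability_index(seq),
        "isoelectric_point": isoelectric_point(seq, pka_set),
        "net_charge_pH7": net_charge(seq, 7.0, pka_set),
        "boman": boman_index(seq),
        "w_content": trp_content(seq),
    }


@dataclasses.dataclass
class PropertyMatrix:
    """Raw and min-max-normalized property values, one row per peptide."""

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None
    col_min: pd.Series | None = None
    col_max: pd.Series | None = None


def profile_peptides(peptides, pka_set: str = "emboss") -> PropertyMatrix:
    if not peptides:
        raise ValueError("no peptides to profile")
    rows = {p.id: profile(p.sequence, pka_set) for p in peptides}
    raw = pd.DataFrame.from_dict(rows, orient="index")[list(PROPERTY_NAMES)]
    return normalize_matrix(PropertyMatrix(raw=raw))


def normalize_matrix(matrix: PropertyMatrix) -> PropertyMatrix:
    """Per-column min-max normalization to [0,1]; constant columns map to 0."""
    raw = matrix.raw
    cmin, cmax = raw.min(axis=0), raw.max(axis=0)
    span = cmax - cmin
    constant = span == 0
    if constant.any():
        warnings.warn(f"constant property columns map to 0: {list(raw.columns[constant])}")
    safe = span.where(~constant, 1.0)
    norm = (raw - cmin) / safe
    norm.loc[:, constant] = 0.0
    return PropertyMatrix(raw=raw, normalized=norm, col_min=cmin, col_max=cmax)


def export_properties(matrix: PropertyMatrix, path):
    """TSV of raw values and _norm columns side by side."""
    norm = matrix.normalized.add_suffix("_norm")
    pd.concat([matrix.raw, norm], axis=1).to_csv(path, sep="\t", index_label="id")


def export_heatmap_matrix(matrix: PropertyMatrix, path):
    """TSV of the normalized matrix (heat-map analogue)."""
    matrix.normalized.to_csv(path, sep="\t", index_label="id")


def export_scatter(matrix: PropertyMatrix, path):
    """TSV of GRAVY vs net charge with the Boman index (raw values)."""
    cols = matrix.raw[["gravy", "net_charge_pH7", "boman"]]
    cols.to_csv(path, sep="\t", index_label="id")
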