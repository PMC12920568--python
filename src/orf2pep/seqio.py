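"""Sequence and annotation I/O: FASTA, GFF3, BED and ORF translation.

Internal coordinates are 0-based half-open on the forward strand; GFF3
output converts to the standard 1-based inclusive convention.  Translation
uses NCBI genetic code table 11 (bacteria/archaea), with the called start
codon always rendered as methionine.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_NON_DNA = re.compile(r"[^ACGTN]")
_NON_PROTEIN = re.compile(r"[^ACDEFGHIKLMNPQRSTVWYX]")

_TABLE11 = unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE11.stop_codons)          # {TAA, TAG, TGA}
START_CODONS = frozenset({"ATG", "CTG", "GTG", "TTG"})


@dataclasses.dataclass(frozen=True)
class GenomeRecord:
    """A DNA sequence over {A,C,G,T,N}, uppercased and normalized on load."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in record {self.id}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class PeptideRecord:
    """A peptide over the 20 standard residues plus X."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty peptide sequence for record {self.id}")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"non-protein characters in record {self.id}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class GeneCall:
    """A retained coding prediction (0-based half-open forward-strand coords)."""

    seq_id: str
    start: int
    end: int
    strand: str
    probability: float
    source_orf: object = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene call requires start < end, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")

    @property
    def stop_coordinate(self) -> int:
        """Forward-strand coordinate identifying the gene's 3' (stop) end."""
        return self.end if self.strand == "+" else self.start


def _normalize(seq: str, molecule: str) -> str:
    seq = seq.upper().replace("U", "T") if molecule == "dna" else seq.upper()
    if molecule == "dna":
        return _NON_DNA.sub("N", seq)
    return _NON_PROTEIN.sub("X", seq)


def read_fasta(path, molecule: str = "dna"):
    """Read a FASTA file into GenomeRecord or PeptideRecord objects.

    IUPAC ambiguity codes other than N collapse to N (DNA) or X (protein).
    Raises on an empty file and on duplicate record IDs.
    """
    if molecule not in {"dna", "protein"}:
        raise ValueError("molecule must be 'dna' or 'protein'")
    records = []
    seen, dupes = set(), []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            dupes.append(rec.id)
        seen.add(rec.id)
        seq = _normalize(str(rec.seq), molecule)
        desc = rec.description
        if desc == rec.id:
            desc = ""
        elif desc.startswith(rec.id + " "):
            desc = desc[len(rec.id) + 1:]
        cls = GenomeRecord if molecule == "dna" else PeptideRecord
        records.append(cls(id=rec.id, sequence=seq, description=desc))
    if dupes:
        raise ValueError(f"duplicate record IDs in {path}: {sorted(set(dupes))}")
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable, path):
    """Write records as 60-column wrapped FASTA."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    return Path(path)


def write_gff(calls: Iterable[GeneCall], path, source: str = "orf2pep"):
    """Write gene calls as GFF3 CDS features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, call in enumerate(calls, start=1):
            attrs = f"ID=gene{i}"
            fh.write(
                f"{call.seq_id}\t{source}\tCDS\t{call.start + 1}\t{call.end}\t"
                f"{call.probability:.4f}\t{call.strand}\t0\t{attrs}\n"
            )
    return Path(path)


def write_bed(candidates: Iterable, path):
    """Write ORF candidates as BED6 (0-based half-open, empty score)."""
    with open(path, "w") as fh:
        for i, c in enumerate(candidates, start=1):
            fh.write(f"{c.seq_id}\t{c.start}\t{c.end}\torf{i}\t.\t{c.strand}\n")
    return Path(path)


def translate_orf(nt_seq: str, is_start_codon_orf: bool = True) -> str:
    """Translate an ORF nucleotide sequence under NCBI table 11.

    A trailing incomplete codon is trimmed; a trailing stop codon is dropped
    from the peptide; codons containing N render X.  When the ORF was called
    from a start codon, the first codon renders M whatever its identity
    (table-11 alternative initiators GTG/TTG/CTG code for fMet in vivo).
    An internal stop raises with the offending nucleotide offset.
    """
    nt_seq = nt_seq.upper()
    usable = len(nt_seq) - len(nt_seq) % 3
    codons = [nt_seq[i:i + 3] for i in range(0, usable, 3)]
    if not codons:
        raise ValueError("sequence shorter than one codon")
    aas = []
    for ci, codon in enumerate(codons):
        if "N" in codon:
            aas.append("X")
        elif codon in STOP_CODONS:
            if ci != len(codons) - 1:
                raise ValueError(
                    f"internal stop codon {codon} at nucleotide offset {ci * 3}")
            aas.append("*")
        else:
            aas.append(str(Seq(codon).translate(table=11)))
    if aas[-1] == "*":
        aas.pop()
    if not aas:
        raise ValueError("ORF encodes no residues after removing the stop codon")
    if is_start_codon_orf:
        aas[0] = "M"
    return "".join(aas)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
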