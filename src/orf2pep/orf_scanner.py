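"""Six-frame ORF enumeration with completeness classes and length filters.

The scanner walks every frame on both strands, splits each frame into
stop-bounded segments, and emits candidates according to the completeness
taxonomy of fragment-derived ORFs:

* ``complete``      — in-frame start codon (ATG/CTG/GTG/TTG) through stop.
* ``missing5``      — fragment edge through the first in-frame stop (the
                      upstream region, and hence the true start, is absent).
* ``missing3``      — in-frame start codon through the fragment edge (no
                      stop before the sequence ends).
* ``missing_both``  — a whole-fragment frame containing neither start nor
                      stop codon.

Candidates shorter than ``min_len`` (60 bp by default, stop codon included)
are suppressed.  The 30 bp window 5' of the start codon is retained on each
candidate for translation-initiation-site scoring; it never shifts the ORF
coordinates themselves.
"""

from __future__ import annotations

import dataclasses

from .seqio import DNA_ALPHABET, START_CODONS, STOP_CODONS, GenomeRecord, reverse_complement

DEFAULT_MIN_LEN = 60
DEFAULT_UPSTREAM = 30
DEFAULT_FIXED_LEN = 700
PAD_SYMBOL = "-"

COMPLETE = "complete"
MISSING5 = "missing5"
MISSING3 = "missing3"
MISSING_BOTH = "missing_both"


@dataclasses.dataclass(frozen=True)
class OrfCandidate:
    """A located ORF; coordinates are 0-based half-open on the forward strand."""

    seq_id: str
    start: int
    end: int
    strand: str
    frame: int
    completeness: str
    nt_seq: str
    upstream_window: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def stop_coordinate(self) -> int:
        """Forward-strand coordinate identifying the 3' (stop) end."""
        return self.end if self.strand == "+" else self.start

    def __post_init__(self):
        if self.end - self.start != len(self.nt_seq):
            raise ValueError("nt_seq length does not match coordinates")
        if len(self.upstream_window) > DEFAULT_UPSTREAM:
            raise ValueError("upstream window longer than 30 bp")


@dataclasses.dataclass(frozen=True)
class StandardizedOrf:
    candidate: OrfCandidate
    fixed_seq: str

    def __post_init__(self):
        core = self.fixed_seq.rstrip(PAD_SYMBOL)
        if PAD_SYMBOL in core:
            raise ValueError("pad symbols must only appear at the 3' end")


def _scan_strand(seq: str, min_len: int, upstream: int, all_starts: bool):
    """Yield (cstart, cend, frame, completeness) on the given coding-strand string.

    Coordinates are half-open on the *coding* strand handed in.
    """
    n = len(seq)
    for frame in range(3):
        ncod = (n - frame) // 3
        if ncod == 0:
            continue
        codon_at = lambda ci: seq[frame + 3 * ci: frame + 3 * ci + 3]
        stops = [ci for ci in range(ncod) if codon_at(ci) in STOP_CODONS]
        segments = []  # (first_codon, last_codon_inclusive, has5_edge, has_stop)
        if not stops:
            segments.append((0, ncod - 1, True, False))
        else:
            segments.append((0, stops[0], True, True))
            for a, b in zip(stops, stops[1:]):
                segments.append((a + 1, b, False, True))
            if stops[-1] + 1 <= ncod - 1:
                segments.append((stops[-1] + 1, ncod - 1, False, False))
        for first, last, at_edge, has_stop in segments:
            seg_codons = range(first, last + (0 if has_stop else 1))
            starts = [ci for ci in seg_codons if codon_at(ci) in START_CODONS]
            end_pos = frame + 3 * (last + 1)

            def emit(ci_start, completeness):
                s = frame + 3 * ci_start
                if end_pos - s >= min_len:
                    yield (s, end_pos, frame, completeness)

            if has_stop:
                chosen = starts if all_starts else starts[:1]
                for ci in chosen:
                    yield from emit(ci, COMPLETE)
                if at_edge:
                    # 5'-truncated reading: edge codon through the stop.
                    if not (starts and starts[0] == first):
                        yield from emit(first, MISSING5)
            else:
                if starts:
                    chosen = starts if all_starts else starts[:1]
                    for ci in chosen:
                        yield from emit(ci, MISSING3)
                elif at_edge:
                    yield from emit(first, MISSING_BOTH)


def scan_orfs(record: GenomeRecord, min_len: int = DEFAULT_MIN_LEN,
              upstream: int = DEFAULT_UPSTREAM, all_starts: bool = False):
    """Enumerate ORF candidates in all six frames of ``record``.

    Default mode emits, per stop-bounded segment, the ORF from its 5'-most
    in-frame start codon (the longest ORF for that stop); ``all_starts``
    emits one candidate per in-frame start.  Fragment-edge segments yield
    the matching incomplete completeness class.
    """
    seq = record.sequence
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters: {sorted(bad)}")
    n = len(seq)
    out = {}

    def add(key, cand):
        prior = out.get(key)
        if prior is None or (prior.completeness != COMPLETE and
                             cand.completeness == COMPLETE):
            out[key] = cand

    for s, e, frame, comp in _scan_strand(seq, min_len, upstream, all_starts):
        win = seq[max(0, s - upstream):s]
        add((s, e, "+"),
            OrfCandidate(record.id, s, e, "+", frame, comp, seq[s:e], win))

    rc = reverse_complement(seq)
    for s, e, frame, comp in _scan_strand(rc, min_len, upstream, all_starts):
        fs, fe = n - e, n - s
        win = rc[max(0, s - upstream):s]
        add((fs, fe, "-"),
            OrfCandidate(record.id, fs, fe, "-", frame, comp, rc[s:e], win))

    return sorted(out.values(), key=lambda c: (c.start, c.end, c.strand))


def standardize_length(candidate: OrfCandidate, target: int = DEFAULT_FIXED_LEN) -> StandardizedOrf:
    """Pad (3' end) or truncate (keep 5' end) the ORF to ``target`` symbols."""
    if target <= 0:
        raise ValueError("target length must be positive")
    seq = candidate.nt_seq
    if len(seq) >= target:
        fixed = seq[:target]
    else:
        fixed = seq + PAD_SYMBOL * (target - len(seq))
    return StandardizedOrf(candidate=candidate, fixed_seq=fixed)


def overlap_bp(a, b) -> int:
    """Forward-strand overlap in bp between two intervals, 0 when disjoint."""
    if a.seq_id != b.seq_id:
        raise ValueError(f"intervals on different sequences: {a.seq_id} vs {b.seq_id}")
    return max(0, min(a.end, b.end) - max(a.start, b.start))
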