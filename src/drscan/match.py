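"""Approximate occurrence search for direct repeats under a Levenshtein budget.

The detection engine behind the pipeline's first two steps: find every
position in a read where a query direct repeat occurs within ``d_max``
insertions, deletions, or substitutions. The contract is defined by output
(all sub-threshold occurrences), not by any particular multi-pattern
algorithm: a vectorized semi-global dynamic program enumerates, for every end
position in the read, the minimum edit distance to the query, with a fast
edit-distance pre-filter to skip reads that cannot contain a hit.

``N`` never matches anything — including another ``N`` — so low-quality base
calls cannot fabricate repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .seqio import DRQuery, NucleotideSequence, revcomp

# Remaps making N in the two strings distinct symbols, so edlib scores
# N-vs-N (and N-vs-base) as a mismatch, per the package-wide N rule.
_N_LEFT = str.maketrans("N", "!")
_N_RIGHT = str.maketrans("N", "?")

_N_CODE = ord("N")


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of reference-guided detection.

    d_max
        Acceptable Levenshtein edit distance between a query DR and its
        occurrence in a read; the study range is 0-3.
    min_spacer, max_spacer
        Admissible gap between two chained DR copies, bp. Spacers in known
        CRISPR arrays run 26-50 bp; the maximum allowed distance between
        detected repeats defaults to 60 bp.
    dr_len_range
        Advisory length range for query DRs (warning only on ingest).
    both_strands
        Also search each query's reverse complement (strand ``-``).
    """

    d_max: int = 3
    min_spacer: int = 26
    max_spacer: int = 60
    dr_len_range: tuple[int, int] = (23, 47)
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")
        if not 0 < self.min_spacer <= self.max_spacer:
            raise ValueError("need 0 < min_spacer <= max_spacer")
        if self.dr_len_range[0] <= 0:
            raise ValueError("DR lengths must be positive")


@dataclass(frozen=True, order=True)
class DRMatch:
    """One approximate occurrence of a query DR inside a read.

    Coordinates are 0-based half-open on the read; ``strand`` is the
    orientation of the query relative to the read.
    """

    read_id: str = field(compare=False)
    query_id: str = field(compare=False)
    start: int
    end: int
    strand: str = field(compare=False)
    edits: int = field(compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad match interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "DRMatch") -> bool:
        return self.start < other.end and other.start < self.end


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance with N counting as a mismatch against anything."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(
        a.translate(_N_LEFT), b.translate(_N_RIGHT), task="distance"
    )["editDistance"]


def _end_distances(read_codes: np.ndarray, query: str) -> np.ndarray:
    """Semi-global DP: ``D[j]`` = min edit distance of ``query`` to any
    substring of the read ending at position ``j`` (0..L inclusive).

    Row recurrence with the in-row left dependency resolved as a running
    minimum of ``t[j'] + (j - j')``, which keeps every row a handful of
    vectorized operations.
    """
    L = read_codes.size
    idx = np.arange(L + 1, dtype=np.int32)
    d = np.zeros(L + 1, dtype=np.int32)  # free start anywhere in the read
    t = np.empty(L + 1, dtype=np.int32)
    for ch in query.encode():
        if ch == _N_CODE:
            sub = np.ones(L, dtype=np.int32)
        else:
            sub = (read_codes != ch).astype(np.int32)
            sub[read_codes == _N_CODE] = 1
        t[0] = d[0] + 1
        np.minimum(d[:-1] + sub, d[1:] + 1, out=t[1:])
        d = np.minimum.accumulate(t - idx) + idx
    return d


def _best_start(read: str, query: str, end: int, edits: int, d_max: int) -> int:
    """Start of the occurrence ending at ``end``: among starts achieving the
    minimal edit count, the latest one (shortest span)."""
    m = len(query)
    for span in range(max(0, m - d_max), m + d_max + 1):
        i = end - span
        if i < 0:
            continue
        if levenshtein(read[i:end], query) == edits:
            return i
    raise AssertionError("end-distance DP and span re-check disagree")


def _collapse(candidates: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Collapse overlapping candidate spans of one (query, strand) into their
    best representative: minimum edits, then shortest span, then leftmost."""
    if not candidates:
        return []
    candidates.sort(key=lambda c: (c[0], c[1]))
    kept: list[list[tuple[int, int, int]]] = [[candidates[0]]]
    group_end = candidates[0][1]
    for cand in candidates[1:]:
        if cand[0] < group_end:  # overlaps the current group
            kept[-1].append(cand)
            group_end = max(group_end, cand[1])
        else:
            kept.append([cand])
            group_end = cand[1]
    return [
        min(group, key=lambda c: (c[2], c[1] - c[0], c[0]))
        for group in kept
    ]


def find_occurrences(
    read: NucleotideSequence,
    queries: Sequence[DRQuery],
    params: Optional[DetectionParams] = None,
) -> list[DRMatch]:
    """All approximate occurrences of any query DR in one read.

    Semi-global semantics: wherever some substring of the read lies within
    ``params.d_max`` edits of a query, a match is reported; overlapping
    candidate spans of the same query and strand are collapsed to the one
    with minimum edits (ties: shortest span, then leftmost start). With
    ``both_strands`` each query is also searched as its reverse complement,
    reported with strand ``-``. Results are sorted by (start, end).
    """
    if params is None:
        params = DetectionParams()
    if not queries:
        raise ValueError("query collection must be nonempty")
    d_max = params.d_max
    seq = read.residues
    read_codes = np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.int16)
    read_shim = seq.translate(_N_LEFT)

    matches: list[DRMatch] = []
    for q in queries:
        variants = [(q.residues, "+")]
        if params.both_strands:
            variants.append((revcomp(q.residues), "-"))
        for qseq, strand in variants:
            if len(seq) < len(qseq) - d_max:
                continue
            # cheap pre-filter: best infix distance over the whole read
            pre = edlib.align(
                qseq.translate(_N_RIGHT), read_shim,
                mode="HW", task="distance", k=d_max,
            )["editDistance"]
            if pre == -1:
                continue
            dists = _end_distances(read_codes, qseq)
            ends = np.nonzero(dists <= d_max)[0]
            candidates = []
            for j in ends:
                j = int(j)
                e = int(dists[j])
                i = _best_start(seq, qseq, j, e, d_max)
                if i < j:  # zero-length spans (tiny queries at d_max) are noise
                    candidates.append((i, j, e))
            for i, j, e in _collapse(candidates):
                matches.append(
                    DRMatch(read.id, q.id, i, j, strand, e)
                )
    matches.sort(key=lambda m: (m.start, m.end, m.query_id, m.strand))
    return matches


def _priority(m: DRMatch) -> tuple:
    # lower edits, then longer span, then leftmost, then query id, then strand
    return (m.edits, -m.span, m.start, m.end, m.query_id, m.strand)


def chain_nonoverlapping(matches: Sequence[DRMatch]) -> list[DRMatch]:
    """Maximal non-overlapping subset of one read's matches.

    Greedy by priority (lower edits, then longer span, then leftmost start,
    then query id lexicographic): a match is accepted iff it does not overlap
    any already-accepted match. This equals the exhaustive choice of the
    lexicographically best maximal non-overlapping subset under the same
    ordering. Output sorted by start.
    """
    accepted: list[DRMatch] = []
    for m in sorted(matches, key=_priority):
        if all(not m.overlaps(a) for a in accepted):
            accepted.append(m)
    accepted.sort(key=lambda m: (m.start, m.end))
    return accepted
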