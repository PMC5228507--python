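"""Reference-guided CRISPR detection: recruit, verify geometry, extract.

Three steps over unassembled reads: (1) recruit reads containing at least one
approximate occurrence of a query direct repeat; (2) within each recruited
read, look for two or more chained copies of the same query DR at an
admissible distance from each other; (3) extract the sequence between
consecutive copies as a spacer and collapse exact duplicates into a
non-redundant set (similarity-level collapse is a separate, later clustering
step).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .match import DetectionParams, DRMatch, chain_nonoverlapping, find_occurrences
from .seqio import DRQuery, NucleotideSequence, revcomp


@dataclass(frozen=True)
class Spacer:
    """One extracted inter-repeat sequence, with its flanking DR matches.

    ``residues`` follow the query DR's orientation: a spacer called between
    two minus-strand DR copies is reverse-complemented on extraction.
    ``start``/``end`` remain read coordinates (0-based half-open).
    """

    residues: str
    read_id: str
    query_id: str
    strand: str
    left_dr: DRMatch
    right_dr: DRMatch

    @property
    def start(self) -> int:
        return self.left_dr.end

    @property
    def end(self) -> int:
        return self.right_dr.start

    @property
    def sequence_id(self) -> str:
        return spacer_id(self.residues)


@dataclass(frozen=True)
class NonRedundantSpacer:
    """A distinct spacer sequence and every occurrence that produced it."""

    sequence_id: str
    residues: str
    occurrences: tuple[Spacer, ...]

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)


def spacer_id(residues: str) -> str:
    """Stable content-derived spacer identifier."""
    return "sp_" + hashlib.sha1(residues.encode()).hexdigest()[:12]


def recruit_reads(
    reads: Sequence[NucleotideSequence],
    queries: Sequence[DRQuery],
    params: Optional[DetectionParams] = None,
) -> list[tuple[NucleotideSequence, list[DRMatch]]]:
    """Step 1: the subset of reads containing >= 1 DR occurrence.

    Read order is preserved; each recruited read carries its match list.
    """
    if not reads:
        raise ValueError("read set must be nonempty")
    params = params or DetectionParams()
    recruited = []
    for read in reads:
        matches = find_occurrences(read, queries, params)
        if matches:
            recruited.append((read, matches))
    return recruited


def call_spacers(
    read: NucleotideSequence,
    chained: Sequence[DRMatch],
    params: Optional[DetectionParams] = None,
) -> list[Spacer]:
    """Step 2+3 on one read: emit the gap between each consecutive pair of
    chained same-query, same-strand DR matches whose length is admissible.

    A triplet of DR copies yields two spacers (the array reading). Pairs
    whose flanks come from different queries are not spacers: a query set
    mixes DRs of many taxa and chimeric flanks have no biological reading.
    """
    params = params or DetectionParams()
    spacers = []
    for prev, nxt in zip(chained, chained[1:]):
        if prev.query_id != nxt.query_id or prev.strand != nxt.strand:
            continue
        gap = nxt.start - prev.end
        if not params.min_spacer <= gap <= params.max_spacer:
            continue
        residues = read.residues[prev.end:nxt.start]
        if prev.strand == "-":
            residues = revcomp(residues)
        spacers.append(
            Spacer(residues, read.id, prev.query_id, prev.strand, prev, nxt)
        )
    return spacers


def detect_spacers(
    reads: Sequence[NucleotideSequence],
    queries: Sequence[DRQuery],
    params: Optional[DetectionParams] = None,
) -> list[NonRedundantSpacer]:
    """The full pipeline: recruit -> chain -> call -> exact dedupe.

    Exact-duplicate residues collapse to one entry (first occurrence wins the
    slot; all occurrences are retained as provenance). Deterministic given
    input order. Non-redundancy here is string identity only; similarity
    clustering at a threshold is `drscan.cluster`'s job.
    """
    params = params or DetectionParams()
    by_seq: dict[str, list[Spacer]] = {}
    for read, matches in recruit_reads(reads, queries, params):
        chained = chain_nonoverlapping(matches)
        for sp in call_spacers(read, chained, params):
            by_seq.setdefault(sp.residues, []).append(sp)
    return [
        NonRedundantSpacer(spacer_id(seq), seq, tuple(occs))
        for seq, occs in by_seq.items()
    ]


SpacerLike = Union[str, Spacer, NonRedundantSpacer, NucleotideSequence]


def _residues_of(item: SpacerLike) -> str:
    if isinstance(item, str):
        return item
    return item.residues


def canonical(residues: str) -> str:
    """Strand-insensitive canonical form: lexicographic min of the two
    orientations."""
    rc = revcomp(residues)
    return residues if residues <= rc else rc


def shared_spacers(
    set_a: Iterable[SpacerLike],
    set_b: Iterable[SpacerLike],
    strand_insensitive: bool = True,
) -> tuple[int, list[str]]:
    """Count exact sequence identities between two spacer collections.

    With ``strand_insensitive`` a sequence and its reverse complement are
    the same spacer. Returns (count, sorted shared sequences in canonical
    form).
    """
    norm = canonical if strand_insensitive else (lambda s: s)
    a = {norm(_residues_of(x)) for x in set_a}
    b = {norm(_residues_of(x)) for x in set_b}
    shared = sorted(a & b)
    return len(shared), shared


def spacer_rate(n_spacers: int, n_reads: int) -> float:
    """Spacers per million reads — the cross-metagenome normalization."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    return n_spacers / n_reads * 1e6


def write_spacer_fasta(spacers: Sequence[NonRedundantSpacer], path) -> None:
    """Spacer FASTA: id = content digest; description carries the first
    occurrence's read, query, strand, and 0-based half-open coordinates."""
    from .seqio import write_fasta

    records = []
    for sp in spacers:
        first = sp.occurrences[0]
        desc = (
            f"read={first.read_id} query={first.query_id} strand={first.strand} "
            f"pos={first.start}:{first.end} n_occ={sp.n_occurrences}"
        )
        records.append(NucleotideSequence(sp.sequence_id, sp.residues, desc))
    write_fasta(records, path)


def write_provenance(spacers: Sequence[NonRedundantSpacer], path) -> None:
    """Provenance TSV: one row per spacer occurrence."""
    cols = [
        "spacer_id", "read_id", "query_id", "strand",
        "start", "end", "edits_left", "edits_right",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for sp in spacers:
            for occ in sp.occurrences:
                fh.write(
                    "\t".join(
                        map(
                            str,
                            [
                                sp.sequence_id, occ.read_id, occ.query_id,
                                occ.strand, occ.start, occ.end,
                                occ.left_dr.edits, occ.right_dr.edits,
                            ],
                        )
                    )
                    + "\n"
                )
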