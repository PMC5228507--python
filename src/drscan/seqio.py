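"""Sequence data model and FASTA/FASTQ I/O.

All coordinates throughout the package are 0-based, half-open ``[start, end)``.
Residues are canonicalized to uppercase on ingest and restricted to the
alphabet ``{A, C, G, T, N}``; ``N`` is a legal residue in reads but never
counts as a match in any downstream comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# empirical direct-repeat length range in known CRISPR arrays, bp
DR_LEN_RANGE = (23, 47)


class SequenceFormatError(ValueError):
    """Raised for malformed or empty sequence files and alphabet violations."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA sequence: the unit of all pipeline I/O."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence id must be nonempty")
        if not self.residues:
            raise SequenceFormatError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DRQuery:
    """A query direct repeat, optionally annotated with its host taxon.

    ``host_taxon`` is free text (typically a genus or order name); when absent
    it propagates as ``"unknown"`` in virus-host networks.
    """

    id: str
    residues: str
    host_taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("DR query id must be nonempty")
        if not self.residues:
            raise SequenceFormatError(f"DR query {self.id!r} has no residues")
        lo, hi = DR_LEN_RANGE
        if not lo <= len(self.residues) <= hi:
            warnings.warn(
                f"DR query {self.id!r} is {len(self.residues)} bp, outside the "
                f"empirical direct-repeat range [{lo}, {hi}] bp",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.residues)


def _validate(seq_id: str, residues: str) -> str:
    residues = residues.upper()
    for pos, ch in enumerate(residues):
        if ch not in ALPHABET:
            raise SequenceFormatError(
                f"record {seq_id!r}: invalid residue {ch!r} at position {pos}"
            )
    return residues


def _check_unique(ids: list[str], path) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise SequenceFormatError(f"{path}: duplicate record id {i!r}")
        seen.add(i)


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Residues are uppercased; record order is preserved. An empty file,
    a duplicate id, or a non-ACGTN residue raises :class:`SequenceFormatError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            NucleotideSequence(
                id=rec.id,
                residues=_validate(rec.id, str(rec.seq)),
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    _check_unique([r.id for r in records], path)
    return records


def read_fastq(path) -> list[NucleotideSequence]:
    """Read 4-line-per-record FASTQ; quality strings are discarded.

    The detection model operates on base calls only, so qualities carry no
    information for this pipeline. Truncated records raise with the record
    index; same alphabet/uniqueness contracts as :func:`read_fasta`.
    """
    records = []
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            records.append(
                NucleotideSequence(
                    id=rec.id,
                    residues=_validate(rec.id, str(rec.seq)),
                    description=rec.description[len(rec.id):].strip(),
                )
            )
    except ValueError as exc:
        raise SequenceFormatError(
            f"{path}: malformed FASTQ near record {len(records)}: {exc}"
        ) from exc
    if not records:
        raise SequenceFormatError(f"{path}: no FASTQ records found")
    _check_unique([r.id for r in records], path)
    return records


def read_sequences(path) -> list[NucleotideSequence]:
    """Dispatch on extension: .fq/.fastq -> FASTQ, anything else -> FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return read_fastq(path)
    return read_fasta(path)


def read_dr_queries(path) -> list[DRQuery]:
    """Read query direct repeats from FASTA or a 2/3-column TSV.

    TSV columns: id, sequence[, host_taxon]. For FASTA input the record
    description (text after the id) is taken as the host taxon when present.
    """
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt", ".tab"}:
        queries = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise SequenceFormatError(
                        f"{path}:{lineno}: expected at least 2 tab-separated columns"
                    )
                taxon = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
                queries.append(
                    DRQuery(fields[0], _validate(fields[0], fields[1]), taxon)
                )
        if not queries:
            raise SequenceFormatError(f"{path}: no DR queries found")
        _check_unique([q.id for q in queries], path)
        return queries
    return [
        DRQuery(r.id, r.residues, r.description or None)
        for r in read_fasta(path)
    ]


def revcomp(residues: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N. An involution."""
    return residues.translate(_COMPLEMENT)[::-1]


def write_fasta(records: Iterable[NucleotideSequence], path, line_width: int = 70) -> None:
    """Write records as wrapped FASTA; round-trips with :func:`read_fasta`."""
    records = list(records)
    if not records:
        raise SequenceFormatError("refusing to write an empty FASTA file")
    bio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=line_width)
    writer.write_file(bio_records)
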