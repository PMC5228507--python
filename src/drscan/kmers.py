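"""Oligonucleotide usage signatures and the virus-host squared distance.

A genome's dinucleotide (k=2) or trinucleotide (k=3) profile is the
frequency of each of the 4^k words over all overlapping windows, windows
containing N excluded. The distance between a virus and its CRISPR-matched
host is the sum over words of the squared frequency difference — a squared
Euclidean measure; group summaries report the mean with a ~95% interval of
two standard errors. Counting is strand-naive (forward strand only) by
default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import revcomp

_BASES = "ACGT"
_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3}


def kmer_words(k: int) -> list[str]:
    """All 4^k words of {A,C,G,T} in lexicographic order."""
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


@dataclass(frozen=True)
class KmerProfile:
    """Normalized overlapping k-mer frequency vector, lexicographic order."""

    sequence_id: str
    k: int
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if self.frequencies.shape != (4 ** self.k,):
            raise ValueError("frequency vector length must be 4^k")


def kmer_frequencies(
    seq, k: int, sequence_id: str | None = None, both_strands: bool = False
) -> KmerProfile:
    """Overlapping k-mer frequencies of one sequence (k = 2 or 3).

    Windows containing N are skipped, keeping the result a proper
    distribution over {A,C,G,T}^k. ``both_strands`` additionally counts the
    reverse complement (off by default: the distance measure is strand-naive).
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if hasattr(seq, "residues"):
        sequence_id = sequence_id or seq.id
        seq = seq.residues
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    strands = [seq, revcomp(seq)] if both_strands else [seq]
    counts = np.zeros(4 ** k, dtype=np.int64)
    for s in strands:
        raw = np.frombuffer(s.encode(), dtype=np.uint8)
        codes = np.full(raw.size, -1, dtype=np.int64)
        for byte, val in _BASE_CODE.items():
            codes[raw == byte] = val
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        vals = win @ powers
        vals = vals[(win >= 0).all(axis=1)]
        counts += np.bincount(vals, minlength=4 ** k)
    total = counts.sum()
    freqs = counts / total if total > 0 else counts.astype(float)
    return KmerProfile(sequence_id or "<anonymous>", k, freqs)


def usage_distance(p: KmerProfile, q: KmerProfile) -> float:
    """Sum of squared per-word frequency differences (squared Euclidean)."""
    if p.k != q.k:
        raise ValueError(f"profiles have different k: {p.k} vs {q.k}")
    return float(np.sum((p.frequencies - q.frequencies) ** 2))


@dataclass(frozen=True)
class GroupSummary:
    """Mean distance for one group with its ~95% (two standard error) band."""

    group: str
    k: int
    n: int
    mean: float
    se: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mean - 2 * self.se, self.mean + 2 * self.se)


def summarize_pairs(pairs: pd.DataFrame) -> list[GroupSummary]:
    """Group virus-host pair distances and report mean +/- 2*SE per k.

    ``pairs`` needs columns virus_id, host_id, group, d2, d3; ``group`` is
    whatever the pairs should be averaged over (a host name or a metagenome
    name). Duplicate (group, virus_id, host_id) rows are collapsed first so
    each group summarizes a non-redundant virus list. SE = sd/sqrt(n) with
    SE = 0 for singleton groups.
    """
    required = {"virus_id", "host_id", "group", "d2", "d3"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table is missing columns: {sorted(missing)}")
    dedup = pairs.drop_duplicates(subset=["group", "virus_id", "host_id"])
    if len(dedup) < len(pairs):
        warnings.warn(
            f"dropped {len(pairs) - len(dedup)} duplicate virus-host pairs "
            "within groups (non-redundant virus lists)"
        )
    summaries = []
    for group, sub in dedup.groupby("group", sort=True):
        for k, col in ((2, "d2"), (3, "d3")):
            vals = sub[col].to_numpy(dtype=float)
            n = vals.size
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            summaries.append(GroupSummary(str(group), k, n, mean, se))
    return summaries


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    rows = [
        {
            "group": s.group,
            "k": s.k,
            "n": s.n,
            "mean": s.mean,
            "se": s.se,
            "lo": s.interval[0],
            "hi": s.interval[1],
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def pair_distances(
    pairs: pd.DataFrame, genomes: dict[str, str]
) -> pd.DataFrame:
    """Attach d2/d3 columns to a (virus_id, host_id, group) pairs table.

    ``genomes`` maps every referenced id to its sequence. The operation uses
    exactly the sequences given — multi-replicon genomes are never
    auto-concatenated; pass the replicon you mean (e.g., chromosome 1).
    """
    profiles: dict[tuple[str, int], KmerProfile] = {}

    def prof(gid: str, k: int) -> KmerProfile:
        if (gid, k) not in profiles:
            if gid not in genomes:
                raise KeyError(f"no genome sequence for id {gid!r}")
            profiles[(gid, k)] = kmer_frequencies(genomes[gid], k, gid)
        return profiles[(gid, k)]

    out = pairs.copy()
    out["d2"] = [
        usage_distance(prof(v, 2), prof(h, 2))
        for v, h in zip(out["virus_id"], out["host_id"])
    ]
    out["d3"] = [
        usage_distance(prof(v, 3), prof(h, 3))
        for v, h in zip(out["virus_id"], out["host_id"])
    ]
    return out
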