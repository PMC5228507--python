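"""Greedy identity clustering of spacers into a non-redundant set.

Semantics follow nucleotide CD-HIT: sequences are sorted longest-first and
scanned in order; each joins the first existing cluster whose representative
it matches at >= the identity threshold (0.9 by default), else founds a new
cluster. Identity is the number of identical aligned positions in the best
global alignment divided by the length of the shorter sequence. The
guarantee here is the semantics, not CD-HIT's word-filter speed tricks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

from .detect import NonRedundantSpacer, spacer_id
from .seqio import revcomp

# global alignment scoring used to define "best alignment"
MATCH = 1
MISMATCH = -1
GAP = -2


@dataclass(frozen=True)
class ClusterParams:
    """threshold: minimum member-to-representative identity, in (0.5, 1.0]."""

    threshold: float = 0.9
    strand_insensitive: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0.5, 1.0]")


@dataclass
class SpacerCluster:
    """One cluster: the representative (its longest member) plus members."""

    cluster_id: int
    representative_id: str
    representative_seq: str
    member_ids: list[str] = field(default_factory=list)
    member_identities: list[float] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _align_identities(a: str, b: str) -> int:
    """Identical aligned positions in the best global alignment of a and b
    (match +1 / mismatch -1 / gap -2, linear), maximizing identities among
    score-optimal alignments. N is never an identity, not even against N."""
    n, m = len(a), len(b)
    prev = [(GAP * j, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur = [(GAP * i, 0)]
        prev_jm1 = prev[0]
        for j in range(1, m + 1):
            eq = ai == b[j - 1] and ai != "N"
            ds, di = prev_jm1
            diag = (ds + (MATCH if eq else MISMATCH), di + (1 if eq else 0))
            up = (prev[j][0] + GAP, prev[j][1])
            left = (cur[j - 1][0] + GAP, cur[j - 1][1])
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            cur.append(best)
            prev_jm1 = prev[j]
        prev = cur
    return prev[m][1]


def pairwise_identity(a: str, b: str, strand_insensitive: bool = True) -> float:
    """Fraction of identical aligned positions over the shorter sequence.

    The shorter-sequence denominator is CD-HIT's convention. With
    ``strand_insensitive`` the identity is the max over ``b`` and its reverse
    complement. Symmetric; in [0, 1].
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    denom = min(len(a), len(b))
    ident = _align_identities(a, b) / denom
    if strand_insensitive:
        ident = max(ident, _align_identities(a, revcomp(b)) / denom)
    return ident


SpacerInput = Union[str, NonRedundantSpacer, tuple]


def _as_pairs(spacers: Sequence[SpacerInput]) -> list[tuple[str, str]]:
    pairs = []
    for sp in spacers:
        if isinstance(sp, str):
            pairs.append((spacer_id(sp), sp))
        elif isinstance(sp, tuple):
            pairs.append((sp[0], sp[1]))
        else:
            pairs.append((sp.sequence_id, sp.residues))
    return pairs


def greedy_cluster(
    spacers: Sequence[SpacerInput],
    params: ClusterParams = ClusterParams(),
) -> list[SpacerCluster]:
    """Cluster spacers greedily at the identity threshold.

    Accepts raw strings, (id, sequence) pairs, or non-redundant spacer
    records. Scan order is length-descending, id-ascending; assignment is
    first-fit to the earliest qualifying representative. The result
    partitions the input: every spacer lands in exactly one cluster, and its
    identity to its representative is recorded.
    """
    pairs = _as_pairs(spacers)
    if not pairs:
        raise ValueError("spacer collection must be nonempty")
    order = sorted(pairs, key=lambda p: (-len(p[1]), p[0]))
    clusters: list[SpacerCluster] = []
    for sid, seq in order:
        placed = False
        for cl in clusters:
            ident = pairwise_identity(
                cl.representative_seq, seq, params.strand_insensitive
            )
            if ident >= params.threshold:
                cl.member_ids.append(sid)
                cl.member_identities.append(ident)
                placed = True
                break
        if not placed:
            clusters.append(
                SpacerCluster(len(clusters), sid, seq, [sid], [1.0])
            )
    return clusters


def write_representatives(clusters: Sequence[SpacerCluster], path) -> None:
    from .seqio import NucleotideSequence, write_fasta

    write_fasta(
        [
            NucleotideSequence(
                cl.representative_id,
                cl.representative_seq,
                f"cluster={cl.cluster_id} size={cl.size}",
            )
            for cl in clusters
        ],
        path,
    )


def write_clstr(clusters: Sequence[SpacerCluster], path) -> None:
    """CD-HIT ``.clstr``-like membership listing."""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(f">Cluster {cl.cluster_id}\n")
            for i, (mid, ident) in enumerate(
                zip(cl.member_ids, cl.member_identities)
            ):
                if mid == cl.representative_id:
                    fh.write(f"{i}\t>{mid} *\n")
                else:
                    fh.write(f"{i}\t>{mid} at {100 * ident:.2f}%\n")


def write_cluster_tsv(clusters: Sequence[SpacerCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_id\tidentity\tis_representative\n")
        for cl in clusters:
            for mid, ident in zip(cl.member_ids, cl.member_identities):
                rep = int(mid == cl.representative_id)
                fh.write(f"{cl.cluster_id}\t{mid}\t{ident:.4f}\t{rep}\n")
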