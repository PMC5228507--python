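"""Spacer-to-virus alignment and the bipartite virus-host network.

Clustered spacers are aligned against a viral genome library with a
seed-and-extend ungapped local aligner (+1 match / -2 mismatch, 11 bp exact
seeds) and Karlin-Altschul E-values; hits at E <= 1e-03 become edges of a
bipartite network whose spacer nodes carry the host-taxon label of the
direct repeat that detected them — the host side of an edge comes only from
that annotation, never from the virus. A 12-column tabular alignment reader
lets genuine BLAST output stand in for the built-in aligner in replication
studies; bit-for-bit NCBI parity is a non-goal.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .detect import NonRedundantSpacer
from .seqio import NucleotideSequence, revcomp

logger = logging.getLogger(__name__)

_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


def karlin_lambda(match: int, mismatch: int) -> float:
    """Positive root of Karlin's equation sum p_i p_j exp(lambda*s_ij) = 1
    for uniform base composition: 1/4 e^(lambda*r) + 3/4 e^(lambda*q) = 1.
    Solved by bisection; for +1/-2 this gives lambda ~ 1.33."""
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 > mismatch")

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lo, hi = 1e-9, 10.0
    if f(hi) < 0:
        raise ValueError("no positive root in bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# standard published K for the +1/-2 ungapped nucleotide scoring pair
_K_PLUS1_MINUS2 = 0.621


@dataclass(frozen=True)
class AlignParams:
    """Scoring and statistics of the built-in ungapped aligner."""

    match_reward: int = 1
    mismatch_penalty: int = -2
    seed_length: int = 11
    lam: float = field(default_factory=lambda: karlin_lambda(1, -2))
    kappa: float = _K_PLUS1_MINUS2
    evalue_cutoff: float = 1e-3

    def __post_init__(self) -> None:
        if not self.match_reward > 0 > self.mismatch_penalty:
            raise ValueError("need reward > 0 > penalty")
        if self.seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One spacer-to-virus local alignment (0-based half-open coordinates).

    ``strand`` is the spacer orientation relative to the subject; in ungapped
    mode identities + mismatches equals the aligned length.
    """

    spacer_id: str
    subject_id: str
    spacer_start: int
    spacer_end: int
    subject_start: int
    subject_end: int
    strand: str
    identities: int
    mismatches: int
    score: float
    evalue: float


@dataclass(frozen=True)
class VirusHostEdge:
    """One (spacer, virus) edge of the bipartite interaction network."""

    spacer_id: str
    virus_id: str
    host_taxon: str
    best_evalue: float
    n_hits: int


def evalue(score: float, m: int, n: int, params: AlignParams = AlignParams()) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m <= 0 or n <= 0:
        raise ValueError("search-space dimensions must be positive")
    return params.kappa * m * n * math.exp(-params.lam * score)


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Rolling k-mer integer codes (base 4); windows containing N get -1."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(raw.size, -1, dtype=np.int64)
    for byte, val in _BASE_CODE.items():
        codes[raw == byte] = val
    if raw.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win @ powers
    vals[(win < 0).any(axis=1)] = -1
    return vals


def _best_segment(scores: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring nonempty subarray: (start, end, score); earliest then
    longest on ties, deterministically."""
    best = (-(10 ** 9), 0, 0)  # (score, start, end)
    run_score, run_start = 0, 0
    for i, s in enumerate(scores):
        if run_score <= 0:
            run_score, run_start = int(s), i
        else:
            run_score += int(s)
        if run_score > best[0] or (
            run_score == best[0]
            and (run_start < best[1] or (run_start == best[1] and i + 1 > best[2]))
        ):
            best = (run_score, run_start, i + 1)
    return best[1], best[2], best[0]


SpacerArg = Union[NonRedundantSpacer, NucleotideSequence, tuple]


def _spacer_pairs(spacers: Sequence[SpacerArg]) -> list[tuple[str, str]]:
    out = []
    for sp in spacers:
        if isinstance(sp, tuple):
            out.append((sp[0], sp[1]))
        elif isinstance(sp, NonRedundantSpacer):
            out.append((sp.sequence_id, sp.residues))
        else:
            out.append((sp.id, sp.residues))
    return out


def align_spacers(
    spacers: Sequence[SpacerArg],
    viruses: Sequence[NucleotideSequence],
    params: AlignParams = AlignParams(),
) -> list[AlignmentHit]:
    """Seed-and-extend ungapped alignment of every spacer against the library.

    Every exact shared word of ``seed_length`` nucleates its diagonal; per
    (spacer, subject, strand, diagonal) the maximal-scoring ungapped segment
    is kept. E-values use the summed library length as the database size;
    hits with E <= the cutoff are returned sorted by (spacer_id, evalue).
    """
    if not spacers or not viruses:
        raise ValueError("spacer and virus collections must be nonempty")
    k = params.seed_length
    pairs = _spacer_pairs(spacers)
    n_total = sum(len(v.residues) for v in viruses)

    # seed index over both spacer orientations
    seed_index: dict[int, list[tuple[int, str, int]]] = {}
    oriented: dict[tuple[int, str], np.ndarray] = {}
    lengths: dict[int, int] = {}
    for si, (sid, seq) in enumerate(pairs):
        if len(seq) < k:
            warnings.warn(
                f"spacer {sid!r} is shorter than the seed length {k}; skipped"
            )
            continue
        lengths[si] = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = np.frombuffer(s.encode(), dtype=np.uint8).astype(np.int16)
            oriented[(si, strand)] = arr
            for off, code in enumerate(_kmer_codes(s, k)):
                if code >= 0:
                    seed_index.setdefault(int(code), []).append((si, strand, off))
    if not seed_index:
        return []
    seed_keys = np.fromiter(seed_index.keys(), dtype=np.int64)

    hits: list[AlignmentHit] = []
    for virus in viruses:
        vseq = virus.residues
        varr = np.frombuffer(vseq.encode(), dtype=np.uint8).astype(np.int16)
        vcodes = _kmer_codes(vseq, k)
        if vcodes.size == 0:
            continue
        positions = np.nonzero(np.isin(vcodes, seed_keys))[0]
        done: set[tuple[int, str, int]] = set()
        for p in positions:
            for si, strand, off in seed_index[int(vcodes[p])]:
                diag = int(p) - off
                key = (si, strand, diag)
                if key in done:
                    continue
                done.add(key)
                sarr = oriented[(si, strand)]
                m = sarr.size
                lo = max(0, -diag)
                hi = min(m, varr.size - diag)
                seg = sarr[lo:hi] == varr[lo + diag:hi + diag]
                # N never matches: spacer or subject N scores as mismatch
                seg &= sarr[lo:hi] != ord("N")
                seg &= varr[lo + diag:hi + diag] != ord("N")
                scores = np.where(seg, params.match_reward, params.mismatch_penalty)
                a, b, score = _best_segment(scores)
                ident = int(seg[a:b].sum())
                length = b - a
                E = evalue(score, lengths[si], n_total, params)
                if E > params.evalue_cutoff:
                    continue
                qs, qe = lo + a, lo + b
                if strand == "-":
                    qs, qe = m - qe, m - qs
                hits.append(
                    AlignmentHit(
                        spacer_id=pairs[si][0],
                        subject_id=virus.id,
                        spacer_start=qs,
                        spacer_end=qe,
                        subject_start=diag + lo + a,
                        subject_end=diag + lo + b,
                        strand=strand,
                        identities=ident,
                        mismatches=length - ident,
                        score=float(score),
                        evalue=E,
                    )
                )
    hits.sort(key=lambda h: (h.spacer_id, h.evalue, h.subject_id, h.subject_start))
    return hits


def read_tabular_hits(
    path, params: AlignParams = AlignParams()
) -> tuple[list[AlignmentHit], int]:
    """Read a 12-column tab-separated alignment table.

    Columns: query, subject, %identity, length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore — 1-based inclusive
    coordinates, converted to 0-based half-open; sstart > send encodes the
    minus strand. Rows above the E-value cutoff are dropped; returns
    (hits, n_dropped).
    """
    hits: list[AlignmentHit] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                (qid, sid, pident, length, mism, _gaps,
                 qstart, qend, sstart, send, ev, bits) = fields
                pident, ev, bits = float(pident), float(ev), float(bits)
                length, mism = int(length), int(mism)
                qstart, qend = int(qstart), int(qend)
                sstart, send = int(sstart), int(send)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if ev > params.evalue_cutoff:
                dropped += 1
                continue
            if sstart <= send:
                strand, s0, s1 = "+", sstart - 1, send
            else:
                strand, s0, s1 = "-", send - 1, sstart
            ident = round(pident * length / 100.0)
            hits.append(
                AlignmentHit(
                    spacer_id=qid,
                    subject_id=sid,
                    spacer_start=qstart - 1,
                    spacer_end=qend,
                    subject_start=s0,
                    subject_end=s1,
                    strand=strand,
                    identities=ident,
                    mismatches=mism,
                    score=bits,
                    evalue=ev,
                )
            )
    if dropped:
        logger.info("dropped %d rows above the E-value cutoff", dropped)
    return hits, dropped


def build_network(
    hits: Sequence[AlignmentHit],
    spacer_provenance: Mapping[str, Optional[str]],
) -> list[VirusHostEdge]:
    """Collapse hits into (spacer, virus) edges carrying the host taxon.

    ``spacer_provenance`` maps spacer_id to the host-taxon label of the DR
    query that detected it; a missing label propagates as "unknown". A hit
    referencing a spacer absent from the provenance map is an error.
    """
    grouped: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        if h.spacer_id not in spacer_provenance:
            raise KeyError(f"hit references unknown spacer id {h.spacer_id!r}")
        grouped.setdefault((h.spacer_id, h.subject_id), []).append(h)
    edges = [
        VirusHostEdge(
            spacer_id=sid,
            virus_id=vid,
            host_taxon=spacer_provenance[sid] or "unknown",
            best_evalue=min(h.evalue for h in hs),
            n_hits=len(hs),
        )
        for (sid, vid), hs in grouped.items()
    ]
    edges.sort(key=lambda e: (e.spacer_id, e.virus_id))
    return edges


_SIF_RELATION = "spacer_to_virus"


def write_network(edges: Sequence[VirusHostEdge], basename) -> None:
    """SIF + edge/node attribute TSVs for network tools (Cytoscape-style).

    Node labels are formatted "taxon (id)". An empty network yields an empty
    SIF and headers-only TSVs.
    """
    basename = str(basename)
    with open(basename + ".sif", "w") as fh:
        for e in edges:
            fh.write(f"{e.spacer_id}\t{_SIF_RELATION}\t{e.virus_id}\n")
    with open(basename + ".edges.tsv", "w") as fh:
        fh.write("spacer_id\tvirus_id\thost_taxon\tbest_evalue\tn_hits\n")
        for e in edges:
            fh.write(
                f"{e.spacer_id}\t{e.virus_id}\t{e.host_taxon}\t"
                f"{e.best_evalue:.6g}\t{e.n_hits}\n"
            )
    with open(basename + ".nodes.tsv", "w") as fh:
        fh.write("node_id\tnode_type\tlabel\n")
        seen: set[str] = set()
        for e in edges:
            if e.spacer_id not in seen:
                seen.add(e.spacer_id)
                fh.write(
                    f"{e.spacer_id}\tspacer\t{e.host_taxon} ({e.spacer_id})\n"
                )
        for e in edges:
            if e.virus_id not in seen:
                seen.add(e.virus_id)
                fh.write(f"{e.virus_id}\tvirus\tvirus ({e.virus_id})\n")


def read_network(basename) -> list[VirusHostEdge]:
    """Reconstruct the edge list from the files written by write_network."""
    basename = str(basename)
    sif_pairs = []
    with open(basename + ".sif") as fh:
        for line in fh:
            if line.strip():
                s, _rel, v = line.rstrip("\n").split("\t")
                sif_pairs.append((s, v))
    edges = []
    with open(basename + ".edges.tsv") as fh:
        next(fh)
        for line in fh:
            s, v, taxon, ev, n = line.rstrip("\n").split("\t")
            edges.append(VirusHostEdge(s, v, taxon, float(ev), int(n)))
    if sorted(sif_pairs) != sorted((e.spacer_id, e.virus_id) for e in edges):
        raise ValueError(f"{basename}: SIF and edge-attribute files disagree")
    return edges


def to_graph(edges: Sequence[VirusHostEdge]):
    """The same network as a networkx bipartite graph (optional mirror)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.spacer_id, node_type="spacer", host_taxon=e.host_taxon)
        g.add_node(e.virus_id, node_type="virus")
        g.add_edge(
            e.spacer_id, e.virus_id,
            best_evalue=e.best_evalue, n_hits=e.n_hits,
        )
    return g


def write_graphml(edges: Sequence[VirusHostEdge], path) -> None:
    import networkx as nx

    nx.write_graphml(to_graph(edges), str(path))
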