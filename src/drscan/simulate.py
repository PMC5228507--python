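"""Synthetic metagenome generator with exact planted truth.

Emulates the study conditions the detection pipeline targets: pyrosequencing-
era read sets (~450-520 bp single-end reads), a library of random viral
genomes, and reads carrying planted CRISPR array fragments — direct-repeat
copies mutated by an exact, recorded number of edits, flanking spacers
excised from the simulated viruses at recorded coordinates — on a background
of repeat-free random reads. Every artifact is a pure function of
(parameters, seed), and the truth manifest is constructed to be well-posed:
each planted repeat copy is re-sampled until its span is the unique best
approximate occurrence in its neighborhood, so detection scores measure the
detector and not generator ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .detect import NonRedundantSpacer
from .match import levenshtein
from .seqio import DRQuery, NucleotideSequence, revcomp

_BASES = "ACGT"

# neighborhood half-width for the planted-span uniqueness audit; covers all
# alternative spans of a <=3-edit occurrence shifted off the planted one
_AUDIT_PAD = 6


@dataclass(frozen=True)
class SimParams:
    """Generator knobs; defaults emulate the study conditions.

    Read lengths follow a truncated normal (mean 480 bp, sd 40, floor
    100 bp), matching the 429-523 bp average read lengths of the
    pyrosequencing runs this pipeline targets. Spacers are 26-50 bp, the
    empirical CRISPR spacer range; DR copies carry an exact number of edits
    drawn uniformly from [0, dr_mutation_edits]. Background reads (and array
    flanks) are rejection-sampled to contain no DR occurrence within
    ``background_rejection_edits``, so detection precision has a clean
    denominator.
    """

    seed: int = 0
    n_viruses: int = 100
    virus_length: tuple[int, int] = (5_000, 50_000)
    n_array_reads: int = 50
    n_background_reads: int = 950
    read_length_mean: float = 480.0
    read_length_sd: float = 40.0
    read_length_min: int = 100
    dr_mutation_edits: int = 3
    spacer_length: tuple[int, int] = (26, 50)
    spacers_per_array: tuple[int, int] = (1, 3)
    background_gc: float = 0.5
    n_dr_queries: int = 29
    dr_length: tuple[int, int] = (23, 47)
    plant_reverse_prob: float = 0.5
    background_rejection_edits: int = 3
    # detection geometry used only to label detectability in the truth
    detect_min_spacer: int = 26
    detect_max_spacer: int = 60

    def __post_init__(self) -> None:
        if min(self.n_viruses, 1) < 1:
            raise ValueError("n_viruses must be >= 1")
        if self.n_array_reads < 0 or self.n_background_reads < 0:
            raise ValueError("read counts must be >= 0")
        if self.dr_mutation_edits < 0:
            raise ValueError("dr_mutation_edits must be >= 0")
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must be in (0, 1)")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted spacer (a multi-spacer array read emits
    one row per spacer, sharing the read id)."""

    read_id: str
    query_id: str
    strand: str
    spacer: str  # residues in query-DR orientation
    virus_id: str
    virus_start: int
    virus_end: int
    read_start: int  # spacer interval in final read coordinates
    read_end: int
    edits_left: int
    edits_right: int
    detectable: bool

    @property
    def max_edits(self) -> int:
        return max(self.edits_left, self.edits_right)


@dataclass
class SimResult:
    reads: list[NucleotideSequence]
    viruses: list[NucleotideSequence]
    queries: list[DRQuery]
    truth: list[PlantedTruth]
    params: SimParams


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def simulate_viruses(
    params: SimParams, rng: np.random.Generator
) -> list[NucleotideSequence]:
    """I.i.d. random genomes standing in for a viral genome library."""
    lo, hi = params.virus_length
    viruses = []
    for i in range(params.n_viruses):
        length = int(rng.integers(lo, hi + 1))
        viruses.append(
            NucleotideSequence(f"virus_{i:04d}", _random_seq(rng, length))
        )
    return viruses


def simulate_dr_queries(
    params: SimParams, rng: np.random.Generator
) -> list[DRQuery]:
    """Random direct-repeat queries with synthetic host-taxon labels.

    Queries are redrawn until they are mutually distant and far from their
    own reverse complement (> 2 * d_max + 2 edits), so planted arrays have an
    unambiguous owning query — real DR sets of closely related taxa need not
    satisfy this.
    """
    margin = 2 * params.background_rejection_edits + 2
    queries: list[DRQuery] = []
    while len(queries) < params.n_dr_queries:
        length = int(rng.integers(params.dr_length[0], params.dr_length[1] + 1))
        seq = _random_seq(rng, length)
        if levenshtein(seq, revcomp(seq)) <= margin:
            continue
        if any(
            min(levenshtein(seq, q.residues), levenshtein(seq, revcomp(q.residues)))
            <= margin
            for q in queries
        ):
            continue
        i = len(queries)
        queries.append(DRQuery(f"dr_{i:03d}", seq, f"taxon_{i:03d}"))
    return queries


def _contains_query(
    seq: str, queries: Sequence[DRQuery], max_edits: int
) -> bool:
    """True if any query (either strand) occurs in seq within max_edits."""
    for q in queries:
        for variant in (q.residues, revcomp(q.residues)):
            if len(seq) < len(variant) - max_edits:
                continue
            res = edlib.align(variant, seq, mode="HW", task="distance", k=max_edits)
            if res["editDistance"] != -1:
                return True
    return False


def _mutate_exact(seq: str, n_edits: int, rng: np.random.Generator) -> str:
    """Apply random edits until the result is at distance exactly n_edits."""
    if n_edits == 0:
        return seq
    for _ in range(200):
        s = list(seq)
        for _ in range(n_edits):
            op = rng.choice(["sub", "ins", "del"])
            if op == "del" and len(s) > 1:
                del s[int(rng.integers(len(s)))]
            elif op == "ins":
                s.insert(int(rng.integers(len(s) + 1)), _BASES[rng.integers(4)])
            else:
                pos = int(rng.integers(len(s)))
                s[pos] = rng.choice([b for b in _BASES if b != s[pos]])
        mutated = "".join(s)
        if levenshtein(mutated, seq) == n_edits:
            return mutated
    raise RuntimeError(f"could not realize an exact {n_edits}-edit mutation")


def _span_is_unique(read: str, query: str, start: int, end: int, edits: int) -> bool:
    """Audit: the planted span is the strict best occurrence among all
    overlapping candidate spans in its neighborhood (checked with edlib,
    independently of the detection DP)."""
    for i in range(max(0, start - _AUDIT_PAD), start + _AUDIT_PAD + 1):
        for j in range(end - _AUDIT_PAD, min(len(read), end + _AUDIT_PAD) + 1):
            if j <= i or (i, j) == (start, end):
                continue
            if levenshtein(read[i:j], query) <= edits:
                return False
    return True


def _draw_read_length(params: SimParams, rng: np.random.Generator) -> int:
    while True:
        length = int(round(rng.normal(params.read_length_mean, params.read_length_sd)))
        if length >= params.read_length_min:
            return length


def simulate_array_read(
    queries: Sequence[DRQuery],
    viruses: Sequence[NucleotideSequence],
    params: SimParams,
    rng: np.random.Generator,
    read_id: str = "array_read",
) -> tuple[NucleotideSequence, list[PlantedTruth]]:
    """One read carrying a planted DR-spacer-DR(-spacer-DR...) array.

    Spacers are excised from the viruses at recorded coordinates; each DR
    copy is an exactly-e-edit mutant of the chosen query (e drawn uniformly
    in [0, dr_mutation_edits]), so detectability at every edit budget is
    knowable a priori. The whole array always lies inside the read.
    """
    if not queries or not viruses:
        raise ValueError("query and virus sets must be nonempty")
    if params.spacer_length[0] > params.spacer_length[1]:
        raise ValueError("bad spacer length range")

    query = queries[int(rng.integers(len(queries)))]
    n_spacers = int(
        rng.integers(params.spacers_per_array[0], params.spacers_per_array[1] + 1)
    )
    strand = "-" if rng.random() < params.plant_reverse_prob else "+"

    for _attempt in range(100):
        # spacers excised from viruses
        spacer_info = []
        for _ in range(n_spacers):
            virus = viruses[int(rng.integers(len(viruses)))]
            length = int(
                rng.integers(params.spacer_length[0], params.spacer_length[1] + 1)
            )
            if len(virus.residues) <= length:
                raise ValueError("spacer range incompatible with virus length")
            pos = int(rng.integers(len(virus.residues) - length + 1))
            spacer_info.append(
                (virus.id, pos, pos + length, virus.residues[pos:pos + length])
            )
        # mutated DR copies
        copies = []
        for _ in range(n_spacers + 1):
            e = int(rng.integers(0, params.dr_mutation_edits + 1))
            copies.append((e, _mutate_exact(query.residues, e, rng)))

        parts = [copies[0][1]]
        for (_, _, _, sp), (e, cp) in zip(spacer_info, copies[1:]):
            parts.append(sp)
            parts.append(cp)
        array = "".join(parts)

        read_len = max(_draw_read_length(params, rng), len(array))
        flank_total = read_len - len(array)
        left_len = int(rng.integers(flank_total + 1))
        right_len = flank_total - left_len
        left = _draw_clean_flank(left_len, queries, params, rng)
        right = _draw_clean_flank(right_len, queries, params, rng)
        read_fwd = left + array + right

        # copy spans in forward (array) orientation
        spans = []
        pos = left_len
        for i, (e, cp) in enumerate(copies):
            spans.append((pos, pos + len(cp), e))
            pos += len(cp)
            if i < n_spacers:
                pos += len(spacer_info[i][3])
        if not all(
            _span_is_unique(read_fwd, query.residues, s, t, e) for s, t, e in spans
        ):
            continue  # ambiguous planting; redraw mutations and flanks

        if strand == "-":
            read_seq = revcomp(read_fwd)
            L = len(read_seq)
            flip = lambda a, b: (L - b, L - a)  # noqa: E731
        else:
            read_seq = read_fwd
            flip = lambda a, b: (a, b)  # noqa: E731

        truths = []
        pos = left_len + len(copies[0][1])
        for i, (vid, vs, ve, sp) in enumerate(spacer_info):
            s_start, s_end = pos, pos + len(sp)
            rs, re_ = flip(s_start, s_end)
            gap_ok = (
                params.detect_min_spacer <= len(sp) <= params.detect_max_spacer
            )
            truths.append(
                PlantedTruth(
                    read_id=read_id,
                    query_id=query.id,
                    strand=strand,
                    spacer=sp,
                    virus_id=vid,
                    virus_start=vs,
                    virus_end=ve,
                    read_start=rs,
                    read_end=re_,
                    edits_left=copies[i][0],
                    edits_right=copies[i + 1][0],
                    detectable=gap_ok,
                )
            )
            pos = s_end + len(copies[i + 1][1])
        return NucleotideSequence(read_id, read_seq), truths
    raise RuntimeError("failed to plant an unambiguous array in 100 attempts")


def _draw_clean_flank(
    length: int,
    queries: Sequence[DRQuery],
    params: SimParams,
    rng: np.random.Generator,
) -> str:
    if length == 0:
        return ""
    for _ in range(100):
        flank = _random_seq(rng, length, params.background_gc)
        if not _contains_query(flank, queries, params.background_rejection_edits):
            return flank
    raise RuntimeError("failed to draw a repeat-free flank")


def simulate_metagenome(
    params: SimParams,
    queries: Optional[Sequence[DRQuery]] = None,
    viruses: Optional[Sequence[NucleotideSequence]] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimResult:
    """A shuffled mixture of planted-array reads and repeat-free background.

    Fixed (params, seed) gives byte-identical outputs. Queries and viruses
    are generated when not supplied.
    """
    rng = rng or np.random.default_rng(params.seed)
    queries = list(queries) if queries is not None else simulate_dr_queries(params, rng)
    viruses = (
        list(viruses) if viruses is not None else simulate_viruses(params, rng)
    )

    entries: list[tuple[NucleotideSequence, list[PlantedTruth]]] = []
    for i in range(params.n_array_reads):
        read, truths = simulate_array_read(
            queries, viruses, params, rng, read_id=f"planted_{i:05d}"
        )
        entries.append((read, truths))
    for _ in range(params.n_background_reads):
        length = _draw_read_length(params, rng)
        for _ in range(100):
            seq = _random_seq(rng, length, params.background_gc)
            if not _contains_query(seq, queries, params.background_rejection_edits):
                break
        else:
            raise RuntimeError("failed to draw a repeat-free background read")
        entries.append((NucleotideSequence("bg", seq), []))

    order = rng.permutation(len(entries))
    reads, truth = [], []
    for new_idx, old_idx in enumerate(order):
        read, truths = entries[int(old_idx)]
        new_id = f"read_{new_idx:06d}"
        reads.append(NucleotideSequence(new_id, read.residues, read.id))
        for t in truths:
            truth.append(
                PlantedTruth(
                    read_id=new_id, query_id=t.query_id, strand=t.strand,
                    spacer=t.spacer, virus_id=t.virus_id,
                    virus_start=t.virus_start, virus_end=t.virus_end,
                    read_start=t.read_start, read_end=t.read_end,
                    edits_left=t.edits_left, edits_right=t.edits_right,
                    detectable=t.detectable,
                )
            )
    truth.sort(key=lambda t: (t.read_id, t.read_start))
    return SimResult(reads, viruses, list(queries), truth, params)


TRUTH_COLUMNS = [
    "read_id", "query_id", "strand", "spacer", "virus_id", "virus_start",
    "virus_end", "read_start", "read_end", "edits_left", "edits_right",
    "detectable",
]


def write_truth(truth: Sequence[PlantedTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            row = [getattr(t, c) for c in TRUTH_COLUMNS]
            row[-1] = int(row[-1])
            fh.write("\t".join(map(str, row)) + "\n")


def read_truth(path) -> list[PlantedTruth]:
    truth = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth manifest columns")
        for line in fh:
            vals = dict(zip(TRUTH_COLUMNS, line.rstrip("\n").split("\t")))
            for c in ("virus_start", "virus_end", "read_start", "read_end",
                      "edits_left", "edits_right"):
                vals[c] = int(vals[c])
            vals["detectable"] = bool(int(vals["detectable"]))
            truth.append(PlantedTruth(**vals))
    return truth


def write_params(params: SimParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(params), fh, indent=2, default=list)
        fh.write("\n")


@dataclass(frozen=True)
class DetectionScore:
    """Recall/precision of a detection run against the planted truth."""

    recall: float
    precision: float
    n_detectable: int
    n_recovered: int
    n_detected: int
    n_true_positive: int

    @property
    def no_detections(self) -> bool:
        return self.n_detected == 0


def score_detection(
    truth: Sequence[PlantedTruth],
    detected: Sequence[NonRedundantSpacer],
    d_max: int,
    read_ids: Optional[set[str]] = None,
) -> tuple[DetectionScore, list[dict]]:
    """Score detected spacers against the truth manifest at one edit budget.

    A planting counts as recovered when some detected spacer has exactly its
    residues and traces (by provenance) to its read. The denominator is the
    plantings detectable at this budget: geometry admissible and both
    flanking copies within d_max edits. Precision is the fraction of
    detected spacers tracing to any planting; with zero detections precision
    is reported as 1.0 and flagged via ``no_detections``.
    """
    if read_ids is not None:
        unknown = {t.read_id for t in truth} - read_ids
        if unknown:
            raise ValueError(
                f"truth references reads absent from the read set: "
                f"{sorted(unknown)[:3]}..."
            )
    detected_keys = {
        (occ.read_id, nr.residues) for nr in detected for occ in nr.occurrences
    }
    planted_keys = {(t.read_id, t.spacer) for t in truth}

    rows = []
    n_detectable = n_recovered = 0
    for t in truth:
        in_budget = t.detectable and t.max_edits <= d_max
        recovered = (t.read_id, t.spacer) in detected_keys
        if in_budget:
            n_detectable += 1
            if recovered:
                n_recovered += 1
        rows.append(
            {
                "read_id": t.read_id,
                "query_id": t.query_id,
                "detectable_at_budget": in_budget,
                "recovered": recovered,
            }
        )

    n_detected = len(detected)
    n_tp = sum(
        1
        for nr in detected
        if any((occ.read_id, nr.residues) in planted_keys for occ in nr.occurrences)
    )
    recall = n_recovered / n_detectable if n_detectable else 1.0
    precision = n_tp / n_detected if n_detected else 1.0
    return (
        DetectionScore(recall, precision, n_detectable, n_recovered, n_detected, n_tp),
        rows,
    )
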