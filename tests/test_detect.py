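import numpy as np
import pytest

from conftest import random_dna
from drscan.detect import (
    call_spacers,
    detect_spacers,
    recruit_reads,
    shared_spacers,
    spacer_rate,
    write_spacer_fasta,
)
from drscan.match import DetectionParams, chain_nonoverlapping, find_occurrences
from drscan.seqio import DRQuery, NucleotideSequence, revcomp
from oracles import lev_edlib

Q = "ACGGTTACCAGGATCCTTAAGCGTACGGTA"  # 30 bp


@pytest.fixture
def query():
    return DRQuery("drq", Q, "Haloquadratum")


def array_read(read_id, query_seq, spacers, flanks=("", ""), reverse=False):
    parts = [flanks[0], query_seq]
    for sp in spacers:
        parts += [sp, query_seq]
    parts.append(flanks[1])
    seq = "".join(parts)
    if reverse:
        seq = revcomp(seq)
    return NucleotideSequence(read_id, seq)


class TestRecruitReads:
    def test_planted_truth(self, rng, query):
        reads = [
            NucleotideSequence(f"bg{i}", random_dna(rng, 150)) for i in range(7)
        ]
        spacer = random_dna(rng, 30)
        reads += [array_read(f"arr{i}", Q, [spacer]) for i in range(3)]
        recruited = recruit_reads(reads, [query], DetectionParams(d_max=0))
        assert [r.id for r, _ in recruited] == ["arr0", "arr1", "arr2"]

    def test_budget_exhausted(self, rng, query):
        mutated = "T" + Q[1:] if Q[0] != "T" else "A" + Q[1:]
        reads = [array_read("arr", mutated, [random_dna(rng, 30)])]
        assert recruit_reads(reads, [query], DetectionParams(d_max=0)) == []
        assert len(recruit_reads(reads, [query], DetectionParams(d_max=1))) == 1

    def test_empty_read_set_is_an_error(self, query):
        with pytest.raises(ValueError):
            recruit_reads([], [query])

    def test_recruitment_nondecreasing_in_budget(self, small_sim):
        counts = []
        for d in range(4):
            recruited = recruit_reads(
                small_sim.reads, small_sim.queries, DetectionParams(d_max=d)
            )
            counts.append(len(recruited))
        assert counts == sorted(counts)


class TestCallSpacers:
    def _spacers(self, read, query, params=None):
        params = params or DetectionParams()
        ms = chain_nonoverlapping(find_occurrences(read, [query], params))
        return call_spacers(read, ms, params)

    def test_canonical_array_fragment(self, rng, query):
        sp = random_dna(rng, 30)
        out = self._spacers(array_read("r", Q, [sp]), query)
        assert [s.residues for s in out] == [sp]
        assert out[0].start == len(Q) and out[0].end == len(Q) + 30

    def test_two_spacer_array_yields_two(self, rng, query):
        s1, s2 = random_dna(rng, 30), random_dna(rng, 40)
        out = self._spacers(array_read("r", Q, [s1, s2]), query)
        assert [s.residues for s in out] == [s1, s2]

    def test_gap_above_max_spacer_rejected(self, rng, query):
        out = self._spacers(
            array_read("r", Q, [random_dna(rng, 70)]),
            query,
            DetectionParams(max_spacer=60),
        )
        assert out == []

    def test_minus_strand_spacer_reoriented(self, rng, query):
        sp = random_dna(rng, 30)
        out = self._spacers(array_read("r", Q, [sp], reverse=True), query)
        assert [s.residues for s in out] == [sp]
        assert out[0].strand == "-"

    def test_cross_query_flanks_are_not_spacers(self, rng):
        q1 = DRQuery("q1", Q)
        q2 = DRQuery("q2", random_dna(rng, 30))
        read = NucleotideSequence("r", Q + random_dna(rng, 30) + q2.residues)
        params = DetectionParams(d_max=0)
        ms = chain_nonoverlapping(find_occurrences(read, [q1, q2], params))
        assert len(ms) == 2
        assert call_spacers(read, ms, params) == []


class TestDetectSpacers:
    def test_duplicate_collapse_retains_provenance(self, rng, query):
        sp = random_dna(rng, 30)
        reads = [array_read(f"r{i}", Q, [sp]) for i in range(5)]
        out = detect_spacers(reads, [query], DetectionParams(d_max=0))
        assert len(out) == 1
        assert out[0].n_occurrences == 5
        assert sorted(o.read_id for o in out[0].occurrences) == [
            f"r{i}" for i in range(5)
        ]

    def test_random_background_outputs_all_audit_clean(self, rng, query):
        reads = [
            NucleotideSequence(f"bg{i}", random_dna(rng, 300)) for i in range(200)
        ]
        params = DetectionParams(d_max=0)
        out = detect_spacers(reads, [query], params)
        # whatever is emitted must re-verify against the query by direct DP
        for nr in out:
            for occ in nr.occurrences:
                read = next(r for r in reads if r.id == occ.read_id)
                q = Q if occ.strand == "+" else revcomp(Q)
                left = read.residues[occ.left_dr.start:occ.left_dr.end]
                right = read.residues[occ.right_dr.start:occ.right_dr.end]
                assert lev_edlib(left, q) <= params.d_max
                assert lev_edlib(right, q) <= params.d_max

    def test_higher_budget_superset(self, small_sim):
        seqs = {}
        for d in (0, 3):
            out = detect_spacers(
                small_sim.reads, small_sim.queries, DetectionParams(d_max=d)
            )
            seqs[d] = {nr.residues for nr in out}
        assert seqs[0] <= seqs[3]

    def test_byte_identical_reruns(self, tmp_path, small_sim):
        paths = []
        for i in (1, 2):
            out = detect_spacers(
                small_sim.reads, small_sim.queries, DetectionParams(d_max=3)
            )
            p = tmp_path / f"run{i}.fasta"
            write_spacer_fasta(out, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestSharedSpacers:
    def test_disjoint_sets(self):
        n, shared = shared_spacers(["ACGTAACC"], ["GGTTTGCA"])
        assert (n, shared) == (0, [])

    def test_strand_insensitive_contract(self):
        s = "ACGGTTACCAGGATCC"
        assert shared_spacers([s], [revcomp(s)])[0] == 1
        assert shared_spacers([s], [revcomp(s)], strand_insensitive=False)[0] == 0

    def test_bounded_by_smaller_set(self, rng):
        a = [random_dna(rng, 30) for _ in range(10)]
        b = a[:4] + [random_dna(rng, 30) for _ in range(2)]
        assert shared_spacers(a, b)[0] <= min(len(set(a)), len(set(b)))


class TestSpacerRate:
    def test_study_scale_values(self):
        # 9 spacers in 1.5M reads; 80 spacers in 0.971M reads
        assert spacer_rate(9, 1_500_000) == pytest.approx(6.0)
        assert spacer_rate(80, 971_000) == pytest.approx(82.38929, abs=1e-4)

    def test_zero_spacers(self):
        assert spacer_rate(0, 10) == 0.0

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError):
            spacer_rate(5, 0)
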