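import numpy as np
import pytest

import edlib
from drscan.detect import detect_spacers
from drscan.match import DetectionParams
from drscan.seqio import revcomp
from drscan.simulate import (
    PlantedTruth,
    SimParams,
    read_truth,
    score_detection,
    simulate_array_read,
    simulate_dr_queries,
    simulate_metagenome,
    simulate_viruses,
    write_truth,
)
from oracles import lev_edlib


def small_params(**kw):
    base = dict(
        seed=3,
        n_viruses=5,
        virus_length=(2_000, 5_000),
        n_array_reads=6,
        n_background_reads=20,
        n_dr_queries=3,
        spacers_per_array=(1, 2),
    )
    base.update(kw)
    return SimParams(**base)


class TestSimulateViruses:
    def test_deterministic_for_fixed_seed(self):
        p = small_params()
        v1 = simulate_viruses(p, np.random.default_rng(7))
        v2 = simulate_viruses(p, np.random.default_rng(7))
        assert [(a.id, a.residues) for a in v1] == [(b.id, b.residues) for b in v2]

    def test_lengths_within_range(self):
        p = small_params(n_viruses=20)
        for v in simulate_viruses(p, np.random.default_rng(1)):
            assert p.virus_length[0] <= len(v.residues) <= p.virus_length[1]

    def test_gc_within_binomial_bound(self):
        p = small_params(n_viruses=3, virus_length=(20_000, 20_000))
        viruses = simulate_viruses(p, np.random.default_rng(2))
        for v in viruses:
            n = len(v.residues)
            gc = sum(c in "GC" for c in v.residues)
            sd = np.sqrt(n * 0.25)
            assert abs(gc - 0.5 * n) < 3 * sd * 2  # 3 sd on the binomial count


class TestSimulateArrayRead:
    def test_zero_edit_copies_are_exact(self):
        p = small_params(dr_mutation_edits=0, plant_reverse_prob=0.0)
        rng = np.random.default_rng(5)
        queries = simulate_dr_queries(p, rng)
        viruses = simulate_viruses(p, rng)
        read, truths = simulate_array_read(queries, viruses, p, rng)
        q = next(x for x in queries if x.id == truths[0].query_id)
        for t in truths:
            left = read.residues[t.read_start - len(q.residues):t.read_start]
            right = read.residues[t.read_end:t.read_end + len(q.residues)]
            assert left == q.residues
            assert right == q.residues

    def test_truth_spacer_matches_virus_substring(self):
        p = small_params()
        rng = np.random.default_rng(9)
        queries = simulate_dr_queries(p, rng)
        viruses = {v.id: v for v in simulate_viruses(p, rng)}
        for _ in range(10):
            read, truths = simulate_array_read(
                queries, list(viruses.values()), p, rng
            )
            for t in truths:
                assert (
                    viruses[t.virus_id].residues[t.virus_start:t.virus_end]
                    == t.spacer
                )
                in_read = read.residues[t.read_start:t.read_end]
                if t.strand == "-":
                    in_read = revcomp(in_read)
                assert in_read == t.spacer

    def test_recorded_edit_counts_reverify_by_dp(self):
        """The DR copy adjacent to each planted spacer matches its query at
        exactly the recorded edit count (checked via windowed edlib)."""
        p = small_params(n_dr_queries=2)
        rng = np.random.default_rng(13)
        queries = simulate_dr_queries(p, rng)
        viruses = simulate_viruses(p, rng)
        for _ in range(15):
            read, truths = simulate_array_read(queries, viruses, p, rng)
            q = next(x for x in queries if x.id == truths[0].query_id)
            qseq = q.residues if truths[0].strand == "+" else revcomp(q.residues)
            for t in truths:
                eL = t.edits_left if t.strand == "+" else t.edits_right
                eR = t.edits_right if t.strand == "+" else t.edits_left
                pad = 4
                left_win = read.residues[
                    max(0, t.read_start - len(qseq) - pad):t.read_start
                ]
                right_win = read.residues[t.read_end:t.read_end + len(qseq) + pad]
                dL = edlib.align(qseq, left_win, mode="HW", task="distance")[
                    "editDistance"
                ]
                dR = edlib.align(qseq, right_win, mode="HW", task="distance")[
                    "editDistance"
                ]
                assert dL == eL
                assert dR == eR


class TestSimulateMetagenome:
    def test_counts_and_shuffling(self):
        p = small_params(spacers_per_array=(1, 1))
        result = simulate_metagenome(p)
        assert len(result.reads) == p.n_array_reads + p.n_background_reads
        assert len(result.truth) == p.n_array_reads
        truth_ids = {t.read_id for t in result.truth}
        assert truth_ids <= {r.id for r in result.reads}

    def test_fixed_seed_byte_identical(self):
        p = small_params()
        r1 = simulate_metagenome(p)
        r2 = simulate_metagenome(p)
        assert [(a.id, a.residues) for a in r1.reads] == [
            (b.id, b.residues) for b in r2.reads
        ]
        assert r1.truth == r2.truth

    def test_different_seeds_differ(self):
        r1 = simulate_metagenome(small_params(seed=3))
        r2 = simulate_metagenome(small_params(seed=4))
        assert [a.residues for a in r1.reads] != [b.residues for b in r2.reads]

    def test_mean_read_length_near_configured(self):
        p = small_params(n_array_reads=0, n_background_reads=120)
        result = simulate_metagenome(p)
        lengths = np.array([len(r.residues) for r in result.reads])
        se = p.read_length_sd / np.sqrt(len(lengths))
        assert abs(lengths.mean() - p.read_length_mean) < 4 * se

    def test_background_reads_are_repeat_free(self, small_sim):
        truth_reads = {t.read_id for t in small_sim.truth}
        background = [r for r in small_sim.reads if r.id not in truth_reads]
        for read in background[:10]:
            for q in small_sim.queries:
                for variant in (q.residues, revcomp(q.residues)):
                    res = edlib.align(
                        variant, read.residues, mode="HW", task="distance", k=3
                    )
                    assert res["editDistance"] == -1

    def test_truth_round_trips_through_tsv(self, tmp_path, small_sim):
        p = tmp_path / "truth.tsv"
        write_truth(small_sim.truth, p)
        assert read_truth(p) == small_sim.truth


class TestScoreDetection:
    def test_perfect_detection_on_fixture(self, small_sim):
        detected = detect_spacers(
            small_sim.reads, small_sim.queries, DetectionParams(d_max=3)
        )
        score, rows = score_detection(small_sim.truth, detected, d_max=3)
        assert score.recall == 1.0
        assert score.precision == 1.0
        assert len(rows) == len(small_sim.truth)

    def test_empty_detection_conventions(self, small_sim):
        score, _ = score_detection(small_sim.truth, [], d_max=3)
        assert score.recall == 0.0
        assert score.precision == 1.0 and score.no_detections

    def test_budget_controls_denominator(self, small_sim):
        detected = {
            d: detect_spacers(
                small_sim.reads, small_sim.queries, DetectionParams(d_max=d)
            )
            for d in (0, 3)
        }
        s_low, _ = score_detection(small_sim.truth, detected[0], d_max=0)
        s_high, _ = score_detection(small_sim.truth, detected[3], d_max=3)
        # plantings with >0 edits leave the low-budget denominator entirely
        n_zero_edit = sum(1 for t in small_sim.truth if t.max_edits == 0)
        assert s_low.n_detectable == n_zero_edit
        assert s_high.n_detectable == len(
            [t for t in small_sim.truth if t.detectable]
        )
        assert s_low.recall == 1.0 and s_high.recall == 1.0

    def test_mismatched_read_universe_is_an_error(self, small_sim):
        with pytest.raises(ValueError, match="absent"):
            score_detection(
                small_sim.truth, [], d_max=3, read_ids={"not_a_read"}
            )
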