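import numpy as np
import pytest

from drscan.seqio import DRQuery, NucleotideSequence
from drscan.simulate import SimParams, simulate_metagenome


def random_dna(rng: np.random.Generator, length: int, with_n: float = 0.0) -> str:
    alphabet = "ACGT"
    seq = rng.choice(list(alphabet), size=length)
    if with_n > 0:
        mask = rng.random(length) < with_n
        seq[mask] = "N"
    return "".join(seq)


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic metagenome shared by pipeline-level tests:
    8 planted array reads on a 40-read repeat-free background, 8 viruses,
    4 DR queries, DR copies mutated by up to 3 exact edits."""
    params = SimParams(
        seed=11,
        n_viruses=8,
        virus_length=(3_000, 8_000),
        n_array_reads=8,
        n_background_reads=40,
        n_dr_queries=4,
        spacers_per_array=(1, 2),
    )
    return simulate_metagenome(params)


def make_read(read_id: str, *parts: str) -> NucleotideSequence:
    return NucleotideSequence(read_id, "".join(parts))


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def dr_query():
    # 30 bp, inside the empirical 23-47 bp DR range
    return DRQuery("drq", "ACGGTTACCAGGATCCTTAAGCGTACGGTA", "Haloquadratum")
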