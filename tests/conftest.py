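import numpy as np
import pytest

from divsel.config import MCMCSchedule, PipelineConfig
from divsel.datatypes import MarkerMatrix
from divsel.simulate import gen_aflp, gen_metadata


@pytest.fixture(scope="session")
def meta12():
    """Default 12-population transect metadata."""
    return gen_metadata(n_pops=12, seed=1)


@pytest.fixture(scope="session")
def neutral_matrix(meta12):
    """700 neutral loci, 12 x 15 individuals, background F_ST 0.02."""
    matrix, truth = gen_aflp(meta12, n_neutral=700, n_selected=0,
                             fst_background=0.02, n_replicates=0, seed=2)
    return matrix, truth


@pytest.fixture(scope="session")
def mixed_matrix(meta12):
    """700 neutral + 30 clinal loci at the default generator settings."""
    matrix, truth = gen_aflp(meta12, n_neutral=700, n_selected=30,
                             fst_background=0.02, n_replicates=0, seed=3)
    return matrix, truth


@pytest.fixture
def toy_matrix():
    """2 populations x 3 individuals, 5 loci — small enough to brute-force."""
    bands = np.array([
        [1, 1, 0, 0, 1],
        [1, 0, 0, 0, 1],
        [1, 1, 0, 1, 1],
        [0, 0, 1, 1, 0],
        [0, 1, 1, 1, 0],
        [0, 0, 1, 0, 0],
    ], dtype=np.int8)
    ids = [f"i{k}" for k in range(6)]
    pop_of = {ids[k]: ("A" if k < 3 else "B") for k in range(6)}
    return MarkerMatrix(individual_ids=ids, locus_ids=list("abcde"),
                        bands=bands, pop_of=pop_of)


@pytest.fixture
def fast_config():
    """Small-but-honest settings for end-to-end runs inside tests."""
    return PipelineConfig(
        n_envelope_sims=20_000,
        n_permutations=499,
        detectors=("fdist", "scan"),
        partition_rules=(("fdist", "scan"),),
        mcmc=MCMCSchedule(iterations=8_000, burn_in=2_000, thinning=10,
                          n_pilot=8, pilot_length=300),
    )
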