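import numpy as np
import pytest

from enhscreen.core import Config
from enhscreen.pipeline import run_pipeline
from enhscreen.simulate import SimulationConfig, make_reference


@pytest.fixture(scope="session")
def default_sim() -> SimulationConfig:
    """The default study conditions: 200 regions, 10 planted hits,
    depletion -1.5 log2, NB dispersion 0.1, 3 replicates, seed 1."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_result(default_sim):
    """One full pipeline run on the default conditions, shared by tests."""
    return run_pipeline(default_sim)


@pytest.fixture(scope="session")
def small_sim() -> SimulationConfig:
    return SimulationConfig(
        seed=7, n_chrom=1, chrom_len_bp=400_000, n_regions=20,
        frac_true_hits=0.25, n_decoy_tus=60, n_lowcount_tus=5,
        n_proteins=100, cohort_n_samples=120)


@pytest.fixture(scope="session")
def small_reference(small_sim):
    return make_reference(small_sim)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
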