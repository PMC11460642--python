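import numpy as np
import pytest

from cogload.cli import RunConfig, run_analyze, run_simulate
from cogload.synth import default_profile, simulate_session

COHORT_SEED = 7
COHORT_N = 6


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small simulated cohort plus its full analysis, shared across tests.

    Simulation and analysis are deterministic in the seed, so session scope
    is safe.
    """
    root = tmp_path_factory.mktemp("cohort")
    config = RunConfig(n_participants=COHORT_N, seed=COHORT_SEED,
                       output_dir=root / "sessions")
    stems = run_simulate(config)
    config_an = RunConfig(n_participants=COHORT_N, seed=COHORT_SEED,
                          output_dir=root / "analysis")
    tables = run_analyze(config_an, stems)
    return {"stems": stems, "tables": tables, "config": config}


@pytest.fixture(scope="session")
def one_session():
    """One simulated session with ground truth, default profile."""
    profile = default_profile(seed=11)
    return simulate_session(profile, fs_hz=500.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
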