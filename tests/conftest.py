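import dataclasses

import numpy as np
import pytest

from hgparcel.synthetic import (
    PhantomConfig,
    make_cohort,
    make_phantom,
    simulate_fingerprints,
    simulate_timeseries,
)
from hgparcel.workbench import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def noise_free_config():
    return PhantomConfig().noise_free()


@pytest.fixture(scope="session")
def default_phantom(default_config):
    return make_phantom(default_config)


@pytest.fixture(scope="session")
def default_subject(default_config, default_phantom):
    """One generated subject: (phantom, fingerprint, timeseries)."""
    rng = np.random.default_rng(7)
    fp = simulate_fingerprints(default_phantom, default_config, rng)
    ts = simulate_timeseries(default_phantom, default_config, rng)
    return default_phantom, fp, ts


@pytest.fixture(scope="session")
def small_run_config():
    """Scaled-down pipeline config for fast workbench tests."""
    phantom = PhantomConfig(
        n_seed_units=120,
        n_outside_vertices=150,
        n_timepoints=400,
        n_streamlines_per_unit=2000,
        rng_seed=11,
    )
    return RunConfig(phantom=phantom, n_subjects=4, n_restarts=5)


@pytest.fixture(scope="session")
def default_run():
    """Full default pipeline run (20 subjects, default noise, seed 0).

    Shared by the acceptance criteria on K selection, label recovery and
    gradient recovery.
    """
    return run_pipeline(RunConfig())


@pytest.fixture(scope="session")
def small_cohort():
    cfg = PhantomConfig(
        n_seed_units=90,
        n_outside_vertices=126,
        n_timepoints=300,
        n_streamlines_per_unit=2000,
        rng_seed=5,
    )
    return make_cohort(6, cfg), cfg


def pytest_configure(config):
    config.addinivalue_line("markers", "slow: long-running acceptance checks")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
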