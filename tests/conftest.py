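import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import asepower as ap

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """Small causal cohort exercised by most unit tests."""
    cfg = ap.SimulationConfig(n_samples=80, n_transcripts=30, seed=101)
    return ap.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_ase(small_cohort):
    return ap.transcript_ase(small_cohort)


@pytest.fixture(scope="session")
def null_cohort():
    """Global-null cohort at the calibration study size (n=100, 200 transcripts)."""
    cfg = ap.SimulationConfig(
        n_samples=100, n_transcripts=200,
        ase_effect=0.0, gte_effect=0.0, causal_fraction=0.0, seed=211,
    )
    return ap.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def headline_cohort():
    """Matched-effect cohort for the power comparison (500 transcripts)."""
    cfg = ap.SimulationConfig(n_transcripts=500, seed=307)
    return ap.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
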