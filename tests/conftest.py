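import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rdnascope.core import PipelineConfig
from rdnascope.simulate import (
    ReadSimParams,
    SpeciesProfile,
    build_landscape,
    simulate_reads,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_profile():
    """Tiny two-element landscape used across module tests."""
    return SpeciesProfile(
        name="mini",
        gene_lengths={"18S": 800, "ITS1": 200, "5.8S": 120, "ITS2": 200, "28S": 1500},
        igs_elements=[("elemA", 400), ("elemB", 250)],
        n_units=6,
        unit_divergence=0.002,
        igs_spacer_len=150,
        flank_len=1200,
    )


@pytest.fixture(scope="session")
def small_truth(small_profile):
    return build_landscape(small_profile, seed=3)


@pytest.fixture(scope="session")
def small_reads(small_truth):
    params = ReadSimParams(
        mode="long", n_reads=40, median_len=3500, sigma=0.2, error_rate=0.0, mean_q=20
    )
    return simulate_reads(small_truth, params, seed=4)
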