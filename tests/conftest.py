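import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    from dtdmc.acquisition import design_bmatrices

    return design_bmatrices(64, b_range=(0.0, 5.0), seed=7)


@pytest.fixture(scope="session")
def full_design():
    """The production-size acquisition: 216 mixed rank-1/rank-2 b-matrices."""
    from dtdmc.acquisition import design_bmatrices

    return design_bmatrices(216, b_range=(0.0, 5.0), seed=11)
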