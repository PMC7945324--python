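import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rnt import BinaryArm, SurvivalData

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def kcsg_arms() -> tuple[BinaryArm, BinaryArm]:
    """Chemoradiation trial, 81/211 control responses vs 90/209 with consolidation."""
    return BinaryArm(211, 81), BinaryArm(209, 90)


@pytest.fixture
def gilt_arms() -> tuple[BinaryArm, BinaryArm]:
    """Second chemoradiation trial: 26/105 control vs 28/96 with consolidation."""
    return BinaryArm(105, 26), BinaryArm(96, 28)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def make_censored_sample(
    rng: np.random.Generator, n: int = 60, scale: float = 2.0, label: str = ""
) -> SurvivalData:
    """Exponential event times with independent uniform censoring (~30%)."""
    t = rng.exponential(scale, n)
    c = rng.uniform(0.5, 2.5 * scale, n)
    return SurvivalData(
        times=np.minimum(t, c), events=(t <= c).astype(int), arm_label=label
    )


@pytest.fixture
def censored_sample(rng) -> SurvivalData:
    return make_censored_sample(rng)
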