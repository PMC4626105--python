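import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from conekinetics import (
    FeedbackParams,
    PoissonParams,
    TimeGrid,
    feedback_response,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: Printed kernel fits: slow and fast cell dim-flash parameters.
SLOW_DIM = PoissonParams(370.0, 0.052)
FAST_DIM = PoissonParams(1100.0, 0.035)
#: Printed strong-flash kernels behind the regulated-response fits.
SLOW_STRONG = PoissonParams(5200.0, 0.052)
FAST_STRONG = PoissonParams(12300.0, 0.035)
#: Printed feedback fits: (kernel, G, delta, expected recovery label).
PHENOTYPES = [
    ("slow-no-delay", SLOW_STRONG, 0.6, 0.0, "single"),
    ("slow-moderate-delay", SLOW_STRONG, 0.6, 0.06, "dual"),
    ("slow-large-delay", SLOW_STRONG, 0.6, 0.1, "oscillatory"),
    ("fast-no-delay", FAST_STRONG, 0.4, 0.0, "single"),
    ("fast-moderate-delay", FAST_STRONG, 0.4, 0.055, "single"),
    ("fast-large-delay", FAST_STRONG, 0.4, 0.1, "oscillatory"),
]


@pytest.fixture
def grid_1s() -> TimeGrid:
    """The 1 s / 1 ms grid used for all model-trace fits."""
    return TimeGrid(0.0, 1e-3, 1000)


@pytest.fixture
def slow_green(grid_1s):
    """Regulated slow-cell response with the dual-recovery parameters."""
    return feedback_response(SLOW_STRONG, FeedbackParams(0.6, 0.06), grid_1s)


def white_noise_like(values: np.ndarray, sigma_frac: float, seed: int):
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sigma_frac * np.max(np.abs(values)), values.shape)
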