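import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nocistat.synthetic import ScenarioConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230326)


@pytest.fixture
def default_config():
    return ScenarioConfig(seed=11)


@pytest.fixture
def quiet_config():
    """Noise-free scenario for deterministic identities."""
    return ScenarioConfig(seed=11, noise_cv=0.0)


def brute_force_line(x, y, w=None):
    """Independent least-squares oracle: explicit normal equations for
    y = a + b*x, optionally weighted.  Returns (slope, intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    sw, sx, sy = w.sum(), (w * x).sum(), (w * y).sum()
    sxx, sxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / det
    intercept = (sy * sxx - sx * sxy) / det
    return slope, intercept
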