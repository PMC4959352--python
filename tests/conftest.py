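import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# 3x3 grid spanning the regimes the model is used in: near-log-series
# (small S/b), geometric (S/b = 1) and bell-shaped (S/b > 1), at weak to
# near-critical birth/death ratios
PARAM_GRID = [
    (bd, sb) for bd in (0.5, 0.9, 0.99) for sb in (0.05, 0.5, 2.0)
]


@pytest.fixture(params=PARAM_GRID, ids=[f"bd{b}-sb{s}" for b, s in PARAM_GRID])
def ratio_pair(request):
    return request.param
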