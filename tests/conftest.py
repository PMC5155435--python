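import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import qsflute as q

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return q.default_params()


@pytest.fixture(scope="session")
def design_with_120h():
    return q.PanFluteDesign(obs_times=(48.0, 72.0, 96.0, 120.0))


@pytest.fixture(scope="session")
def full_ptop(params, design_with_120h):
    """P_top over the full default design, extended to 120 h (dx = 0.1 mm)."""
    return q.run_panflute(params, design_with_120h, dx=0.1)


@pytest.fixture(scope="session")
def full_table(full_ptop):
    return q.score_table(full_ptop, q.default_thresholds())


@pytest.fixture(scope="session")
def small_design():
    return q.PanFluteDesign(heights=(2.0, 4.0), densities=(1e4, 1e5), obs_times=(24.0,))
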