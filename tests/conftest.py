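import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synchrosep import synthdata as sd

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_library():
    return sd.simulate_library(200, 40, seed=7)


@pytest.fixture(scope="session")
def constant_profile():
    return sd.OffsetProfile("constant", 4.0)


@pytest.fixture(scope="session")
def smooth_profile():
    return sd.OffsetProfile("smooth_drift", 4.0, (0.3, 30.0, 5.0))


@pytest.fixture(scope="session")
def dual_run(small_library, constant_profile):
    """Noise-free dual run on the small library (traces + ground truth)."""
    design = sd.RunDesign(
        "dual", 200.0, 200.0, delta_rt_profile=constant_profile,
        noise_cv=0.0, seed=5,
    )
    traces, gt = sd.simulate_run(small_library, design)
    return design, traces, gt


def gaussian_trace(grid, apexes, areas, sigma_min):
    """Analytic multi-Gaussian trace on a given rt grid (test oracle)."""
    y = np.zeros_like(grid)
    for apex, area in zip(apexes, areas):
        y += area / (sigma_min * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((grid - apex) / sigma_min) ** 2
        )
    return y
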