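import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mpsquant as mq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid64():
    return mq.make_polar_grid(64, 32)


@pytest.fixture(scope="session")
def sharp_sector_study(grid64):
    """Noise-free, sharp-edged sector-annulus defect with closed-form extent
    18.75% (90 deg sector over r in [0.5, 1]), fully reversible."""
    spec = mq.DefectSpec(
        center_theta=90.0, center_r=0.75, half_width_theta=45.0,
        half_width_r=0.25, severity=0.6, reversibility=1.0, edge_softness=1e-6,
    )
    stress, rest, truth = mq.simulate_study(grid64, [spec], noise_level=0.0, seed=0)
    return stress, rest, truth


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / (a.sum() + b.sum())
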