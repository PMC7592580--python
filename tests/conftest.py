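import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import limbvol as lv

settings.register_profile(
    "limbvol",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("limbvol")


@pytest.fixture(scope="session")
def taper_limb():
    """Linear taper 3 -> 5 cm over 40 cm: analytic volume pi*40*(9+15+25)/3."""
    return lv.make_limb(40.0, [(0.0, 3.0), (40.0, 5.0)], seed=11)


@pytest.fixture(scope="session")
def arm_limb():
    """Default arm profile: wrist 2.5, mid-forearm 4, elbow 4.5, upper arm 5 cm."""
    return lv.make_limb(
        40.0, [(0.0, 2.5), (15.0, 4.0), (22.0, 4.5), (40.0, 5.0)], seed=7
    )


@pytest.fixture(scope="session")
def dense_cylinder_scan():
    """Noiseless 4-view capture of a cylinder r=4, L=40 (~25k points kept)."""
    limb = lv.make_limb(40.0, 4.0, seed=3)
    scan = lv.sample_point_cloud(limb, lv.NoiseSpec(points_per_view=12500))
    return limb, scan


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
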