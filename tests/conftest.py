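"""Shared fixtures: the reference camera regime and reusable simulations.

All data is generated at test time by the package's own simulator; heavy
stacks are session-scoped so several tests can share one realization.
"""

import numpy as np
import pytest

from emccdcal import CameraParams
from emccdcal import simulator as sim


@pytest.fixture(scope="session")
def base_camera() -> CameraParams:
    """The reference regime: sigma=10 counts, S0=100 counts, phi=3.5
    e-/count (gain varies per test)."""
    return CameraParams(E=10.0, g=25.0, phi=3.5, S0=100.0, sigma=10.0)


@pytest.fixture(scope="session")
def adu_series():
    """Gain-off intensity series for ADU calibration: six log-spaced levels
    of 5-500 photoelectrons, 5000 frames each, with a matching dark stack."""
    shared = CameraParams(E=1.0, g=1.0, phi=3.5, S0=100.0, sigma=10.0)
    return sim.simulate_intensity_series(np.geomspace(5, 500, 6), shared, 5000, seed=1)


@pytest.fixture(scope="session")
def gain_series_small():
    """Five-point gain series at E=10 pe, reduced to 1500 frames per
    set-point for fast likelihood tests."""
    return sim.simulate_gain_series(10.0, [1, 5, 25, 100, 300], 3.5, 1500, seed=2)
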