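import numpy as np
import pytest

from sasglobal.curve_io import SASCurve
from sasglobal.form_factors import sphere_intensity

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def q_grid():
    return np.geomspace(0.01, 0.3, 60)


@pytest.fixture
def sphere_curve(q_grid):
    """Noise-free sphere curve (R = 50 A) with constant sigma."""
    intensity = sphere_intensity(q_grid, 50.0, 2.0e-6)
    sigma = np.full_like(q_grid, 0.01 * intensity[0])
    return SASCurve(q_grid, intensity, sigma, label="sphere50")
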