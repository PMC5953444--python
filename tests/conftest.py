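import numpy as np
import pytest

from eccfit import ParametricEllipse


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eccentric_ellipse():
    """The reference high-eccentricity shape (ε ≈ 0.947418)."""
    return ParametricEllipse(cx=0.0, cy=0.0, a=1.0, b=0.32, theta=0.0)


def random_ellipse(rng, center_scale=5.0):
    a = rng.uniform(0.5, 4.0)
    return ParametricEllipse(
        cx=rng.uniform(-center_scale, center_scale),
        cy=rng.uniform(-center_scale, center_scale),
        a=a,
        b=a * rng.uniform(0.15, 1.0),
        theta=rng.uniform(0.0, np.pi),
    )
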