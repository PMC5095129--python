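import numpy as np
import pytest

from samshape import Contour, SimulationConfig


def parabola_contour(
    height: float = 120.0,
    radius: float = 80.0,
    n_points: int = 201,
    noise_sd: float = 0.0,
    seed: int = 0,
    x_shift: float = 0.0,
    y_shift: float = 0.0,
    orientation: str = "p0_left",
) -> Contour:
    """Sampled parabola y = h(1 - x²/r²), optionally noisy and translated."""
    x = np.linspace(-radius, radius, n_points)
    y = height * (1.0 - x**2 / radius**2)
    pts = np.column_stack([x + x_shift, y + y_shift])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return Contour(points=pts, orientation=orientation)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_config():
    return SimulationConfig(seed=99)
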