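import math

import numpy as np
import pytest

from grapefit.geometry import Ellipse, ellipse_point, rasterize_ellipse_arc
from grapefit.synthetic import SceneSpec, generate_cluster_scene


@pytest.fixture
def canonical_ellipse() -> Ellipse:
    """Axis-aligned 5x3 ellipse at the origin."""
    return Ellipse(0.0, 0.0, 5.0, 3.0, 0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_ellipse(rng: np.random.Generator, aspect_max: float = 5.0) -> Ellipse:
    a = rng.uniform(5.0, 60.0)
    b = a / rng.uniform(1.0, aspect_max)
    return Ellipse(
        rng.uniform(-100.0, 100.0),
        rng.uniform(-100.0, 100.0),
        a,
        b,
        rng.uniform(0.0, math.pi),
    )


def sample_on_ellipse(e: Ellipse, n: int, rng: np.random.Generator) -> np.ndarray:
    return ellipse_point(e, rng.uniform(0.0, 2.0 * math.pi, size=n))


@pytest.fixture
def full_contour() -> np.ndarray:
    """Rasterized full contour of a 60x40 ellipse, as float pixels."""
    e = Ellipse(120.0, 100.0, 60.0, 40.0, 0.5)
    return rasterize_ellipse_arc(e, (0.0, 2.0 * math.pi), (256, 256)).astype(float)


@pytest.fixture
def small_scene():
    """Deterministic 3-grape scene with mild noise."""
    spec = SceneSpec(n_grapes=3, seed=42, dropout_rate=0.05, spurious_rate=0.05)
    edge_map, gt = generate_cluster_scene(spec)
    return spec, edge_map, gt


def theta_close(t1: float, t2: float, tol: float) -> bool:
    """Angular closeness modulo pi."""
    d = abs(t1 - t2) % math.pi
    return min(d, math.pi - d) <= tol
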