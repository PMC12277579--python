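import math

import numpy as np
import pytest


def draw_disk(mask: np.ndarray, cx: int, cy: int, r: int) -> None:
    h, w = mask.shape
    ys, xs = np.mgrid[0:h, 0:w]
    mask |= (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r


def draw_ellipse(mask: np.ndarray, cx: float, cy: float, a: float, b: float,
                 angle: float = 0.0) -> None:
    h, w = mask.shape
    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - cx, ys - cy
    c, s = math.cos(angle), math.sin(angle)
    mask |= ((dx * c + dy * s) / a) ** 2 + ((-dx * s + dy * c) / b) ** 2 <= 1.0


def ellipse_points(cx: float, cy: float, a: float, b: float, angle: float,
                   n: int = 40) -> np.ndarray:
    """Exact (x, y) samples on an ellipse boundary."""
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    c, s = math.cos(angle), math.sin(angle)
    x = cx + a * np.cos(t) * c - b * np.sin(t) * s
    y = cy + a * np.cos(t) * s + b * np.sin(t) * c
    return np.column_stack([x, y])


@pytest.fixture
def two_touching_disks():
    """One compound component: two radius-30 disks with a 1-px raster
    overlap; the circle intersections (true concave notches) sit at
    x = 99.5, y = 60 +- sqrt(900 - 29.5^2)."""
    mask = np.zeros((120, 200), dtype=bool)
    draw_disk(mask, 70, 60, 30)
    draw_disk(mask, 129, 60, 30)
    notch_y = math.sqrt(900.0 - 29.5**2)
    return mask, [(99.5, 60.0 - notch_y), (99.5, 60.0 + notch_y)]


@pytest.fixture
def small_scene():
    """8 grains at reduced canvas, half of them touching, some chipped."""
    from grainsplit import generate_scene

    return generate_scene(n_grains=8, touch_fraction=0.5, chip_probability=0.2,
                          image_size=(700, 520), seed=3,
                          semi_major_range=(40.0, 60.0))
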