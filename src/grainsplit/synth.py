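"""Synthetic grain scenes with ground truth.

Emulates photographs of wheat grains scattered loosely on white paper:
elliptical grains (axis ratio 1.6-2.4) in tan/brown colors with mild pixel
noise on a near-white background, a configurable share of grains placed
tangent to an earlier grain (clusters of 2-4 with a significant number of
contacts), and optional "chips" — small circular bites out of a grain
boundary that produce exactly the spurious concave corners the
ellipse-partition correction exists to absorb.

Everything is drawn from a single seeded generator, so a scene is a pure
function of (parameters, seed).  The default canvas is 1984x1488 pixels,
the working resolution of the counting pipeline; ``generate_scene`` can
also emit 3968x2976 scenes to exercise the 2x downsampling stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_BACKGROUND = np.array([248, 248, 248], dtype=np.float64)


@dataclass
class GrainTruth:
    center: tuple[float, float]          # (x, y) pixels
    semi_axes: tuple[float, float]       # (a major, b minor)
    angle: float                         # radians
    color: tuple[int, int, int]
    chipped: bool = False


@dataclass
class SceneTruth:
    grains: list[GrainTruth]
    true_count: int
    adjacency: list[tuple[int, int]]
    labels: np.ndarray = field(repr=False)   # (H, W) uint16, 0 = background
    seed: int = 0


def _radius(a: float, b: float, angle: float, theta: float) -> float:
    """Ellipse boundary radius along world direction theta."""
    d = theta - angle
    return a * b / math.hypot(b * math.cos(d), a * math.sin(d))


def _ellipse_field(grain: GrainTruth, xs: np.ndarray, ys: np.ndarray,
                   wobble: tuple[float, float, float]) -> np.ndarray:
    """Implicit value: <= 1 inside the (slightly perturbed) ellipse."""
    cx, cy = grain.center
    a, b = grain.semi_axes
    dx, dy = xs - cx, ys - cy
    c, s = math.cos(grain.angle), math.sin(grain.angle)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    amp, lobes, phase = wobble
    if amp > 0:
        phi = np.arctan2(v, u)
        r_eff = 1.0 + amp * np.sin(lobes * phi + phase)
        return (u * u + v * v) / (r_eff * r_eff)
    return u * u + v * v


def _bbox(grain: GrainTruth, shape: tuple[int, int], pad: float = 3.0):
    cx, cy = grain.center
    r = grain.semi_axes[0] * 1.03 + pad
    x0, x1 = max(0, int(cx - r)), min(shape[1], int(cx + r) + 1)
    y0, y1 = max(0, int(cy - r)), min(shape[0], int(cy + r) + 1)
    return x0, x1, y0, y1


def _grain_mask(grain: GrainTruth, shape: tuple[int, int],
                wobble: tuple[float, float, float]) -> tuple[np.ndarray, tuple]:
    x0, x1, y0, y1 = _bbox(grain, shape)
    xs, ys = np.meshgrid(np.arange(x0, x1, dtype=np.float64),
                         np.arange(y0, y1, dtype=np.float64))
    return _ellipse_field(grain, xs, ys, wobble) <= 1.0, (x0, x1, y0, y1)


def _support_gap(g1: GrainTruth, g2: GrainTruth) -> float:
    """Approximate boundary-to-boundary gap along the center line."""
    dx = g2.center[0] - g1.center[0]
    dy = g2.center[1] - g1.center[1]
    d = math.hypot(dx, dy)
    theta = math.atan2(dy, dx)
    return d - _radius(*g1.semi_axes, g1.angle, theta) - _radius(*g2.semi_axes, g2.angle, theta + math.pi)


_CLEAR_T = np.linspace(0.0, 2.0 * math.pi, 96, endpoint=False)


def _pair_clearance(g1: GrainTruth, g2: GrainTruth) -> float:
    """Minimum signed clearance between g1's sampled boundary and g2
    (negative when a boundary sample of g1 penetrates g2).  Tighter than
    the center-line gap for angled elongated pairs."""
    a, b = g1.semi_axes
    c, s = math.cos(g1.angle), math.sin(g1.angle)
    px = g1.center[0] + a * np.cos(_CLEAR_T) * c - b * np.sin(_CLEAR_T) * s
    py = g1.center[1] + a * np.cos(_CLEAR_T) * s + b * np.sin(_CLEAR_T) * c
    dx, dy = px - g2.center[0], py - g2.center[1]
    dist = np.hypot(dx, dy)
    d2 = g2.angle
    theta = np.arctan2(dy, dx) - d2
    a2, b2 = g2.semi_axes
    r2 = a2 * b2 / np.hypot(b2 * np.cos(theta), a2 * np.sin(theta))
    return float((dist - r2).min())


def generate_scene(
    n_grains: int = 20,
    touch_fraction: float = 0.4,
    chip_probability: float = 0.0,
    image_size: tuple[int, int] = (1984, 1488),
    seed: int = 0,
    semi_major_range: tuple[float, float] = (48.0, 72.0),
    aspect_range: tuple[float, float] = (1.6, 2.4),
    wobble_amplitude: float = 0.01,
    noise_sigma: float = 3.0,
    max_retries: int = 500,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a grain scene and its ground truth.

    ``touch_fraction`` of the grains are placed tangent to a previously
    placed grain, forming clusters of 2-4; the rest are isolated.  With
    probability ``chip_probability`` a grain gets a circular bite of radius
    10-25 % of its minor axis, placed away from any contact so recorded
    adjacencies stay valid.  Returns the uint8 RGB image (H, W, 3) and a
    SceneTruth whose ``labels`` image maps every pixel to its grain.
    """
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1")
    if not 0.0 <= touch_fraction <= 1.0:
        raise ValueError("touch_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w, h = image_size
    shape = (h, w)

    # cluster plan: how many grains attach to an earlier one
    n_touch = int(round(touch_fraction * n_grains))
    n_touch = min(n_touch, n_grains - 1)
    cluster_extras: list[int] = []
    budget = n_touch
    while budget > 0:
        extra = int(min(rng.integers(1, 4), budget))
        cluster_extras.append(extra)
        budget -= extra

    def sample_shape() -> tuple[float, float, float]:
        a = float(rng.uniform(*semi_major_range))
        b = a / float(rng.uniform(*aspect_range))
        return a, b, float(rng.uniform(0.0, math.pi))

    def sample_color() -> tuple[int, int, int]:
        base = np.array([172, 132, 86], dtype=np.float64)
        jitter = rng.uniform(-18, 18, size=3)
        return tuple(int(v) for v in np.clip(base + jitter, 0, 255))

    grains: list[GrainTruth] = []
    adjacency: list[tuple[int, int]] = []
    wobbles: list[tuple[float, float, float]] = []

    def new_wobble() -> tuple[float, float, float]:
        return (wobble_amplitude, float(rng.integers(2, 5)),
                float(rng.uniform(0, 2 * math.pi)))

    def fits_everywhere(g: GrainTruth, skip: int = -1, gap: float = 6.0) -> bool:
        cx, cy = g.center
        r = g.semi_axes[0] * 1.05
        if not (r < cx < w - r and r < cy < h - r):
            return False
        for j, other in enumerate(grains):
            if j == skip:
                continue
            # cheap reject on bounding circles, exact sampled check otherwise
            if math.dist(g.center, other.center) >= (g.semi_axes[0]
                                                     + other.semi_axes[0] + gap):
                continue
            if _pair_clearance(g, other) < gap:
                return False
        return True

    def place_free() -> GrainTruth:
        a, b, ang = sample_shape()
        for _ in range(max_retries):
            cx = float(rng.uniform(a + 6, w - a - 6))
            cy = float(rng.uniform(a + 6, h - a - 6))
            g = GrainTruth((cx, cy), (a, b), ang, sample_color())
            if fits_everywhere(g):
                return g
        raise RuntimeError("could not place a grain without overlap; "
                           "reduce n_grains or grain size")

    def place_touching(anchor_idx: int) -> GrainTruth | None:
        anchor = grains[anchor_idx]
        a, b, ang = sample_shape()
        for _ in range(60):
            phi = float(rng.uniform(0, 2 * math.pi))
            d0 = (_radius(*anchor.semi_axes, anchor.angle, phi)
                  + _radius(a, b, ang, phi + math.pi))
            placed = None
            for d in np.arange(d0 + 1.0, d0 - 4.0, -0.5):
                cx = anchor.center[0] + d * math.cos(phi)
                cy = anchor.center[1] + d * math.sin(phi)
                g = GrainTruth((cx, cy), (a, b), ang, sample_color())
                if not fits_everywhere(g, skip=anchor_idx, gap=6.0):
                    break
                gap = _support_gap(g, anchor)
                if gap < -2.5:            # pushed too deep
                    break
                if gap <= -0.5:           # raster tangency with slight overlap
                    placed = g
                    break
            if placed is not None:
                return placed
        return None

    # build clusters, then isolated grains
    order_budget = n_grains
    for extra in cluster_extras:
        seed_grain = place_free()
        grains.append(seed_grain)
        wobbles.append(new_wobble())
        order_budget -= 1
        cluster = [len(grains) - 1]
        placed_extra = 0
        attempts = 0
        while placed_extra < extra and attempts < 20 * extra:
            attempts += 1
            anchor_idx = int(rng.choice(cluster))
            g = place_touching(anchor_idx)
            if g is None:
                continue
            grains.append(g)
            wobbles.append(new_wobble())
            adjacency.append((anchor_idx, len(grains) - 1))
            cluster.append(len(grains) - 1)
            placed_extra += 1
            order_budget -= 1
        if placed_extra < extra:
            raise RuntimeError("could not build a touching cluster; "
                               "scene too crowded")
    for _ in range(order_budget):
        grains.append(place_free())
        wobbles.append(new_wobble())

    # render
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _BACKGROUND
    img += rng.normal(0.0, 2.0, size=img.shape)
    labels = np.zeros(shape, dtype=np.uint16)
    for i, g in enumerate(grains):
        m, (x0, x1, y0, y1) = _grain_mask(g, shape, wobbles[i])
        sub = img[y0:y1, x0:x1]
        noise = rng.normal(0.0, noise_sigma, size=(m.sum(), 3))
        sub[m] = np.clip(np.array(g.color, dtype=np.float64) + noise, 0, 255)
        labels[y0:y1, x0:x1][m] = i + 1

    # chips: circular bites away from any contact
    for i, g in enumerate(grains):
        if rng.uniform() >= chip_probability:
            continue
        a, b = g.semi_axes
        for _ in range(20):
            phi = float(rng.uniform(0, 2 * math.pi))
            r_edge = _radius(a, b, g.angle, phi)
            px = g.center[0] + r_edge * math.cos(phi)
            py = g.center[1] + r_edge * math.sin(phi)
            chip_r = float(rng.uniform(0.10, 0.25)) * (2.0 * b)
            clear = True
            for j, other in enumerate(grains):
                if j == i:
                    continue
                dx, dy = px - other.center[0], py - other.center[1]
                theta = math.atan2(dy, dx)
                edge = _radius(*other.semi_axes, other.angle, theta + math.pi)
                if math.hypot(dx, dy) < edge + chip_r + 4.0:
                    clear = False
                    break
            if not clear:
                continue
            x0 = max(0, int(px - chip_r) - 1)
            x1 = min(w, int(px + chip_r) + 2)
            y0 = max(0, int(py - chip_r) - 1)
            y1 = min(h, int(py + chip_r) + 2)
            xs, ys = np.meshgrid(np.arange(x0, x1, dtype=np.float64),
                                 np.arange(y0, y1, dtype=np.float64))
            bite = ((xs - px) ** 2 + (ys - py) ** 2 <= chip_r**2) \
                & (labels[y0:y1, x0:x1] == i + 1)
            sub = img[y0:y1, x0:x1]
            sub[bite] = np.clip(
                _BACKGROUND + rng.normal(0.0, 2.0, size=(bite.sum(), 3)), 0, 255)
            labels[y0:y1, x0:x1][bite] = 0
            grains[i].chipped = True
            break

    image = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    truth = SceneTruth(grains=grains, true_count=n_grains,
                       adjacency=adjacency, labels=labels, seed=seed)
    return image, truth
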