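"""Ellipse fitting and optimal contour-segment partitioning (cpe counting).

A grain boundary is close to elliptical, so a compound contour containing
several touching grains can be explained by assigning each of its corner-cut
segments to one of a few ellipses.  Every set partition of the segments is
scored by the algebraic least-squares fit error of one ellipse per subset
(residual normalized by pixel count) plus a penalty for subsets whose
individually fitted segment ellipses disagree about the center, normalized
by the smallest semi-minor axis B among the inscribed ellipses.  The
partition with the lowest total error wins and its subset count is the
grain count.  Because merging consistent segments reduces the number of
near-noise-floor residual terms while merging across grains blows the
residual up, the search both absorbs spurious corners (chips, bumps) and
keeps genuinely distinct grains apart.

Geometry here lives in (x, y) = (col, row) coordinates; conic quadratic
form a11 x^2 + 2 a12 xy + a22 y^2 + 2 b1 x + 2 b2 y + 1 = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .contours import (
    Contour,
    CornerSet,
    Segment,
    count_closed_segments,
    detect_corners,
    estimate_count_cp,
    split_segments,
)

log = logging.getLogger(__name__)

_MIN_FIT_POINTS = 5


class ContourTooComplexError(ValueError):
    """Raised when a contour has more segments than the partition search
    is allowed to enumerate."""


@dataclass
class ConicCoefficients:
    a11: float
    a12: float
    a22: float
    b1: float
    b2: float

    def discriminant(self) -> float:
        return self.a11 * self.a22 - self.a12 **2


@dataclass
class EllipseFit:
    """Least-squares conic fit to a pixel set with its geometric reading."""

    coefficients: ConicCoefficients
    center: tuple[float, float]          # (x, y)
    semi_axes: tuple[float, float]       # (major, minor)
    angle: float                         # radians, major axis vs +x, in [0, pi)
    residual: float                      # ||D a + 1||^2 in conditioned coords
    n_points: int
    is_valid_ellipse: bool
    # conditioning frame, kept to evaluate residuals at arbitrary points
    _shift: np.ndarray = field(repr=False, default=None)
    _scale: float = field(repr=False, default=1.0)
    _alpha: np.ndarray = field(repr=False, default=None)

    def algebraic_residuals(self, points: np.ndarray) -> np.ndarray:
        """Conic equation value (conditioned frame) at each (x, y) point;
        zero on the fitted conic."""
        p = (np.asarray(points, dtype=np.float64) - self._shift) / self._scale
        x, y = p[:, 0], p[:, 1]
        a = self._alpha
        return a[0] * x * x + 2 * a[1] * x * y + a[2] * y * y + 2 * a[3] * x + 2 * a[4] * y + 1.0


@dataclass
class Partition:
    subsets: list[list[int]]
    per_subset_fit: list[EllipseFit | None]
    total_error: float
    grain_count: int


def fit_conic_lsq(points: np.ndarray) -> EllipseFit:
    """Fit the conic a11 x^2 + 2 a12 xy + a22 y^2 + 2 b1 x + 2 b2 y = -1
    to (x, y) points by SVD least squares.

    Points are centered on their centroid and isotropically scaled to RMS
    radius sqrt(2) before solving (the raw quadratic system is badly
    conditioned at image-scale coordinates); the conic is mapped back
    afterwards.  Fewer than five distinct points raise; degenerate conics
    (e.g. collinear points) come back with ``is_valid_ellipse`` False.
    """
    pts = np.unique(np.asarray(points, dtype=np.float64).reshape(-1, 2), axis=0)
    if len(pts) < _MIN_FIT_POINTS:
        raise ValueError("underdetermined: need at least 5 distinct points")

    shift = pts.mean(axis=0)
    centered = pts - shift
    rms = math.sqrt(float((centered**2).sum(axis=1).mean()))
    scale = rms / math.sqrt(2.0) if rms > 0 else 1.0
    p = centered / scale
    x, y = p[:, 0], p[:, 1]
    d = np.column_stack([x * x, 2 * x * y, y * y, 2 * x, 2 * y])
    alpha, *_ = np.linalg.lstsq(d, -np.ones(len(p)), rcond=None)
    residual = float(np.sum((d @ alpha + 1.0) ** 2))

    a11, a12, a22, b1, b2 = (float(v) for v in alpha)
    disc = a11 * a22 - a12 * a12
    valid = disc > 1e-12
    center_n = np.zeros(2)
    axes = (0.0, 0.0)
    angle = 0.0
    if valid:
        a2 = np.array([[a11, a12], [a12, a22]])
        center_n = np.linalg.solve(a2, -np.array([b1, b2]))
        v_at_center = 1.0 + b1 * center_n[0] + b2 * center_n[1]
        if (a11 + a22) * v_at_center >= 0:
            valid = False
        else:
            evals, evecs = np.linalg.eigh(a2)
            semi = np.sqrt(-v_at_center / evals)       # same sign guaranteed
            order = np.argsort(semi)[::-1]             # major first
            semi = semi[order]
            major_vec = evecs[:, order[0]]
            angle = math.atan2(major_vec[1], major_vec[0]) % math.pi
            axes = (float(semi[0] * scale), float(semi[1] * scale))
            if not (axes[1] > 0 and np.isfinite(axes[0])):
                valid = False

    # map the conic back to original coordinates
    m = np.array([[a11, a12, b1], [a12, a22, b2], [b1, b2, 1.0]])
    t = np.array([[1 / scale, 0, -shift[0] / scale],
                  [0, 1 / scale, -shift[1] / scale],
                  [0, 0, 1.0]])
    mo = t.T @ m @ t
    if abs(mo[2, 2]) > 1e-300:
        mo = mo / mo[2, 2]
    coeffs = ConicCoefficients(float(mo[0, 0]), float(mo[0, 1]), float(mo[1, 1]),
                               float(mo[0, 2]), float(mo[1, 2]))
    center = tuple(shift + scale * center_n) if valid else (float("nan"), float("nan"))
    return EllipseFit(
        coefficients=coeffs,
        center=(float(center[0]), float(center[1])),
        semi_axes=axes,
        angle=float(angle),
        residual=residual,
        n_points=len(pts),
        is_valid_ellipse=bool(valid),
        _shift=shift,
        _scale=scale,
        _alpha=alpha,
    )


def _segment_xy(seg: Segment) -> np.ndarray:
    return seg.points[:, ::-1].astype(np.float64)     # (row, col) -> (x, y)


class _FitCache:
    """Memoized ellipse fits and pairwise overlaps keyed by frozensets of
    segment indices."""

    def __init__(self, segments: list[Segment], min_pixels: int):
        self.segments = segments
        self.min_pixels = min_pixels
        self._cache: dict[frozenset, EllipseFit | None] = {}
        self._poly: dict[frozenset, object] = {}
        self._overlap: dict[frozenset, float] = {}

    def fit(self, subset: frozenset) -> EllipseFit | None:
        got = self._cache.get(subset)
        if subset in self._cache:
            return got
        pts = np.concatenate([_segment_xy(self.segments[i]) for i in sorted(subset)])
        if len(np.unique(pts, axis=0)) < max(self.min_pixels, _MIN_FIT_POINTS):
            res = None
        else:
            res = fit_conic_lsq(pts)
        self._cache[subset] = res
        return res

    def _polygon(self, subset: frozenset):
        if subset not in self._poly:
            self._poly[subset] = _ellipse_polygon(self.fit(subset))
        return self._poly[subset]

    def overlap_fraction(self, sub_a: frozenset, sub_b: frozenset) -> float:
        """Intersection area of the two subsets' fitted ellipses as a
        fraction of the smaller ellipse's area."""
        key = frozenset((sub_a, sub_b))
        if key in self._overlap:
            return self._overlap[key]
        fa, fb = self.fit(sub_a), self.fit(sub_b)
        # cheap reject: bounding circles disjoint
        if math.dist(fa.center, fb.center) > fa.semi_axes[0] + fb.semi_axes[0]:
            frac = 0.0
        else:
            pa, pb = self._polygon(sub_a), self._polygon(sub_b)
            inter = pa.intersection(pb).area
            frac = inter / min(pa.area, pb.area)
        self._overlap[key] = frac
        return frac


def ellipse_perimeter(semi_axes: tuple[float, float]) -> float:
    """Ramanujan's approximation of the ellipse circumference."""
    a, b = semi_axes
    h = ((a - b) / (a + b)) ** 2 if a + b > 0 else 0.0
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _ellipse_polygon(fit: EllipseFit, n_vertices: int = 64):
    from shapely.geometry import Polygon

    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    a, b = fit.semi_axes
    c, s = math.cos(fit.angle), math.sin(fit.angle)
    x = fit.center[0] + a * np.cos(t) * c - b * np.sin(t) * s
    y = fit.center[1] + a * np.cos(t) * s + b * np.sin(t) * c
    return Polygon(np.column_stack([x, y]))


def partition_error(
    subsets: list[list[int]],
    segments: list[Segment],
    lam: float = 0.0,
    min_pixels: int = 5,
    cache: _FitCache | None = None,
    overlap_max_frac: float = 0.2,
    support_min_frac: float = 0.3,
) -> tuple[float, list[EllipseFit | None]]:
    """Total error of one candidate partition.

    Per subset: (union-fit residual / pixel count) + lam * (mean distance
    between the union-fit center and the centers of ellipses fitted to each
    constituent segment alone) / B, where B is the smallest semi-minor axis
    among the subset's valid inscribed ellipses.  Subsets whose pooled
    pixels are too few, or whose union fit is not a real ellipse, make the
    partition infeasible (+inf).  Segments too short to fit alone, or whose
    lone fit degenerates to a sliver (semi-minor under half the union's),
    contribute nothing to the penalty.

    Two physical-consistency constraints reject "phantom" grains fitted
    to the concave walls of a chip bite.  Grains are disjoint, so if any
    pair of subset ellipses intersects by more than ``overlap_max_frac``
    of the smaller ellipse's area, the partition is infeasible (raster
    tangency between genuinely touching grains and ordinary fit error
    stay well under the default 0.2).  And a counted grain must show
    enough of its outline: a subset whose pooled pixels number fewer than
    ``support_min_frac`` of its fitted ellipse's perimeter is infeasible
    (loosely placed grains expose most of their boundary — an isolated
    grain near 100 %, a grain in a cluster of 2-4 typically over 60 % —
    while a handful of bite-wall fragments "supports" only a few percent
    of whatever large ellipse happens to pass through them).

    ``lam`` defaults to 0: the normalized residual sum already pays one
    noise-floor term per subset, which both absorbs spurious corners and
    keeps distinct grains apart, whereas the dispersion penalty taxes only
    merged subsets with a center statistic that partial arcs determine
    poorly, so any sizable lam biases the search toward over-splitting
    (see the methods note).
    """
    cache = cache or _FitCache(segments, min_pixels)
    total = 0.0
    fits: list[EllipseFit | None] = []
    keys = [frozenset(sub) for sub in subsets]
    for sub in subsets:
        union = cache.fit(frozenset(sub))
        fits.append(union)
        if union is None or not union.is_valid_ellipse:
            return float("inf"), fits
        if union.n_points < support_min_frac * ellipse_perimeter(union.semi_axes):
            return float("inf"), fits
    if overlap_max_frac < 1.0:
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if cache.overlap_fraction(keys[i], keys[j]) > overlap_max_frac:
                    return float("inf"), fits
    for sub, union in zip(subsets, fits):
        total += union.residual / union.n_points

        if len(sub) > 1 and lam != 0.0:
            b_min = union.semi_axes[1]
            dists = []
            for i in sub:
                single = cache.fit(frozenset((i,)))
                if (single is None or not single.is_valid_ellipse
                        or single.semi_axes[1] < 0.5 * union.semi_axes[1]):
                    continue
                dists.append(math.dist(single.center, union.center))
                b_min = min(b_min, single.semi_axes[1])
            if dists:
                total += lam * (sum(dists) / len(dists)) / max(b_min, 1e-6)
    return total, fits


def iter_set_partitions(k: int):
    """All set partitions of range(k) in restricted-growth-string order."""
    a = [0] * k

    def rec(i: int, m: int):
        if i == k:
            groups: list[list[int]] = [[] for _ in range(m)]
            for j, g in enumerate(a):
                groups[g].append(j)
            yield groups
            return
        for g in range(m + 1):
            a[i] = g
            yield from rec(i + 1, max(m, g + 1))

    yield from rec(0, 0) if k else iter([[]])


def best_partition(
    segments: list[Segment],
    max_segments: int = 10,
    lam: float = 0.0,
    min_pixels: int = 5,
    overlap_max_frac: float = 0.2,
    support_min_frac: float = 0.3,
) -> Partition:
    """Exhaustive Bell-number search for the minimum-error set partition of
    a contour's segments.  Ties break toward fewer subsets, then toward
    earlier enumeration order.  Raises ContourTooComplexError beyond
    ``max_segments`` segments (Bell(10) = 115 975 partitions is the default
    ceiling)."""
    k = len(segments)
    if k == 0:
        raise ValueError("no segments to partition")
    if k > max_segments:
        raise ContourTooComplexError(
            f"contour has {k} segments, above the limit of {max_segments}")
    cache = _FitCache(segments, min_pixels)
    best: tuple[float, int] | None = None
    best_partition_: Partition | None = None
    for subsets in iter_set_partitions(k):
        err, fits = partition_error(subsets, segments, lam, min_pixels, cache,
                                    overlap_max_frac, support_min_frac)
        key = (err, len(subsets))
        if best is None or key < best:
            best = key
            best_partition_ = Partition(
                subsets=[list(s) for s in subsets],
                per_subset_fit=fits,
                total_error=err,
                grain_count=len(subsets),
            )
    assert best_partition_ is not None
    return best_partition_


@dataclass
class CpeConfig:
    radius: int = 7
    crf_threshold: float = 0.6
    max_segments: int = 10
    lam: float = 0.0
    min_pixels: int = 5
    overlap_max_frac: float = 0.2
    support_min_frac: float = 0.3


@dataclass
class ContourResult:
    """Per-contour outcome of the corner + ellipse-partition counting."""

    contour_id: int
    n_corners: int
    odd_corners: bool
    n_segments: int
    count_cp: int
    count_cpe: int
    fallback_used: str | None
    partition: Partition | None
    ellipses: list[EllipseFit]
    segment_assignment: list[int]
    corner_assignment: list[int]
    corners: CornerSet | None = field(repr=False, default=None)
    segments: list[Segment] | None = field(repr=False, default=None)
    contour: Contour | None = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "contour_id": self.contour_id,
            "n_corners": self.n_corners,
            "n_segments": self.n_segments,
            "count_cp": self.count_cp,
            "count_cpe": self.count_cpe,
            "fallback_used": self.fallback_used,
            "ellipses": [
                {"center": list(f.center), "axes": list(f.semi_axes), "angle": f.angle}
                for f in self.ellipses if f is not None and f.is_valid_ellipse
            ],
            "segment_assignment": list(self.segment_assignment),
        }


def count_grains_cpe(
    contour: Contour,
    mask: np.ndarray | None = None,
    config: CpeConfig | None = None,
) -> ContourResult:
    """Count the grains inside one contour: detect corners, split into
    segments, search the optimal ellipse partition; falls back to the
    corner-point estimate when the contour is too complex or no feasible
    elliptical partition exists."""
    cfg = config or CpeConfig()
    corners = detect_corners(contour, mask, cfg.radius, cfg.crf_threshold)
    segments = split_segments(contour, corners)
    n_corners = len(corners)
    r_closed = count_closed_segments(segments)
    count_cp = estimate_count_cp(n_corners, r_closed)

    if n_corners == 0:
        # isolated convex grain: no partition search needed
        try:
            fit = fit_conic_lsq(_segment_xy(segments[0]))
        except ValueError:
            fit = None
        ellipses = [fit] if fit is not None else []
        return ContourResult(contour.label, 0, False, 1, count_cp, 1, None,
                             Partition([[0]], [fit], 0.0, 1), ellipses, [0], [],
                             corners, segments, contour)

    fallback = None
    partition = None
    try:
        partition = best_partition(segments, cfg.max_segments, cfg.lam,
                                   cfg.min_pixels, cfg.overlap_max_frac,
                                   cfg.support_min_frac)
        if not math.isfinite(partition.total_error):
            fallback = "invalid_fits"
    except ContourTooComplexError:
        fallback = "too_complex"

    if fallback is not None:
        log.info("contour %d: falling back to corner-point estimate (%s)",
                 contour.label, fallback)
        count = count_cp
        seg_assign = list(range(len(segments)))
        fits: list[EllipseFit | None] = []
    else:
        count = partition.grain_count
        seg_assign = [0] * len(segments)
        for gi, sub in enumerate(partition.subsets):
            for si in sub:
                seg_assign[si] = gi
        fits = partition.per_subset_fit

    # corner pixels go to the adjacent subset whose ellipse explains them best
    corner_assign: list[int] = []
    if fallback is None and n_corners > 0:
        k = len(segments)
        for ci in range(n_corners):
            px = contour.points[corners.corner_indices[ci]][::-1].astype(np.float64)
            cand = {seg_assign[(ci - 1) % k], seg_assign[ci]}
            corner_assign.append(min(
                cand,
                key=lambda g: (abs(float(fits[g].algebraic_residuals(px[None, :])[0]))
                               if fits[g] is not None else float("inf")),
            ))

    ellipses = [f for f in fits if f is not None]
    return ContourResult(contour.label, n_corners, n_corners % 2 == 1,
                         len(segments), count_cp, count, fallback, partition,
                         ellipses, seg_assign, corner_assign, corners, segments,
                         contour)
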