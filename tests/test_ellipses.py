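import math

import numpy as np
import pytest
from scipy.special import ellipe
from sympy import bell
from sympy.utilities.iterables import multiset_partitions

from grainsplit import (
    best_partition,
    count_grains_cpe,
    detect_corners,
    extract_contours,
    fit_conic_lsq,
    partition_error,
    split_segments,
)
from grainsplit.ellipses import ContourTooComplexError, iter_set_partitions

from conftest import draw_disk, draw_ellipse, ellipse_points


class TestFitConic:
    def test_exact_ellipse_recovered(self):
        pts = ellipse_points(100, 80, 30, 15, 0.0, n=40)
        fit = fit_conic_lsq(pts)
        assert fit.is_valid_ellipse
        assert fit.center[0] == pytest.approx(100, abs=0.5)
        assert fit.center[1] == pytest.approx(80, abs=0.5)
        assert fit.semi_axes[0] == pytest.approx(30, abs=0.5)
        assert fit.semi_axes[1] == pytest.approx(15, abs=0.5)
        assert fit.residual < 1e-6

    def test_five_point_circle_is_symmetric(self):
        pts = ellipse_points(50, 40, 10, 10, 0.0, n=5)
        fit = fit_conic_lsq(pts)
        c = fit.coefficients
        assert c.a11 == pytest.approx(c.a22, abs=1e-9)
        assert c.a12 == pytest.approx(0.0, abs=1e-9)
        assert fit.center[0] == pytest.approx(50, abs=1e-6)
        assert fit.center[1] == pytest.approx(40, abs=1e-6)
        assert fit.semi_axes[0] == pytest.approx(10, abs=1e-6)

    def test_parallel_lines_are_not_an_ellipse(self):
        x = np.linspace(0, 20, 12)
        pts = np.concatenate([np.column_stack([x, np.zeros(12)]),
                              np.column_stack([x, np.full(12, 5.0)])])
        assert not fit_conic_lsq(pts).is_valid_ellipse

    def test_underdetermined_input_raises(self):
        with pytest.raises(ValueError, match="underdetermined"):
            fit_conic_lsq(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))

    def test_duplicate_points_are_collapsed(self):
        pts = ellipse_points(10, 10, 8, 5, 0.3, n=20)
        fit = fit_conic_lsq(np.concatenate([pts, pts]))
        assert fit.n_points == 20

    def test_residual_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(2)
        pts = ellipse_points(0, 0, 25, 12, 0.5, n=60)
        pts += rng.normal(0, 0.3, pts.shape)          # make residual nonzero
        base = fit_conic_lsq(pts).residual
        th = 0.65
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        moved = pts @ rot.T + [313.0, -127.0]
        assert fit_conic_lsq(moved).residual == pytest.approx(base, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_parameter_recovery_random_ellipses(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            cx, cy = rng.uniform(50, 400, 2)
            a = rng.uniform(20, 60)
            b = a / rng.uniform(1.1, 2.5)
            ang = rng.uniform(0, math.pi)
            fit = fit_conic_lsq(ellipse_points(cx, cy, a, b, ang, n=50))
            assert fit.is_valid_ellipse and fit.residual < 1e-6
            assert fit.center[0] == pytest.approx(cx, abs=0.5)
            assert fit.center[1] == pytest.approx(cy, abs=0.5)
            assert fit.semi_axes[0] == pytest.approx(a, abs=0.5)
            assert fit.semi_axes[1] == pytest.approx(b, abs=0.5)
            d = abs(fit.angle - ang) % math.pi
            assert min(d, math.pi - d) < math.radians(0.5)

    def test_agrees_with_skimage_ellipse_model(self):
        from skimage.measure import EllipseModel

        rng = np.random.default_rng(9)
        pts = ellipse_points(120, 90, 40, 22, 0.8, n=80)
        pts += rng.normal(0, 0.4, pts.shape)
        fit = fit_conic_lsq(pts)
        em = EllipseModel()
        assert em.estimate(pts)
        xc, yc, a, b, _ = em.params
        if b > a:
            a, b = b, a
        assert fit.center[0] == pytest.approx(xc, abs=1.0)
        assert fit.center[1] == pytest.approx(yc, abs=1.0)
        assert fit.semi_axes[0] == pytest.approx(a, abs=1.0)
        assert fit.semi_axes[1] == pytest.approx(b, abs=1.0)


def _segments_of(mask):
    c = extract_contours(mask)[0]
    corners = detect_corners(c, mask)
    return c, corners, split_segments(c, detect_corners(c, mask))


class TestPartitionError:
    def test_single_subset_on_exact_ellipse_has_tiny_error_and_no_penalty(self):
        mask = np.zeros((140, 180), dtype=bool)
        draw_ellipse(mask, 90, 70, 50, 28, 0.3)
        c, corners, segs = _segments_of(mask)
        assert len(segs) == 1
        err0, _ = partition_error([[0]], segs, lam=0.0)
        err1, _ = partition_error([[0]], segs, lam=1.0)
        assert err0 < 0.02
        assert err1 == err0                 # singletons carry no penalty

    def test_mixing_two_grains_costs_more_than_separating_them(
            self, two_touching_disks):
        mask, _ = two_touching_disks
        c, corners, segs = _segments_of(mask)
        assert len(segs) == 2
        together, _ = partition_error([[0, 1]], segs)
        apart, _ = partition_error([[0], [1]], segs)
        assert apart < together

    def test_subset_with_degenerate_union_fit_is_infeasible(self):
        # two parallel pixel runs: the joint LSQ conic degenerates, so any
        # subset pooling them cannot represent a grain
        from grainsplit.contours import Segment

        rows = np.arange(10, 40)
        seg_a = Segment(0, -1, -1, np.column_stack([rows, np.full(30, 5)]))
        seg_b = Segment(0, -1, -1, np.column_stack([rows, np.full(30, 25)]))
        err, _ = partition_error([[0, 1]], [seg_a, seg_b])
        assert err == math.inf


class TestBestPartition:
    def test_single_segment_has_unique_partition(self):
        mask = np.zeros((100, 120), dtype=bool)
        draw_ellipse(mask, 60, 50, 35, 20)
        _, _, segs = _segments_of(mask)
        part = best_partition(segs)
        assert part.grain_count == 1 and part.subsets == [[0]]

    def test_two_touching_disks_split_into_two(self, two_touching_disks):
        mask, _ = two_touching_disks
        _, _, segs = _segments_of(mask)
        part = best_partition(segs)
        assert part.grain_count == 2
        assert sorted(map(tuple, part.subsets)) == [(0,), (1,)]

    def test_enumeration_is_complete_bell_numbers(self):
        for k in range(1, 8):
            assert sum(1 for _ in iter_set_partitions(k)) == int(bell(k))

    def test_too_many_segments_rejected(self, two_touching_disks):
        mask, _ = two_touching_disks
        _, _, segs = _segments_of(mask)
        with pytest.raises(ContourTooComplexError):
            best_partition(segs, max_segments=1)


# --- independent brute-force evaluator (no shared code with the package) ---

def _oracle_fit(pts_xy):
    pts = np.unique(pts_xy, axis=0)
    if len(pts) < 5:
        return None
    mu = pts.mean(axis=0)
    sc = math.sqrt(((pts - mu) ** 2).sum(axis=1).mean() / 2.0)
    q = (pts - mu) / sc
    D = np.column_stack([q[:, 0] ** 2, 2 * q[:, 0] * q[:, 1], q[:, 1] ** 2,
                         2 * q[:, 0], 2 * q[:, 1]])
    alpha = np.linalg.pinv(D) @ (-np.ones(len(q)))
    resid = float(((D @ alpha + 1.0) ** 2).sum())
    A = np.array([[alpha[0], alpha[1]], [alpha[1], alpha[2]]])
    if np.linalg.det(A) <= 1e-12:
        return None
    ctr = np.linalg.solve(A, -alpha[3:5])
    v = 1.0 + alpha[3] * ctr[0] + alpha[4] * ctr[1]
    if (alpha[0] + alpha[2]) * v >= 0:
        return None
    ev, evec = np.linalg.eigh(A)
    semis = np.sort(np.sqrt(-v / ev) * sc)[::-1]
    i = int(np.argmax(np.sqrt(-v / ev)))
    ang = math.atan2(evec[1, i], evec[0, i]) % math.pi
    return {"center": mu + sc * ctr, "axes": semis, "angle": ang,
            "resid": resid, "n": len(pts)}


def _oracle_inside(f, xs, ys):
    dx, dy = xs - f["center"][0], ys - f["center"][1]
    c, s = math.cos(f["angle"]), math.sin(f["angle"])
    a, b = f["axes"]
    return ((dx * c + dy * s) / a) ** 2 + ((-dx * s + dy * c) / b) ** 2 <= 1.0


def _oracle_overlap(fa, fb):
    lo = np.minimum(fa["center"] - fa["axes"][0], fb["center"] - fb["axes"][0])
    hi = np.maximum(fa["center"] + fa["axes"][0], fb["center"] + fb["axes"][0])
    xs, ys = np.meshgrid(np.arange(lo[0], hi[0], 0.25),
                         np.arange(lo[1], hi[1], 0.25))
    ina, inb = _oracle_inside(fa, xs, ys), _oracle_inside(fb, xs, ys)
    denom = min(ina.sum(), inb.sum())
    return (ina & inb).sum() / denom if denom else 0.0


def _oracle_perimeter(axes):
    a, b = axes
    return 4.0 * a * float(ellipe(1.0 - (b / a) ** 2))


def _oracle_error(subsets, seg_xy):
    fits = []
    for sub in subsets:
        f = _oracle_fit(np.concatenate([seg_xy[i] for i in sub]))
        if f is None or f["n"] < 0.3 * _oracle_perimeter(f["axes"]):
            return math.inf
        fits.append(f)
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            if _oracle_overlap(fits[i], fits[j]) > 0.2:
                return math.inf
    return sum(f["resid"] / f["n"] for f in fits)


def oracle_best_partition(segments):
    seg_xy = [s.points[:, ::-1].astype(float) for s in segments]
    best_key, best_sets = None, None
    for subsets in multiset_partitions(list(range(len(segments)))):
        err = _oracle_error(subsets, seg_xy)
        key = (err, len(subsets))
        if best_key is None or key < best_key:
            best_key, best_sets = key, subsets
    return best_key[0], {frozenset(s) for s in best_sets}


class TestPartitionOracle:
    @pytest.mark.parametrize("seed", [0, 3])
    def test_best_partition_matches_independent_evaluator(self, seed):
        """Exhaustive re-evaluation of every set partition with separately
        written fitting/feasibility code must select the same partition."""
        from grainsplit import generate_scene
        from grainsplit.preprocess import PreprocessConfig, preprocess_pipeline

        img, _ = generate_scene(n_grains=8, touch_fraction=0.5,
                                chip_probability=0.2, image_size=(700, 520),
                                seed=seed, semi_major_range=(40.0, 60.0))
        pre = preprocess_pipeline(img, PreprocessConfig(downsample_factor=1))
        checked = 0
        for c in extract_contours(pre.mask):
            corners = detect_corners(c, pre.mask)
            segs = split_segments(c, corners)
            if not 2 <= len(segs) <= 6:
                continue
            part = best_partition(segs)
            if not math.isfinite(part.total_error):
                continue
            oerr, osets = oracle_best_partition(segs)
            assert {frozenset(s) for s in part.subsets} == osets
            assert part.total_error == pytest.approx(oerr, rel=1e-6)
            checked += 1
        assert checked >= 1


class TestCountCpe:
    def test_isolated_ellipse_counts_one_with_accurate_fit(self):
        mask = np.zeros((160, 200), dtype=bool)
        draw_ellipse(mask, 100, 80, 55, 30, 0.7)
        c = extract_contours(mask)[0]
        res = count_grains_cpe(c, mask)
        assert res.count_cpe == 1 and res.n_corners == 0
        fit = res.ellipses[0]
        assert fit.center[0] == pytest.approx(100, abs=1.0)
        assert fit.center[1] == pytest.approx(80, abs=1.0)
        assert fit.semi_axes[0] == pytest.approx(55, abs=1.0)
        assert fit.semi_axes[1] == pytest.approx(30, abs=1.0)

    def test_chain_of_three_touching_ellipses_counts_three(self):
        mask = np.zeros((160, 400), dtype=bool)
        for cx in (80, 180, 280):
            draw_ellipse(mask, cx, 80, 52, 30)
        c = extract_contours(mask)[0]
        res = count_grains_cpe(c, mask)
        assert res.count_cpe == 3

    def test_chipped_isolated_grain_still_counts_one(self):
        mask = np.zeros((160, 220), dtype=bool)
        draw_ellipse(mask, 110, 80, 60, 32, 0.2)
        bite = np.zeros_like(mask)
        bx = 110 + 60 * math.cos(1.1) * math.cos(0.2) - 32 * math.sin(1.1) * math.sin(0.2)
        by = 80 + 60 * math.cos(1.1) * math.sin(0.2) + 32 * math.sin(1.1) * math.cos(0.2)
        draw_disk(bite, int(bx), int(by), 10)
        mask &= ~bite
        c = extract_contours(mask)[0]
        res = count_grains_cpe(c, mask)
        assert res.n_corners >= 1           # the chip produces spurious corners
        assert res.count_cpe == 1
        assert res.count_cp >= 2            # uncorrected estimate over-counts

    def test_count_invariant_to_start_point_and_orientation(
            self, two_touching_disks):
        from grainsplit.contours import Contour

        mask, _ = two_touching_disks
        c = extract_contours(mask)[0]
        base = count_grains_cpe(c, mask).count_cpe
        rolled = Contour(points=np.roll(c.points, 17, axis=0),
                         region_area=c.region_area,
                         region_mask=c.region_mask, label=c.label)
        reversed_ = Contour(points=c.points[::-1].copy(),
                            region_area=c.region_area,
                            region_mask=c.region_mask, label=c.label)
        assert count_grains_cpe(rolled, mask).count_cpe == base
        assert count_grains_cpe(reversed_, mask).count_cpe == base
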