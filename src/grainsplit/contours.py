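"""Contour extraction and concave-point (corner) detection.

Each connected foreground region contributes one closed, ordered chain of
boundary pixels.  Along the chain, the corner response function (CRF) at a
boundary pixel p is the fraction of the region's grain pixels among all
raster pixels within Euclidean distance R of p: about 0.5 on straight
boundary runs, below 0.5 on convex arcs, and above it in the concave
notches where two touching grains meet.  Maximal runs of contour pixels
with CRF above a threshold (default 0.6) are corner regions; the run's CRF
peak is the corner representative.  The arcs between consecutive corners
are the segments later regrouped into per-grain subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)

# Moore neighborhood in clockwise order (image coordinates, row down):
# N, NE, E, SE, S, SW, W, NW
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


@dataclass
class Contour:
    """Closed boundary pixel chain of one foreground region.

    ``points`` is an (N, 2) int array of (row, col); consecutive points
    (cyclically) are 8-connected.  ``region_mask`` is the filled mask of
    the region the contour bounds, used by the corner response function.
    """

    points: np.ndarray
    region_area: int
    region_mask: np.ndarray = field(repr=False, default=None)
    label: int = 0
    closed: bool = True

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CrfProfile:
    values: np.ndarray      # one CRF value per contour point, in [0, 1]
    radius_R: int


@dataclass
class CornerSet:
    corner_indices: np.ndarray   # strictly increasing indices into the contour
    threshold: float
    profile: CrfProfile | None = None

    def __len__(self) -> int:
        return len(self.corner_indices)


@dataclass
class Segment:
    """Open contour arc between two consecutive corner representatives
    (corner pixels themselves excluded).  With zero corners the single
    segment is the whole contour."""

    contour_id: int
    start_corner_index: int
    end_corner_index: int
    points: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


def _trace_boundary(region: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Moore-neighbor boundary tracing with Jacob's stopping criterion.

    ``region`` must be padded so no foreground pixel touches the array
    border.  ``start`` is the topmost-leftmost foreground pixel, whose west
    neighbor is guaranteed background.
    """
    r0, c0 = start
    points = [start]
    # backtrack = direction pointing from current pixel to the previously
    # examined background neighbor; entering from the west for the start.
    prev_dir = _MOORE_INDEX[(0, -1)]
    cur = start
    first_move = None
    while True:
        found = False
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            dr, dc = _MOORE[d]
            nr, nc = cur[0] + dr, cur[1] + dc
            if region[nr, nc]:
                if cur == start:
                    if first_move is None:
                        first_move = d
                    elif d == first_move and len(points) > 1:
                        # re-entered the start with the same exit: closed
                        return np.array(points[:-1], dtype=np.int64)
                points.append((nr, nc))
                # new backtrack: the neighbor just before the hit, seen
                # from the new pixel
                pr, pc = _MOORE[(d + 7) % 8]
                br, bc = cur[0] + pr, cur[1] + pc
                prev_dir = _MOORE_INDEX[(br - nr, bc - nc)]
                cur = (nr, nc)
                found = True
                break
        if not found:                      # isolated single pixel
            return np.array([start], dtype=np.int64)
        if cur == start:
            # check on next loop whether the exit repeats; also guard
            # against pathological non-termination
            if len(points) > 8 * region.size:
                raise RuntimeError("boundary tracing failed to terminate")


def _signed_area(points: np.ndarray) -> float:
    x = points[:, 1].astype(np.float64)
    y = points[:, 0].astype(np.float64)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_contours(mask: np.ndarray, min_area: int = 30) -> list[Contour]:
    """Outer boundary contour of every 8-connected foreground component
    with at least ``min_area`` pixels.  Holes are ignored; traversal
    orientation is made consistent (positive signed area in (x=col,
    y=row) coordinates) so downstream results do not depend on the
    tracer's direction."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return []
    labels, n = ndi.label(m, structure=_EIGHT)
    out: list[Contour] = []
    slices = ndi.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        region = labels[sl] == lab
        area = int(region.sum())
        if area < min_area:
            continue
        padded = np.pad(region, 1)
        rows, cols = np.nonzero(padded)
        k = np.lexsort((cols, rows))[0]          # topmost, then leftmost
        pts = _trace_boundary(padded, (int(rows[k]), int(cols[k])))
        pts = pts - 1                             # undo padding
        pts[:, 0] += sl[0].start
        pts[:, 1] += sl[1].start
        if len(pts) > 2 and _signed_area(pts) < 0:
            pts = pts[::-1].copy()
        full_region = np.zeros(m.shape, dtype=bool)
        full_region[sl] = region
        out.append(Contour(points=pts, region_area=area,
                           region_mask=full_region, label=lab))
    return out


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dr * dr + dc * dc <= r * r
    return dr[inside], dc[inside]


def _region_mask(contour: Contour, mask: np.ndarray | None) -> np.ndarray:
    if contour.region_mask is not None:
        return contour.region_mask
    if mask is None:
        raise ValueError("contour has no region mask and none was provided")
    m = np.asarray(mask).astype(bool)
    labels, _ = ndi.label(m, structure=_EIGHT)
    r, c = contour.points[0]
    return labels == labels[r, c]


def corner_response(
    contour: Contour,
    mask: np.ndarray | None,
    point_index: int,
    radius_R: int = 7,
) -> float:
    """CRF at one contour pixel: grain pixels of the contour's region
    within the radius-R raster disk, divided by the number of in-bounds
    disk pixels.  Disks are clipped at the image border."""
    if radius_R < 1:
        raise ValueError("radius_R must be >= 1")
    region = _region_mask(contour, mask)
    r, c = contour.points[point_index]
    dr, dc = _disk_offsets(radius_R)
    rr, cc = r + dr, c + dc
    ok = (rr >= 0) & (rr < region.shape[0]) & (cc >= 0) & (cc < region.shape[1])
    a = int(ok.sum())
    npix = int(region[rr[ok], cc[ok]].sum())
    return npix / a


def crf_profile(
    contour: Contour,
    mask: np.ndarray | None = None,
    radius_R: int = 7,
) -> CrfProfile:
    """Vectorized CRF along the whole contour."""
    if radius_R < 1:
        raise ValueError("radius_R must be >= 1")
    region = _region_mask(contour, mask)
    h, w = region.shape
    dr, dc = _disk_offsets(radius_R)
    rr = contour.points[:, 0][:, None] + dr[None, :]
    cc = contour.points[:, 1][:, None] + dc[None, :]
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    vals = np.zeros(rr.shape, dtype=bool)
    vals[ok] = region[rr[ok], cc[ok]]
    a = ok.sum(axis=1)
    return CrfProfile(values=vals.sum(axis=1) / a, radius_R=radius_R)


def detect_corners(
    contour: Contour,
    mask: np.ndarray | None = None,
    radius_R: int = 7,
    threshold: float = 0.6,
) -> CornerSet:
    """Corner representatives: one per maximal cyclic run of contour
    points with CRF above ``threshold``, taking the run's CRF maximum
    (ties to the lowest contour index)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    profile = crf_profile(contour, mask, radius_R)
    above = profile.values > threshold
    n = len(above)
    if not above.any():
        return CornerSet(np.empty(0, dtype=np.int64), threshold, profile)
    if above.all():
        # one run covering the whole contour
        reps = [int(np.argmax(profile.values))]
        return CornerSet(np.array(reps, dtype=np.int64), threshold, profile)
    # rotate so position 0 is below threshold, find runs, rotate back
    start = int(np.argmin(above))
    rolled = np.roll(above, -start)
    edges = np.flatnonzero(np.diff(rolled.astype(np.int8)))
    run_starts = edges[::2] + 1
    run_ends = edges[1::2] + 1 if len(edges) % 2 == 0 else np.append(edges[1::2] + 1, n)
    reps = []
    for s, e in zip(run_starts, run_ends):
        idx = (np.arange(s, e) + start) % n
        vals = profile.values[idx]
        reps.append(int(idx[np.argmax(vals)]))
    reps = np.sort(np.array(reps, dtype=np.int64))
    return CornerSet(reps, threshold, profile)


def split_segments(contour: Contour, corners: CornerSet) -> list[Segment]:
    """Cut the contour at the corner representatives.  k corners give k
    cyclic open arcs (corner pixels excluded); zero corners give one
    segment containing every contour point."""
    n = len(contour.points)
    cid = contour.label
    if len(corners) == 0:
        return [Segment(cid, -1, -1, contour.points.copy())]
    idx = corners.corner_indices
    segs: list[Segment] = []
    for a, b in zip(idx, np.roll(idx, -1)):
        if b > a:
            sel = np.arange(a + 1, b)
        else:                                     # wraparound arc
            sel = np.concatenate([np.arange(a + 1, n), np.arange(0, b)])
        segs.append(Segment(cid, int(a), int(b), contour.points[sel % n]))
    return segs


def estimate_count_cp(n_corners: int, r_closed: int = 0) -> int:
    """Corner-point grain count: Ncorners/2 - Rclosed + 1, floored at one
    grain.  Odd corner counts (raster noise) are rounded up to the next
    even number with a warning."""
    if n_corners < 0 or r_closed < 0:
        raise ValueError("counts must be non-negative")
    if n_corners % 2 == 1:
        log.warning("odd corner count %d rounded up to %d", n_corners, n_corners + 1)
        n_corners += 1
    return max(1, n_corners // 2 - r_closed + 1)


def count_closed_segments(segments: list[Segment]) -> int:
    """Degenerate closed loops: segments whose two endpoint corners
    coincide (only possible when a contour has a single corner)."""
    return sum(
        1 for s in segments
        if s.start_corner_index >= 0 and s.start_corner_index == s.end_corner_index
    )
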