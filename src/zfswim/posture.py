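"""Posture model: boundary, centerline and the 20-point body description.

The posture of the fish in each frame is reduced to a fixed number of
control points (20 by default) spaced uniformly in arc length along the
midline, head first and tail last.  The midline comes from a
topology-preserving morphological skeleton of the silhouette, pruned to
its single longest end-to-end path so that fin spurs and noise branches
drop out without any explicit pruning parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .errors import PostureError
from .segmentation import FishMask

log = logging.getLogger(__name__)

#: Fraction of arc length near each endpoint used by the head-width heuristic.
_HEAD_FRACTION = 0.10

#: Minimum silhouette elongation (major/minor axis ratio) for a midline to
#: be meaningful; below this the medial-axis assumption breaks down.
MIN_ELONGATION = 1.5


@dataclass
class Centerline:
    """Ordered midline polyline in (x, y) pixel coordinates."""

    points: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise PostureError("a centerline needs at least 2 (x, y) points")
        if (np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0).any():
            raise PostureError("centerline has coincident consecutive points")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class ControlPoints:
    """Exactly n arc-length-uniform midline points, head first, tail last."""

    points: np.ndarray  # (n, 2) float
    body_length: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.body_length <= 0:
            raise PostureError("body length must be positive")

    @property
    def head(self) -> np.ndarray:
        return self.points[0]

    @property
    def tail(self) -> np.ndarray:
        return self.points[-1]


# ---------------------------------------------------------------------------
# boundary

_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def extract_boundary(m: FishMask) -> np.ndarray:
    """Ordered closed outer contour of the silhouette, as (x, y) pixel centers.

    Moore-neighbor tracing over boundary pixels; holes in the mask are
    ignored (the outer contour is returned) with a warning.  A
    single-pixel mask yields a degenerate one-point contour, which
    downstream stages flag as unusable.
    """
    mask = m.mask
    if not mask.any():
        raise PostureError("empty mask has no boundary")
    filled = ndimage.binary_fill_holes(mask)
    if filled.sum() != mask.sum():
        log.warning("frame %d: mask has holes; outer contour used", m.frame_index)
    rc = _moore_trace(filled)
    return rc[:, ::-1].astype(float)  # (row, col) -> (x, y)


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    order = np.lexsort((xs, ys))
    start = (int(ys[order[0]]), int(xs[order[0]]))

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    contour = [start]
    cur = start
    prev_dir = 0  # enter scanning at W of the top-left-most pixel (background)
    first_move = None
    while True:
        nxt = None
        for k in range(8):
            i = (prev_dir + k) % 8
            cand = (cur[0] + _MOORE[i][0], cur[1] + _MOORE[i][1])
            if fg(cand):
                nxt = cand
                break
        if nxt is None:  # isolated pixel
            return np.array(contour)
        if first_move is None:
            first_move = (cur, nxt)
        elif (cur, nxt) == first_move:
            break
        contour.append(nxt)
        cur = nxt
        prev_dir = (i + 5) % 8  # restart search just past the backtrack direction
    return np.array(contour[:-1])


# ---------------------------------------------------------------------------
# centerline

def extract_centerline(m: FishMask, smooth_sigma: float = 0.5) -> Centerline:
    """Midline of an elongated silhouette.

    The mask is thinned to a morphological skeleton; the centerline is
    the longest end-to-end geodesic path through the skeleton (Dijkstra
    over 8-connected skeleton pixels with Euclidean step costs).  The
    raw path zigzags at the pixel scale, which would dominate discrete
    angle changes, so it is replaced by a cubic smoothing spline over
    arc length whose residual budget is ``smooth_sigma`` px per point
    (the magnitude of skeleton quantization noise).
    """
    mask = m.mask
    if not mask.any():
        raise PostureError("cannot extract a centerline from an empty mask")
    if _elongation(mask) < MIN_ELONGATION:
        raise PostureError(
            f"silhouette elongation {_elongation(mask):.2f} < {MIN_ELONGATION}; "
            "midline undefined for round shapes"
        )
    # work on the bounding box: skeletonization cost scales with crop size
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    crop = np.pad(mask[y0:y1, x0:x1], 1)
    skel = skeletonize(crop)
    path_rc = _longest_skeleton_path(skel)
    if path_rc is None:
        raise PostureError("skeleton has no endpoints (ring topology)")
    pts = path_rc[:, ::-1].astype(float)  # -> (x, y) in crop coords
    pts += np.array([x0 - 1, y0 - 1])
    pts = _smooth_polyline(pts, smooth_sigma)
    return Centerline(points=pts)


def _elongation(mask: np.ndarray) -> float:
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    ev = np.sort(np.linalg.eigvalsh(cov))
    if ev[0] <= 1e-12:
        return np.inf
    return float(np.sqrt(ev[1] / ev[0]))


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray | None:
    """Longest endpoint-to-endpoint geodesic through the skeleton pixels."""
    rc = np.argwhere(skel)
    n = len(rc)
    if n == 1:
        return rc
    index = -np.ones(skel.shape, int)
    index[tuple(rc.T)] = np.arange(n)
    rows, cols, costs = [], [], []
    for dr, dc in _MOORE[:4]:  # half the neighborhood; graph is symmetric
        shifted = np.full_like(index, -1)
        src = index[max(dr, 0) or None : skel.shape[0] + min(dr, 0) or None,
                    max(dc, 0) or None : skel.shape[1] + min(dc, 0) or None]
        dst = index[max(-dr, 0) or None : skel.shape[0] + min(-dr, 0) or None,
                    max(-dc, 0) or None : skel.shape[1] + min(-dc, 0) or None]
        ok = (src >= 0) & (dst >= 0)
        rows.extend(src[ok])
        cols.extend(dst[ok])
        costs.extend([np.hypot(dr, dc)] * int(ok.sum()))
    graph = coo_matrix((costs, (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray((graph > 0).sum(axis=1)).ravel() + np.asarray((graph > 0).sum(axis=0)).ravel()
    endpoints = np.flatnonzero(deg <= 1)
    if len(endpoints) == 0:
        return None
    if len(endpoints) == 1:
        endpoints = np.append(endpoints, np.argmax(deg))
    dist, pred = dijkstra(graph, directed=False, indices=endpoints, return_predecessors=True)
    finite = np.where(np.isfinite(dist), dist, -1)
    i, j = np.unravel_index(np.argmax(finite), finite.shape)
    path = [j]
    while pred[i, path[-1]] >= 0:
        path.append(pred[i, path[-1]])
    return rc[np.array(path[::-1])]


def _smooth_polyline(pts: np.ndarray, sigma: float) -> np.ndarray:
    """Cubic smoothing spline of the path, parametrized by arc length.

    The smoothing budget ``s = n * sigma**2`` lets the spline deviate
    ~sigma px per skeleton pixel, which absorbs 8-connected staircase
    jitter without flattening body-scale bends.  Very short paths are
    returned unchanged.
    """
    n = len(pts)
    if n < 8 or sigma <= 0:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    try:
        tck, _ = interpolate.splprep(
            [pts[:, 0], pts[:, 1]], u=u, s=n * sigma**2, k=3
        )
    except Exception:  # degenerate geometry: keep the raw path
        return pts
    uu = np.linspace(0.0, u[-1], max(n, 50))
    x, y = interpolate.splev(uu, tck)
    out = np.column_stack([x, y])
    keep = np.ones(len(out), bool)
    keep[1:] = np.linalg.norm(np.diff(out, axis=0), axis=1) > 1e-9
    return out[keep]


# ---------------------------------------------------------------------------
# orientation and resampling

def orient_head_to_tail(
    c: Centerline, m: FishMask, prev: ControlPoints | None = None
) -> Centerline:
    """Order the centerline so index 0 is the head.

    With a previous frame's posture available the orientation that keeps
    endpoints closest to the previous head/tail wins (temporal
    consistency).  On the first frame the wider end is the head, using
    the mean distance-transform value of the mask over the 10% of arc
    length nearest each endpoint — adult zebrafish are widest near the
    head and narrowest at the caudal peduncle.  A symmetric tie falls
    back to head = endpoint with smaller x (then smaller y).
    """
    pts = c.points
    if prev is not None:
        keep = np.linalg.norm(pts[0] - prev.head) + np.linalg.norm(pts[-1] - prev.tail)
        flip = np.linalg.norm(pts[-1] - prev.head) + np.linalg.norm(pts[0] - prev.tail)
        return c if keep <= flip else Centerline(points=pts[::-1].copy())
    w_first, w_last = _end_widths(pts, m.mask)
    if abs(w_first - w_last) > 1e-6:
        return c if w_first > w_last else Centerline(points=pts[::-1].copy())
    a, b = pts[0], pts[-1]
    if (a[0], a[1]) <= (b[0], b[1]):
        return c
    return Centerline(points=pts[::-1].copy())


def _end_widths(pts: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    dt = ndimage.distance_transform_edt(mask)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    widths = []
    for near_start in (True, False):
        sel = s <= _HEAD_FRACTION * total if near_start else s >= (1 - _HEAD_FRACTION) * total
        sub = pts[sel]
        cols = np.clip(np.rint(sub[:, 0]).astype(int), 0, mask.shape[1] - 1)
        rows = np.clip(np.rint(sub[:, 1]).astype(int), 0, mask.shape[0] - 1)
        widths.append(float(dt[rows, cols].mean()))
    return widths[0], widths[1]


def sample_control_points(c: Centerline, n: int = 20) -> ControlPoints:
    """Resample the centerline at n arc-length-uniform positions.

    Point k sits at arc length k*L/(n-1) by linear interpolation along
    the polyline, so the first and last control points coincide with the
    head and tail endpoints and L is the centerline arc length.
    """
    if n < 2:
        raise PostureError("need at least 2 control points")
    pts = c.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = s[-1]
    if L <= 0:
        raise PostureError("degenerate centerline of zero length")
    targets = np.linspace(0.0, L, n)
    out = np.column_stack([np.interp(targets, s, pts[:, 0]), np.interp(targets, s, pts[:, 1])])
    out[0], out[-1] = pts[0], pts[-1]
    return ControlPoints(points=out, body_length=L)


def posture_from_mask(
    m: FishMask, n: int = 20, prev: ControlPoints | None = None
) -> ControlPoints:
    """Convenience: mask -> oriented, uniformly resampled control points."""
    cl = extract_centerline(m)
    cl = orient_head_to_tail(cl, m, prev)
    return sample_control_points(cl, n)
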