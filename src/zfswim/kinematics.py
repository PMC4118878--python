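"""Body-wave measurements: curvature, tail offset, travel distance.

Curvature here is the discrete bending angle of the midline polyline:
at interior control point i it is the absolute (wrapped) change, in
degrees, between the directions of the two midline segments meeting at
i.  A straight fish scores 0 everywhere; larger values mean stronger
local bending.  Tail offset is the distance from the tail point to the
silhouette centroid divided by body length L — about 0.5 for a straight
fish and smaller the more the body curls.  Both are purely shape-based
and therefore invariant to where and in which direction the fish swims.
Travel distance is the path length of the body-centroid trajectory over
a body-waving cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CycleError, PostureError
from .posture import ControlPoints
from .segmentation import FishMask


@dataclass
class PostureMetrics:
    """Shape measurements of one frame."""

    frame_index: int
    curvature: np.ndarray  # (n_points,) degrees, unsigned
    tail_offset: float
    centroid: tuple[float, float]
    body_length: float


def segment_angles(p: ControlPoints) -> np.ndarray:
    """Direction of each midline segment, degrees in (-180, 180].

    Angle i is atan2(dy, dx) of the vector from control point i to
    i + 1, with y pointing down the image (row direction).
    """
    d = np.diff(p.points, axis=0)
    norms = np.linalg.norm(d, axis=1)
    if (norms == 0).any():
        raise PostureError("coincident consecutive control points")
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    ang[ang == -180.0] = 180.0
    return ang


def wrap_angle_diff(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-180, 180]."""
    out = (np.asarray(delta) + 180.0) % 360.0 - 180.0
    return np.where(out == -180.0, 180.0, out)


def body_curvature(p: ControlPoints) -> np.ndarray:
    """Unsigned bending angle (degrees) at each of the n control points.

    Interior point i gets |wrapped(angle_i - angle_{i-1})| of the two
    adjacent segment directions; the two endpoints copy their nearest
    interior neighbour so the profile has exactly n entries.
    """
    if len(p.points) < 3:
        raise PostureError("curvature needs at least 3 control points")
    ang = segment_angles(p)
    interior = np.abs(wrap_angle_diff(np.diff(ang)))
    return np.concatenate([[interior[0]], interior, [interior[-1]]])


def tail_offset(p: ControlPoints, m: FishMask) -> float:
    """T / L: tail-to-body-centroid distance over body length.

    The "center of fish body" is the binary-mask centroid — the same
    centroid that travel distance tracks, so one center definition is
    used throughout.  Smaller values indicate larger bending.
    """
    if p.body_length <= 0:
        raise PostureError("body length must be positive")
    t = float(np.linalg.norm(p.tail - np.asarray(m.centroid)))
    return t / p.body_length


def travel_distance(
    centroids: np.ndarray, mode: str = "path", max_gap: int = 2
) -> float:
    """Centroid path length (px) over one body-waving cycle.

    ``centroids`` is (T, 2) with NaN rows for frames without detection;
    runs of at most ``max_gap`` consecutive missing frames are bridged
    by linear interpolation, longer runs reject the cycle.  With
    ``mode="net"`` the start-to-end displacement is returned instead of
    the summed path.
    """
    c = np.asarray(centroids, float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("centroids must be a (T, 2) array")
    missing = np.isnan(c).any(axis=1)
    if (~missing).sum() < 2:
        raise CycleError("fewer than 2 valid centroids in cycle")
    if missing.any():
        run = _longest_run(missing)
        if run > max_gap or missing[0] or missing[-1]:
            raise CycleError(
                f"{int(missing.sum())} missing detections (longest run {run}) "
                "cannot be bridged"
            )
        idx = np.arange(len(c))
        for col in range(2):
            c[missing, col] = np.interp(idx[missing], idx[~missing], c[~missing, col])
    if mode == "net":
        return float(np.linalg.norm(c[-1] - c[0]))
    return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())


def _longest_run(flags: np.ndarray) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def posture_metrics(p: ControlPoints, m: FishMask) -> PostureMetrics:
    """Bundle the per-frame shape measurements."""
    return PostureMetrics(
        frame_index=m.frame_index,
        curvature=body_curvature(p),
        tail_offset=tail_offset(p, m),
        centroid=m.centroid,
        body_length=p.body_length,
    )
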