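"""Body-waving cycles: segmentation, normalization, smoothing, group stats.

A body-waving cycle is the unit of analysis: a stretch of video in which
the fish goes from (nearly) straight through a bend and back.  Every
cycle is mapped onto a fixed number of frames (30 by default) so that
curvature matrices from different cycles and fish can be averaged
elementwise into per-group spatio-temporal profiles, and per-cycle
scalar metrics (largest curvature, smallest tail offset, travel
distance) can be compared across genotype groups with a Student t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .config import RunConfig
from .errors import AnnotationError, ConfigError, CycleError
from .kinematics import PostureMetrics, travel_distance

log = logging.getLogger(__name__)


@dataclass
class WaveCycle:
    """One straight->bent->straight episode of one fish."""

    fish_id: str
    group: str
    start_frame: int
    end_frame: int  # inclusive
    normalized_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise AnnotationError(
                f"cycle start {self.start_frame} > end {self.end_frame}"
            )

    @property
    def span(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class CurvatureProfile:
    """Curvature matrix C: body locations (rows) x normalized frames (cols)."""

    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, float)
        if self.C.ndim != 2:
            raise ValueError("C must be 2-D (locations x frames)")


@dataclass
class CycleMetrics:
    """Per-cycle scalars used for the group comparison."""

    max_curvature: float
    min_tail_offset: float
    travel_distance: float


@dataclass
class TTestResult:
    t: float
    p: float
    significant: bool


@dataclass
class GroupSummary:
    """Everything reported per genotype group."""

    group: str
    n_cycles: int
    mean_profile: np.ndarray            # mean curvature matrix over cycles
    mean_offset_profile: np.ndarray     # mean tail-offset trace over cycles
    metric_mean: dict[str, float]       # per-cycle extrema, averaged (Fig-style)
    metric_sd: dict[str, float]
    profile_extrema: dict[str, float] = field(default_factory=dict)  # extrema of the mean profile
    relative_mean: dict[str, float] = field(default_factory=dict)
    ttest: dict[str, TTestResult] = field(default_factory=dict)


METRIC_NAMES = ("max_curvature", "min_tail_offset", "travel_distance")


# ---------------------------------------------------------------------------
# cycle segmentation

def load_cycle_annotations(
    path, n_frames: int | None = None, fish_id: str = "", group: str = ""
) -> list[WaveCycle]:
    """Read cycle annotations: CSV rows ``fish_id,start_frame,end_frame``.

    Frames are 0-based and inclusive.  A two-column file (start, end) is
    accepted, taking ``fish_id`` from the argument.  Overlapping
    intervals are allowed with a warning; an interval beyond
    ``n_frames`` is an error.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        log.warning("%s: empty annotation file", path)
        return []
    if df.columns.size >= 3 and str(df.columns[0]).strip() in ("fish_id", "fish"):
        rows = [(str(r[0]), r[1], r[2]) for r in df.itertuples(index=False)]
    elif df.columns.size == 2:
        # headerless two-column file: pandas used the first row as header
        first = [df.columns[0], df.columns[1]]
        rows = [(fish_id, first[0], first[1])]
        rows += [(fish_id, r[0], r[1]) for r in df.itertuples(index=False)]
    else:
        raise AnnotationError(f"{path}: expected 2 or 3 columns, got {df.columns.size}")
    cycles = []
    for i, (fid, start, end) in enumerate(rows):
        try:
            start, end = int(start), int(end)
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"{path}: row {i + 1}: non-integer frame: {exc}") from exc
        if start < 0:
            raise AnnotationError(f"{path}: row {i + 1}: negative start frame")
        if n_frames is not None and end >= n_frames:
            raise AnnotationError(
                f"{path}: row {i + 1}: end frame {end} beyond video length {n_frames}"
            )
        cycles.append(WaveCycle(fid or fish_id, group, start, end))
    spans = sorted((c.start_frame, c.end_frame) for c in cycles)
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            log.warning("%s: overlapping cycle annotations (%d-%d and %d-...)", path, s1, e1, s2)
    return cycles


def detect_cycles_auto(
    tail_offset_series: np.ndarray,
    cfg: RunConfig,
    fish_id: str = "",
    group: str = "",
) -> list[WaveCycle]:
    """Split a clip into cycles at maxima of the smoothed tail-offset trace.

    The tail offset is largest when the body is straightest, so
    consecutive maxima bracket exactly one straight->bent->straight
    episode.  Endpoints that are themselves local maxima (the clip
    starts or ends straight) count as cycle boundaries.
    """
    series = np.asarray(tail_offset_series, float)
    if len(series) < 2 * cfg.cycle_target_length:
        raise CycleError(
            f"series of {len(series)} frames too short for cycle detection"
        )
    smoothed = smooth_series(series, cfg.temporal_cutoff)
    if np.ptp(smoothed) <= 1e-9:
        return []
    peaks, _ = signal.find_peaks(smoothed, prominence=cfg.peak_prominence)
    peaks = list(peaks)
    tol = 1e-9 * max(np.ptp(smoothed), 1.0)
    if 0 not in peaks and smoothed[0] > smoothed[1] + tol:
        peaks.insert(0, 0)
    last = len(smoothed) - 1
    if last not in peaks and smoothed[last] > smoothed[last - 1] + tol:
        peaks.append(last)
    return [
        WaveCycle(fish_id, group, int(a), int(b))
        for a, b in zip(peaks, peaks[1:])
    ]


def normalize_cycle_frames(
    start: int, end: int, target: int, n_frames: int
) -> np.ndarray:
    """Map a cycle span onto exactly ``target`` frame indices.

    Longer spans are subsampled uniformly (index k = start +
    round(k*(len-1)/(target-1)), round half away from zero), so the
    selected frames are not contiguous.  Shorter spans are extended with
    contiguous frames before/after the span, split as evenly as
    possible with the odd frame going after; when one side hits the
    video bounds the other side supplies the remainder.
    """
    if target < 2:
        raise ConfigError("target cycle length must be >= 2")
    if start < 0 or end >= n_frames:
        raise CycleError(f"cycle [{start}, {end}] outside video of {n_frames} frames")
    span = end - start + 1
    if span == target:
        return np.arange(start, end + 1)
    if span > target:
        k = np.arange(target)
        idx = start + np.floor(k * (span - 1) / (target - 1) + 0.5).astype(int)
        # collapse any duplicates produced by rounding onto the next free index
        for i in range(1, target):
            if idx[i] <= idx[i - 1]:
                idx[i] = idx[i - 1] + 1
        if idx[-1] > end:
            raise CycleError("rounding overflow while subsampling cycle")
        return idx
    deficit = target - span
    before = deficit // 2
    after = deficit - before
    avail_before, avail_after = start, n_frames - 1 - end
    if before > avail_before:
        after += before - avail_before
        before = avail_before
    if after > avail_after:
        before += after - avail_after
        after = avail_after
    if before > avail_before:
        raise CycleError(
            f"cannot extend cycle [{start}, {end}] to {target} frames "
            f"within a {n_frames}-frame video"
        )
    return np.arange(start - before, end + after + 1)


# ---------------------------------------------------------------------------
# smoothing

def _butter_lowpass(x: np.ndarray, cutoff: float, axis: int) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass along ``axis``.

    ``cutoff`` is a normalized frequency in (0, 0.5] with 0.5 = Nyquist;
    a cutoff at Nyquist is the identity.
    """
    if not 0.0 < cutoff <= 0.5:
        raise ConfigError(f"cutoff must be in (0, 0.5], got {cutoff}")
    x = np.asarray(x, float)
    if cutoff == 0.5:
        return x.copy()
    n = x.shape[axis]
    b, a = signal.butter(4, 2.0 * cutoff)
    padlen = min(3 * max(len(a), len(b)), n - 2)
    # even-reflection padding keeps edge transients small for the short
    # (20-30 sample) profiles smoothed here
    return signal.filtfilt(b, a, x, axis=axis, padtype="even", padlen=max(padlen, 0))


def smooth_spatial(C: np.ndarray, cutoff: float) -> np.ndarray:
    """Low-pass each column (one frame's curvature along the body)."""
    C = np.asarray(C, float)
    if C.shape[0] < 5:
        raise ValueError("need at least 5 body locations for spatial smoothing")
    return _butter_lowpass(C, cutoff, axis=0)


def smooth_temporal(C: np.ndarray, cutoff: float) -> np.ndarray:
    """Low-pass each row (one body location's curvature across frames)."""
    return _butter_lowpass(np.asarray(C, float), cutoff, axis=-1)


def smooth_series(series: np.ndarray, cutoff: float) -> np.ndarray:
    """Low-pass a 1-D time series (tail offset, centroid coordinate)."""
    return _butter_lowpass(np.asarray(series, float), cutoff, axis=-1)


# ---------------------------------------------------------------------------
# per-cycle products

def cycle_curvature_matrix(
    frame_metrics: dict[int, PostureMetrics],
    cycle: WaveCycle,
    cfg: RunConfig,
) -> CurvatureProfile:
    """Assemble and smooth the curvature matrix C for one cycle.

    Column j is the curvature profile at the j-th normalized frame.
    Spatial then temporal low-pass smoothing is applied; tiny negative
    excursions from filter ringing are clipped to honour the unsigned-
    curvature convention.
    """
    if cycle.normalized_frames is None:
        raise CycleError("cycle has no normalized frame indices")
    cols = []
    for f in cycle.normalized_frames:
        pm = frame_metrics.get(int(f))
        if pm is None:
            raise CycleError(f"no posture at frame {f}; cycle rejected")
        cols.append(pm.curvature)
    C = np.column_stack(cols)
    C = smooth_spatial(C, cfg.spatial_cutoff)
    C = smooth_temporal(C, cfg.temporal_cutoff)
    return CurvatureProfile(C=np.clip(C, 0.0, None))


def cycle_tail_offsets(
    frame_metrics: dict[int, PostureMetrics], cycle: WaveCycle, cfg: RunConfig
) -> np.ndarray:
    """Smoothed tail-offset trace over the cycle's normalized frames."""
    vals = []
    for f in cycle.normalized_frames:
        pm = frame_metrics.get(int(f))
        if pm is None:
            raise CycleError(f"no posture at frame {f}; cycle rejected")
        vals.append(pm.tail_offset)
    return smooth_series(np.asarray(vals), cfg.temporal_cutoff)


def cycle_extrema(
    profile: CurvatureProfile,
    offsets: np.ndarray,
    centroids: np.ndarray,
    travel_mode: str = "path",
) -> CycleMetrics:
    """The three per-cycle scalars: max curvature, min tail offset, travel.

    Curvature and tail offset extrema are taken after smoothing; travel
    distance is the centroid path over the cycle's original span.
    """
    return CycleMetrics(
        max_curvature=float(np.max(profile.C)),
        min_tail_offset=float(np.min(offsets)),
        travel_distance=travel_distance(centroids, mode=travel_mode),
    )


# ---------------------------------------------------------------------------
# group level

def average_group_profiles(
    profiles: list[CurvatureProfile], offsets: list[np.ndarray], group: str
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean curvature matrix and tail-offset trace of a group."""
    if not profiles:
        raise ValueError(f"group {group!r} has no cycles to average")
    shapes = {p.C.shape for p in profiles}
    if len(shapes) > 1:
        raise ValueError(f"group {group!r}: mixed profile shapes {shapes}")
    mean_C = np.mean([p.C for p in profiles], axis=0)
    mean_off = np.mean(offsets, axis=0)
    return mean_C, mean_off


def normalize_to_wildtype(
    metrics_by_group: dict[str, list[CycleMetrics]], wildtype: str
) -> dict[str, dict[str, float]]:
    """Relative metric means: each group divided by the wild-type mean.

    The wild-type group's relative mean is 1 by construction.
    """
    if wildtype not in metrics_by_group:
        raise ValueError(f"wild-type group {wildtype!r} not present")
    wt_means = {
        name: float(np.mean([getattr(m, name) for m in metrics_by_group[wildtype]]))
        for name in METRIC_NAMES
    }
    for name, v in wt_means.items():
        if v == 0:
            raise ValueError(f"wild-type mean of {name} is zero; cannot normalize")
    out = {}
    for group, mlist in metrics_by_group.items():
        out[group] = {
            name: float(np.mean([getattr(m, name) for m in mlist])) / wt_means[name]
            for name in METRIC_NAMES
        }
    return out


def compare_groups(
    group_values,
    wildtype_values,
    alpha: float = 0.05,
    equal_variance: bool = True,
) -> TTestResult:
    """Two-sided two-sample Student t-test of a group against wild-type.

    Pooled-variance (classical Student) by default; Welch with
    ``equal_variance=False``.  Degenerate zero-variance inputs are
    resolved explicitly: equal means give t = 0, p = 1; unequal means
    are reported significant with p below the smallest positive float.
    """
    x = np.asarray(group_values, float)
    y = np.asarray(wildtype_values, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    nx, ny = len(x), len(y)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if equal_variance:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        se = np.sqrt(vx / nx + vy / ny)
        if se > 0:
            df = (vx / nx + vy / ny) ** 2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
        else:
            df = nx + ny - 2
    if se == 0.0:
        if mx == my:
            return TTestResult(t=0.0, p=1.0, significant=False)
        return TTestResult(
            t=float(np.sign(mx - my)) * np.inf,
            p=float(np.nextafter(0.0, 1.0)),
            significant=True,
        )
    t = float((mx - my) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=t, p=p, significant=bool(p < alpha))


def summarize_group(
    group: str,
    profiles: list[CurvatureProfile],
    offsets: list[np.ndarray],
    metrics: list[CycleMetrics],
) -> GroupSummary:
    """Collect per-group means: profiles plus per-cycle extrema statistics.

    Both orders of operation are reported: extrema of the averaged
    profile (``profile_extrema``) and the mean of per-cycle extrema
    (``metric_mean``); the group comparison uses the latter.
    """
    mean_C, mean_off = average_group_profiles(profiles, offsets, group)
    values = {n: np.array([getattr(m, n) for m in metrics]) for n in METRIC_NAMES}
    return GroupSummary(
        group=group,
        n_cycles=len(metrics),
        mean_profile=mean_C,
        mean_offset_profile=mean_off,
        metric_mean={n: float(v.mean()) for n, v in values.items()},
        metric_sd={n: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for n, v in values.items()},
        profile_extrema={
            "max_curvature_of_mean_profile": float(mean_C.max()),
            "min_tail_offset_of_mean_profile": float(mean_off.min()),
        },
    )
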