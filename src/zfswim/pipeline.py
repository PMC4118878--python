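"""End-to-end analysis: video -> per-cycle metrics -> group comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cycles as cyc
from .config import RunConfig
from .errors import CycleError, PostureError, ZfswimError
from .io import FrameSequence
from .kinematics import PostureMetrics, posture_metrics
from .posture import posture_from_mask
from .segmentation import centroid_trajectory, track_sequence

log = logging.getLogger(__name__)


@dataclass
class VideoAnalysis:
    """Everything extracted from one fish's clip."""

    fish_id: str
    group: str
    n_frames: int
    n_detected: int
    frame_metrics: dict[int, PostureMetrics]
    centroids: np.ndarray                       # (T, 2), NaN where undetected
    cycles: list[cyc.WaveCycle]
    profiles: list[cyc.CurvatureProfile]
    offsets: list[np.ndarray]
    metrics: list[cyc.CycleMetrics]
    rejected: list[tuple[cyc.WaveCycle, str]] = field(default_factory=list)


@dataclass
class CohortResult:
    """Group-level products of a cohort run."""

    per_video: list[VideoAnalysis]
    summaries: dict[str, cyc.GroupSummary]
    wildtype: str

    @property
    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for va in self.per_video:
            for i, (c, m) in enumerate(zip(va.cycles, va.metrics)):
                rows.append(
                    {
                        "fish_id": va.fish_id,
                        "group": va.group,
                        "cycle_index": i,
                        "max_curvature_deg": m.max_curvature,
                        "min_tail_offset": m.min_tail_offset,
                        "travel_distance_px": m.travel_distance,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for group, s in self.summaries.items():
            for name in cyc.METRIC_NAMES:
                row = {
                    "group": group,
                    "metric": name,
                    "n_cycles": s.n_cycles,
                    "mean": s.metric_mean[name],
                    "sd": s.metric_sd[name],
                    "relative_mean": s.relative_mean.get(name, np.nan),
                }
                tt = s.ttest.get(name)
                row.update(
                    t=tt.t if tt else np.nan,
                    p=tt.p if tt else np.nan,
                    significant=tt.significant if tt else False,
                )
                rows.append(row)
        return pd.DataFrame(rows)


def analyze_video(
    seq: FrameSequence,
    cycle_spans: list[tuple[int, int]] | list[cyc.WaveCycle],
    cfg: RunConfig,
    fish_id: str = "",
    group: str = "",
) -> VideoAnalysis:
    """Run segmentation, posture and cycle analysis on one clip.

    The background and the centroid trajectory come from every frame;
    posture (skeleton + control points) is only extracted on the frames
    that cycles actually use.  Cycles whose frames lack a usable posture
    are rejected with a reason rather than aborting the video.
    """
    masks = track_sequence(seq, cfg)
    centroids = centroid_trajectory(masks)
    n_detected = int(sum(m is not None for m in masks))

    wave_cycles: list[cyc.WaveCycle] = []
    for c in cycle_spans:
        if isinstance(c, cyc.WaveCycle):
            wc = cyc.WaveCycle(c.fish_id or fish_id, c.group or group, c.start_frame, c.end_frame)
        else:
            wc = cyc.WaveCycle(fish_id, group, int(c[0]), int(c[1]))
        wave_cycles.append(wc)

    rejected: list[tuple[cyc.WaveCycle, str]] = []
    pending: list[cyc.WaveCycle] = []
    needed: set[int] = set()
    for wc in wave_cycles:
        try:
            wc.normalized_frames = cyc.normalize_cycle_frames(
                wc.start_frame, wc.end_frame, cfg.cycle_target_length, len(seq)
            )
        except CycleError as exc:
            rejected.append((wc, str(exc)))
            continue
        pending.append(wc)
        needed.update(int(f) for f in wc.normalized_frames)

    frame_metrics: dict[int, PostureMetrics] = {}
    prev = None
    for f in sorted(needed):
        mask = masks[f]
        if mask is None:
            continue
        try:
            cp = posture_from_mask(mask, n=cfg.n_control_points, prev=prev)
        except PostureError as exc:
            log.warning("%s: frame %d posture failed: %s", fish_id, f, exc)
            continue
        prev = cp
        frame_metrics[f] = posture_metrics(cp, mask)

    ok_cycles, profiles, offsets, metrics = [], [], [], []
    for wc in pending:
        try:
            profile = cyc.cycle_curvature_matrix(frame_metrics, wc, cfg)
            offs = cyc.cycle_tail_offsets(frame_metrics, wc, cfg)
            span_centroids = centroids[wc.start_frame : wc.end_frame + 1]
            m = cyc.cycle_extrema(profile, offs, span_centroids, cfg.travel_mode)
        except (CycleError, ZfswimError) as exc:
            rejected.append((wc, str(exc)))
            continue
        ok_cycles.append(wc)
        profiles.append(profile)
        offsets.append(offs)
        metrics.append(m)
    for wc, reason in rejected:
        log.warning("%s: cycle [%d, %d] rejected: %s", fish_id, wc.start_frame, wc.end_frame, reason)

    return VideoAnalysis(
        fish_id=fish_id,
        group=group,
        n_frames=len(seq),
        n_detected=n_detected,
        frame_metrics=frame_metrics,
        centroids=centroids,
        cycles=ok_cycles,
        profiles=profiles,
        offsets=offsets,
        metrics=metrics,
        rejected=rejected,
    )


def summarize_cohort(
    analyses: list[VideoAnalysis], cfg: RunConfig, wildtype: str = "wildtype"
) -> CohortResult:
    """Aggregate per-video results into group summaries and comparisons.

    Profiles and per-cycle extrema are pooled over all cycles of all
    fish within a group (set ``cfg.per_fish_averaging`` to average per
    fish first).  Metric means are normalized by the wild-type mean and
    every non-wild-type group is tested against wild-type per metric
    with a two-sided Student t-test at ``cfg.alpha``.
    """
    by_group: dict[str, dict] = {}
    for va in analyses:
        g = by_group.setdefault(
            va.group, {"profiles": [], "offsets": [], "metrics": []}
        )
        g["profiles"].extend(va.profiles)
        g["offsets"].extend(va.offsets)
        g["metrics"].extend(va.metrics)

    if not by_group:
        raise ZfswimError("no analyzable videos")
    if wildtype not in by_group:
        raise ZfswimError(f"wild-type group {wildtype!r} not found in {sorted(by_group)}")

    summaries = {
        group: cyc.summarize_group(group, d["profiles"], d["offsets"], d["metrics"])
        for group, d in by_group.items()
    }

    metric_values = {
        group: _metric_arrays(d["metrics"], analyses, group, cfg)
        for group, d in by_group.items()
    }
    relative = cyc.normalize_to_wildtype(
        {g: d["metrics"] for g, d in by_group.items()}, wildtype
    )
    for group, s in summaries.items():
        s.relative_mean = relative[group]
        if group == wildtype:
            continue
        for name in cyc.METRIC_NAMES:
            s.ttest[name] = cyc.compare_groups(
                metric_values[group][name],
                metric_values[wildtype][name],
                alpha=cfg.alpha,
                equal_variance=cfg.equal_variance,
            )
    return CohortResult(per_video=analyses, summaries=summaries, wildtype=wildtype)


def _metric_arrays(metrics, analyses, group, cfg) -> dict[str, np.ndarray]:
    if not cfg.per_fish_averaging:
        return {
            n: np.array([getattr(m, n) for m in metrics]) for n in cyc.METRIC_NAMES
        }
    out: dict[str, list] = {n: [] for n in cyc.METRIC_NAMES}
    for va in analyses:
        if va.group != group or not va.metrics:
            continue
        for n in cyc.METRIC_NAMES:
            out[n].append(float(np.mean([getattr(m, n) for m in va.metrics])))
    return {n: np.array(v) for n, v in out.items()}
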