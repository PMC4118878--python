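"""Parametric undulatory swimmer with exact ground truth.

Renders top-view clips of a dark, elongated fish on a light static
background executing a traveling body wave, the way an adult zebrafish
appears to a high-speed camera above the tank.  The midline is analytic,
so every rendered frame comes with its true 20-point posture, curvature,
tail offset and centroid — which is what makes the whole analysis
pipeline testable without recordings.

Model: in the body frame (arc coordinate u from head 0 to tail L) the
lateral displacement is

    y(u, t) = stiffness * amplitude * (u/L) * sin(2*pi*(u/(lambda*L) - f*t))

i.e. a wave traveling head-to-tail under a linearly growing amplitude
envelope, the carangiform pattern where the head barely yaws and the
tail sweeps widest.  The body is rigidly transported at constant speed
along the heading.  The "stiff" phenotype is a pure amplitude reduction
(stiffness < 1): the minimal knob that lowers curvature, raises tail
offset and — in a real fish — shortens the distance covered per beat.

A body-waving cycle (straight -> bent -> straight) corresponds to half
a beat period: the body shape at t + 1/(2f) is the mirror image of the
shape at t, so the bend magnitude repeats every half period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import FrameSequence, write_video

#: Half-width profile along the body: (arc fraction, half-width px).
#: Blunt head, widest at the trunk, tapering to a thin caudal peduncle.
DEFAULT_WIDTH_PROFILE = ((0.0, 3.0), (0.08, 6.0), (0.35, 7.0), (1.0, 1.5))


@dataclass
class SwimmerParams:
    """Geometry, wave, phenotype and imaging parameters of one swimmer.

    Defaults emulate the recording conditions the pipeline targets:
    480x640 px top view at 250 frames/s, an adult fish of ~140 px body
    length beating at 4 Hz and cruising at ~1.4 body lengths per second.
    """

    body_length: float = 140.0            # px, chord of the undulating midline
    width_profile: tuple = DEFAULT_WIDTH_PROFILE
    amplitude: float = 16.0               # px, tail-tip lateral amplitude
    wavelength: float = 0.95              # body lengths per wave
    beat_frequency: float = 4.0           # Hz (full left+right beat)
    speed: float = 200.0                  # px/s along the heading at stiffness 1
    heading: float = 0.0                  # degrees, 0 = +x, y down
    stiffness: float = 1.0                # in (0, 1]; scales amplitude
    background_intensity: int = 200
    fish_intensity: int = 60
    noise_sd: float = 2.0                 # additive Gaussian, intensity units
    frame_rate: float = 250.0
    frame_count: int = 400
    image_size: tuple[int, int] = (480, 640)   # (height, width)
    start: tuple[float, float] | None = None   # head position at t=0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if not 0.0 < self.stiffness <= 1.0:
            raise ConfigError("stiffness must be in (0, 1]")
        if self.frame_rate <= 0 or self.frame_count < 1:
            raise ConfigError("frame_rate and frame_count must be positive")
        contrast = self.background_intensity - self.fish_intensity
        if contrast < 3 * self.noise_sd:
            raise ConfigError(
                f"fish must be darker than background by >= 3x noise SD "
                f"(contrast {contrast}, noise {self.noise_sd})"
            )

    @property
    def half_period_frames(self) -> float:
        """Frames per body-waving cycle (half a beat period)."""
        return self.frame_rate / (2.0 * self.beat_frequency)

    @property
    def effective_speed(self) -> float:
        """Translation speed, px/s.

        Undulatory thrust scales with tail-beat amplitude, so a stiff
        fish (reduced amplitude) also covers less ground: the nominal
        ``speed`` is scaled by the stiffness factor.
        """
        return self.speed * self.stiffness

    def half_widths(self, u: np.ndarray) -> np.ndarray:
        """Half-width (px) at arc fraction u in [0, 1]."""
        xp, fp = zip(*self.width_profile)
        return np.interp(u, xp, fp)


@dataclass
class GroundTruth:
    """Per-frame analytic truth aligned with the pipeline's conventions."""

    midlines: np.ndarray      # (T, n_points, 2) arc-uniform, head first
    curvature: np.ndarray     # (T, n_points) degrees, unsigned, endpoint-padded
    tail_offset: np.ndarray   # (T,)
    centroid: np.ndarray      # (T, 2) mass centroid of the body strip
    body_length: np.ndarray   # (T,) arc length of the midline


# ---------------------------------------------------------------------------
# analytic midline

def _body_frame_midline(t: float, p: SwimmerParams, n_dense: int) -> np.ndarray:
    u = np.linspace(0.0, p.body_length, n_dense)
    y = (
        p.stiffness
        * p.amplitude
        * (u / p.body_length)
        * np.sin(2.0 * np.pi * (u / (p.wavelength * p.body_length) - p.beat_frequency * t))
    )
    return np.column_stack([u, y])


def _to_lab(body_pts: np.ndarray, t: float, p: SwimmerParams) -> np.ndarray:
    theta = np.radians(p.heading)
    c, s = np.cos(theta), np.sin(theta)
    head = np.asarray(p.start if p.start is not None else _default_start(p), float)
    head = head + p.effective_speed * t * np.array([c, s])
    # head leads: body extends backwards along the heading
    local = np.column_stack([-body_pts[:, 0], body_pts[:, 1]])
    rot = local @ np.array([[c, s], [-s, c]])
    return head + rot


def _default_start(p: SwimmerParams) -> tuple[float, float]:
    margin = max(p.half_widths(np.linspace(0, 1, 50))) + p.amplitude + 6.0
    return (p.body_length + margin, p.image_size[0] / 2.0)


def _arc_resample(pts: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    tgt = np.linspace(0.0, s[-1], n)
    out = np.column_stack([np.interp(tgt, s, pts[:, 0]), np.interp(tgt, s, pts[:, 1])])
    return out, float(s[-1])


def midline_at(
    t: float, params: SwimmerParams, n_points: int = 20, n_dense: int = 2000
) -> np.ndarray:
    """Lab-frame midline at time t, resampled to n arc-uniform points."""
    dense = _to_lab(_body_frame_midline(t, params, n_dense), t, params)
    pts, _ = _arc_resample(dense, n_points)
    return pts


def _strip_centroid(dense: np.ndarray, p: SwimmerParams) -> np.ndarray:
    """Mass centroid of the variable-width body strip (mass ~ 2*w per ds)."""
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    ds = np.concatenate([[seg[0]], (seg[:-1] + seg[1:]) / 2.0, [seg[-1]]])
    s = np.concatenate([[0.0], np.cumsum(seg)])
    w = p.half_widths(s / s[-1])
    m = 2.0 * w * ds
    return (m[:, None] * dense).sum(axis=0) / m.sum()


def _discrete_curvature(pts: np.ndarray) -> np.ndarray:
    ang = np.degrees(np.arctan2(*np.diff(pts, axis=0).T[::-1]))
    d = np.abs((np.diff(ang) + 180.0) % 360.0 - 180.0)
    return np.concatenate([[d[0]], d, [d[-1]]])


def ground_truth_at(t: float, p: SwimmerParams, n_points: int = 20) -> dict:
    """Analytic posture truth for one instant."""
    dense = _to_lab(_body_frame_midline(t, p, 2000), t, p)
    pts, L = _arc_resample(dense, n_points)
    centroid = _strip_centroid(dense, p)
    return {
        "midline": pts,
        "curvature": _discrete_curvature(pts),
        "tail_offset": float(np.linalg.norm(pts[-1] - centroid) / L),
        "centroid": centroid,
        "body_length": L,
    }


# ---------------------------------------------------------------------------
# rendering

def render_frame(
    midline_dense: np.ndarray,
    params: SwimmerParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rasterize one frame: union of disks along the midline, plus noise.

    The disk radius at each midline sample follows the width profile.
    Raises when the body (including its width) leaves the image, because
    a clipped silhouette would silently corrupt the ground truth.
    """
    h, w = params.image_size
    seg = np.linalg.norm(np.diff(midline_dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    radii = params.half_widths(s / s[-1])
    lo = (midline_dense - radii[:, None]).min(axis=0)
    hi = (midline_dense + radii[:, None]).max(axis=0)
    if lo[0] < 0 or lo[1] < 0 or hi[0] > w - 1 or hi[1] > h - 1:
        raise ConfigError(
            "swimmer leaves the image; reduce speed/frame_count or enlarge the image"
        )
    frame = np.full((h, w), params.background_intensity, np.float64)
    fish = np.zeros((h, w), bool)
    for (cx, cy), r in zip(midline_dense, radii):
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        fish[y0:y1, x0:x1] |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    frame[fish] = params.fish_intensity
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        frame += rng.normal(0.0, params.noise_sd, frame.shape)
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)


def generate_video(
    params: SwimmerParams, n_points: int = 20
) -> tuple[FrameSequence, GroundTruth]:
    """Render a full clip and its per-frame ground truth."""
    rng = np.random.default_rng(params.seed)
    n_dense = max(int(params.body_length / 0.7), 50)
    frames, mids, curvs, offs, cents, lens = [], [], [], [], [], []
    for i in range(params.frame_count):
        t = i / params.frame_rate
        dense = _to_lab(_body_frame_midline(t, params, 2000), t, params)
        gt_pts, L = _arc_resample(dense, n_points)
        render_pts, _ = _arc_resample(dense, n_dense)
        frames.append(render_frame(render_pts, params, rng))
        mids.append(gt_pts)
        curvs.append(_discrete_curvature(gt_pts))
        cents.append(_strip_centroid(dense, params))
        offs.append(np.linalg.norm(gt_pts[-1] - cents[-1]) / L)
        lens.append(L)
    seq = FrameSequence(
        np.stack(frames), params.frame_rate, source_id=f"synthetic(seed={params.seed})"
    )
    gt = GroundTruth(
        midlines=np.stack(mids),
        curvature=np.stack(curvs),
        tail_offset=np.asarray(offs),
        centroid=np.stack(cents),
        body_length=np.asarray(lens),
    )
    return seq, gt


def cycle_annotation(params: SwimmerParams, n_cycles: int) -> list[tuple[int, int]]:
    """Consecutive half-beat spans [start, end] (inclusive) from frame 0."""
    p2 = params.half_period_frames
    spans = []
    for i in range(n_cycles):
        start = int(np.ceil(i * p2))
        end = int(np.ceil((i + 1) * p2)) - 1
        if end >= params.frame_count:
            raise ConfigError(
                f"{n_cycles} cycles need {end + 1} frames, video has {params.frame_count}"
            )
        spans.append((start, end))
    return spans


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class FishRecording:
    fish_id: str
    group: str
    params: SwimmerParams
    sequence: FrameSequence
    ground_truth: GroundTruth
    cycles: list[tuple[int, int]]


@dataclass
class Cohort:
    fish: list[FishRecording] = field(default_factory=list)

    @property
    def annotation_rows(self) -> pd.DataFrame:
        rows = [
            {"fish_id": f.fish_id, "start_frame": a, "end_frame": b}
            for f in self.fish
            for a, b in f.cycles
        ]
        return pd.DataFrame(rows)

    @property
    def group_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"fish_id": f.fish_id, "group": f.group} for f in self.fish]
        )


def generate_cohort(
    n_fish: int,
    cycles_per_fish: int,
    normal_params: SwimmerParams,
    stiff_params: SwimmerParams,
    seed: int = 0,
    groups: tuple[str, str] = ("wildtype", "stiff"),
) -> Cohort:
    """Two groups of n_fish swimmers each with annotated cycles.

    The clip is long enough both for the requested cycles and for the
    fish to travel well over a body length, which keeps the temporal-
    median background free of fish (no pixel is occupied in most
    frames).  All randomness derives from ``seed``.
    """
    cohort = Cohort()
    for gi, (group, base) in enumerate(zip(groups, (normal_params, stiff_params))):
        for fi in range(n_fish):
            p = fit_frame_count(base, cycles_per_fish)
            p = replace(p, seed=int((seed * 1000003 + gi * 101 + fi) % (2**31)))
            seq, gt = generate_video(p)
            cohort.fish.append(
                FishRecording(
                    fish_id=f"{group}_{fi:02d}",
                    group=group,
                    params=p,
                    sequence=seq,
                    ground_truth=gt,
                    cycles=cycle_annotation(p, cycles_per_fish),
                )
            )
    return cohort


def fit_frame_count(p: SwimmerParams, n_cycles: int) -> SwimmerParams:
    """Copy of ``p`` with a frame count long enough for clean analysis."""
    need_cycles = int(np.ceil((n_cycles + 0.2) * p.half_period_frames))
    # the body passes over any one pixel for ~L/speed seconds; the clip must
    # be >2x that so the temporal median at every pixel is background
    need_background = int(np.ceil(2.2 * p.body_length / p.effective_speed * p.frame_rate))
    return replace(p, frame_count=max(need_cycles, need_background))


def save_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write videos (uncompressed AVI), ground truth, annotation, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for f in cohort.fish:
        video = outdir / f"{f.fish_id}.avi"
        write_video(video, f.sequence)
        paths[f.fish_id] = video
        gt = f.ground_truth
        n = gt.midlines.shape[1]
        df = pd.DataFrame(
            {
                "frame": np.arange(len(gt.tail_offset)),
                **{f"x{i}": gt.midlines[:, i, 0] for i in range(n)},
                **{f"y{i}": gt.midlines[:, i, 1] for i in range(n)},
                "tail_offset": gt.tail_offset,
                "centroid_x": gt.centroid[:, 0],
                "centroid_y": gt.centroid[:, 1],
                "body_length": gt.body_length,
            }
        )
        df.to_csv(outdir / f"{f.fish_id}_truth.csv", index=False)
    cohort.annotation_rows.to_csv(outdir / "cycles.csv", index=False)
    cohort.group_manifest.to_csv(outdir / "groups.csv", index=False)
    return paths
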