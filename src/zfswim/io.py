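"""Video input, tabular output and the frame-sequence container."""

from __future__ import annotations

import glob as _glob
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import avi
from .errors import DecodeError, EmptyInputError

#: Column order of the per-cycle metrics table; kept stable so downstream
#: tooling can rely on it.
METRICS_COLUMNS = [
    "fish_id",
    "group",
    "cycle_index",
    "max_curvature_deg",
    "min_tail_offset",
    "travel_distance_px",
]


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames plus acquisition metadata.

    ``frames`` is a (T, H, W) uint8 array; the coordinate convention
    throughout the package is origin at the top-left pixel center, x
    rightward (columns), y downward (rows), 0-based indices.
    """

    frames: np.ndarray
    frame_rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise EmptyInputError("a FrameSequence needs at least one 2-D frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to 8-bit luma (ITU-R 601); pass gray through."""
    if img.ndim == 2:
        if img.dtype != np.uint8:
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        return img
    rgb = img[..., :3].astype(np.float64)
    return avi._luminance(rgb[..., 0], rgb[..., 1], rgb[..., 2])


def read_video(path: str | Path, expected_rate: float | None = None) -> FrameSequence:
    """Read an uncompressed AVI, a directory, or a glob of numbered frames.

    Image sequences (PNG/TIFF) carry no rate metadata, so ``expected_rate``
    is required for them; for AVI the container rate is used unless
    ``expected_rate`` overrides it.
    """
    spath = str(path)
    if any(c in spath for c in "*?[") :
        files = sorted(_glob.glob(spath))
        return _read_image_sequence(files, spath, expected_rate)
    p = Path(path)
    if p.is_dir():
        files = sorted(
            str(f) for f in p.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff")
        )
        return _read_image_sequence(files, spath, expected_rate)
    if not p.exists():
        raise DecodeError(f"{path}: no such file")
    if p.suffix.lower() == ".avi":
        frames, rate = avi.read_avi(p)
        if expected_rate is not None:
            rate = expected_rate
        return FrameSequence(frames, rate, source_id=spath)
    # single image file: a 1-frame sequence
    return _read_image_sequence([spath], spath, expected_rate)


def _read_image_sequence(files: list[str], source: str, rate: float | None) -> FrameSequence:
    if not files:
        raise EmptyInputError(f"{source}: no frames found")
    if rate is None:
        raise DecodeError(
            f"{source}: image sequences carry no frame rate; pass expected_rate"
        )
    try:
        frames = [to_grayscale(iio.imread(f)) for f in files]
    except (OSError, ValueError) as exc:
        raise DecodeError(f"{source}: {exc}") from exc
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise DecodeError(f"{source}: frames differ in size: {sorted(shapes)}")
    return FrameSequence(np.stack(frames), rate, source_id=source)


def write_video(path: str | Path, seq: FrameSequence) -> None:
    """Write a sequence as uncompressed grayscale AVI (lossless for uint8)."""
    avi.write_avi(path, seq.frames, seq.frame_rate)


def write_image_sequence(outdir: str | Path, seq: FrameSequence, stem: str = "frame") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(seq.frames):
        p = outdir / f"{stem}_{i:05d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def sequence_duration(seq: FrameSequence) -> float:
    """Clip duration in seconds: frame count over frame rate."""
    return len(seq) / seq.frame_rate


def write_metrics(records: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Write the per-cycle metrics table as CSV with a fixed column order.

    Raises on empty input: an empty metrics file almost always means an
    upstream failure and should not look like a successful run.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise EmptyInputError("refusing to write an empty metrics table")
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table missing columns: {missing}")
    extra = [c for c in df.columns if c not in METRICS_COLUMNS]
    df[METRICS_COLUMNS + extra].to_csv(path, index=False)
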