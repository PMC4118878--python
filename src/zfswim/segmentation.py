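"""Background modelling and fish silhouette segmentation.

The fish is found by classical background subtraction: the background is
the per-pixel temporal median of the clip (valid because the tank is
static and the fish keeps moving), and the fish in each frame is the
largest connected component of the thresholded absolute difference
image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .config import RunConfig
from .errors import TrackingError
from .io import FrameSequence

log = logging.getLogger(__name__)

_STRUCT3 = np.ones((3, 3), bool)


@dataclass
class BackgroundModel:
    """Per-pixel temporal median of a clip."""

    background: np.ndarray


@dataclass
class FishMask:
    """Binary silhouette of the fish in one frame.

    ``centroid`` is the unweighted mean of foreground pixel coordinates,
    in (x, y) = (column, row) order.
    """

    frame_index: int
    mask: np.ndarray
    centroid: tuple[float, float]
    area: int


def compute_background(seq: FrameSequence) -> BackgroundModel:
    """Median background frame.

    For an even number of frames the lower median (index ``(n-1)//2`` of
    the sorted series) is used, which keeps every background pixel an
    actually observed intensity and the raster integer-typed.
    """
    frames = seq.frames
    k = (len(frames) - 1) // 2
    bg = np.partition(frames, k, axis=0)[k]
    return BackgroundModel(background=bg)


def segment_fish(
    frame: np.ndarray, bg: BackgroundModel, cfg: RunConfig, frame_index: int = 0
) -> FishMask | None:
    """Segment the fish in one frame; ``None`` when nothing qualifies.

    Pipeline: absolute difference against the background, global
    threshold, one binary opening then closing with a 3x3 element (to
    drop sensor speckle without eroding the tail), 8-connected component
    labelling, then the largest component with area >= ``cfg.min_area``.
    Ties are broken by the component whose first foreground pixel comes
    earliest in row-major order.
    """
    if frame.shape != bg.background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {bg.background.shape}"
        )
    diff = np.abs(frame.astype(np.int16) - bg.background.astype(np.int16))
    fg = diff > cfg.threshold
    fg = ndimage.binary_opening(fg, structure=_STRUCT3)
    fg = ndimage.binary_closing(fg, structure=_STRUCT3)
    labels, nlab = measure.label(fg, connectivity=2, return_num=True)
    if nlab == 0:
        return None
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    best = 0
    best_area = 0
    flat = labels.ravel()
    for lab in range(1, nlab + 1):
        a = areas[lab]
        if a < cfg.min_area or a < best_area:
            continue
        if a > best_area:
            best, best_area = lab, a
        else:  # tie: earliest first pixel in row-major order wins
            if np.argmax(flat == lab) < np.argmax(flat == best):
                best = lab
    if best == 0:
        return None
    mask = labels == best
    if _touches_border(mask):
        log.warning("frame %d: fish touches the image border; centerline endpoints may be clipped", frame_index)
    ys, xs = np.nonzero(mask)
    return FishMask(
        frame_index=frame_index,
        mask=mask,
        centroid=(float(xs.mean()), float(ys.mean())),
        area=int(best_area),
    )


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def track_sequence(seq: FrameSequence, cfg: RunConfig) -> list[FishMask | None]:
    """Segment every frame against the clip's median background.

    Returns one entry per frame, ``None`` where no detection qualified
    (downstream cycle logic interpolates or rejects).  Raises
    :class:`TrackingError` when more than half the frames have no
    detection, which indicates a broken background model or threshold.
    """
    bg = compute_background(seq)
    masks = [segment_fish(f, bg, cfg, frame_index=i) for i, f in enumerate(seq.frames)]
    n_missing = sum(m is None for m in masks)
    if n_missing > len(masks) / 2:
        raise TrackingError(
            f"{n_missing}/{len(masks)} frames without detection; "
            "check threshold/min_area or background stability"
        )
    if n_missing:
        log.warning("%d/%d frames without detection", n_missing, len(masks))
    return masks


def centroid_trajectory(masks: list[FishMask | None]) -> np.ndarray:
    """(T, 2) array of centroids with NaN rows where detection failed."""
    out = np.full((len(masks), 2), np.nan)
    for i, m in enumerate(masks):
        if m is not None:
            out[i] = m.centroid
    return out
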