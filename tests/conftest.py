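"""Shared fixtures: small synthetic clips and masks, built at test time."""

import numpy as np
import pytest

from zfswim.config import RunConfig
from zfswim.segmentation import FishMask
from zfswim.synthetic import SwimmerParams, cycle_annotation, generate_video


def small_swimmer(**overrides) -> SwimmerParams:
    """A downscaled swimmer that keeps unit tests fast.

    70 px body in a 160x320 frame at 100 fps, 2 Hz beat (25-frame
    body-waving cycles), fast enough (150 px/s) that the median
    background stays clean over a short clip.
    """
    defaults = dict(
        body_length=70.0,
        width_profile=((0.0, 2.0), (0.08, 4.0), (0.35, 5.0), (1.0, 1.2)),
        amplitude=9.0,
        beat_frequency=2.0,
        speed=150.0,
        noise_sd=0.0,
        frame_rate=100.0,
        frame_count=110,
        image_size=(160, 320),
        seed=7,
    )
    defaults.update(overrides)
    return SwimmerParams(**defaults)


@pytest.fixture(scope="session")
def clip():
    """Zero-noise small clip with ground truth and 2 annotated cycles."""
    params = small_swimmer()
    seq, gt = generate_video(params)
    return {
        "params": params,
        "seq": seq,
        "gt": gt,
        "cycles": cycle_annotation(params, 2),
    }


@pytest.fixture
def cfg():
    return RunConfig()


def make_mask(mask: np.ndarray, frame_index: int = 0) -> FishMask:
    """FishMask from a raw boolean raster (tests bypass segmentation)."""
    ys, xs = np.nonzero(mask)
    return FishMask(
        frame_index=frame_index,
        mask=mask,
        centroid=(float(xs.mean()), float(ys.mean())),
        area=int(mask.sum()),
    )
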