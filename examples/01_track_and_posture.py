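"""Segment a synthetic swimmer and read off its posture, frame by frame.

Renders a short top-view clip of an undulating fish, builds the
temporal-median background, segments the silhouette in each frame and
fits the 20-point midline. Prints the per-frame measurements for a few
frames next to the generator's ground truth.
"""

import numpy as np

from zfswim import (
    RunConfig,
    compute_background,
    posture_from_mask,
    posture_metrics,
    segment_fish,
)
from zfswim.synthetic import SwimmerParams, generate_video

params = SwimmerParams(
    body_length=90.0,
    width_profile=((0.0, 2.5), (0.08, 4.5), (0.35, 5.5), (1.0, 1.5)),
    amplitude=11.0,
    speed=160.0,
    noise_sd=2.0,
    frame_rate=250.0,
    frame_count=320,
    image_size=(240, 420),
    seed=1,
)
seq, truth = generate_video(params)
cfg = RunConfig()
bg = compute_background(seq)

print(f"clip: {len(seq)} frames of {seq.height}x{seq.width} px at {seq.frame_rate} fps")
print(f"{'frame':>5} {'max K (deg)':>12} {'true K':>8} {'tail offset':>12} {'true':>6} {'centroid err (px)':>18}")
prev = None
for f in range(60, 75, 3):
    mask = segment_fish(seq[f], bg, cfg, f)
    cp = posture_from_mask(mask, n=cfg.n_control_points, prev=prev)
    prev = cp
    pm = posture_metrics(cp, mask)
    cerr = np.linalg.norm(np.asarray(mask.centroid) - truth.centroid[f])
    print(
        f"{f:>5} {pm.curvature.max():>12.2f} {truth.curvature[f].max():>8.2f} "
        f"{pm.tail_offset:>12.3f} {truth.tail_offset[f]:>6.3f} {cerr:>18.2f}"
    )

print(
    "\nmax K is the largest bending angle (degrees) between adjacent midline\n"
    "segments in that frame; tail offset is tail-to-centroid distance over body\n"
    "length (~0.5 when straight, smaller when bent). Both track the analytic\n"
    "truth to within raster noise, and the centroid lands within ~a pixel."
)
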