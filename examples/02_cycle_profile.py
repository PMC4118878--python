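"""Build the spatio-temporal curvature profile of one body-waving cycle.

Every cycle is normalized to 30 frames, so the curvature measurements
form a 20 x 30 matrix C (body locations x cycle frames) that can be
averaged across cycles and fish. This script analyzes one fish's
annotated cycles and shows how the bending wave travels head-to-tail
through C.
"""

import numpy as np

from zfswim import RunConfig, analyze_video
from zfswim.synthetic import SwimmerParams, cycle_annotation, generate_video, fit_frame_count

params = fit_frame_count(
    SwimmerParams(
        body_length=90.0,
        width_profile=((0.0, 2.5), (0.08, 4.5), (0.35, 5.5), (1.0, 1.5)),
        amplitude=11.0,
        speed=160.0,
        noise_sd=2.0,
        image_size=(240, 420),
        seed=2,
    ),
    n_cycles=3,
)
seq, truth = generate_video(params)
cycles = cycle_annotation(params, 3)
cfg = RunConfig()

analysis = analyze_video(seq, cycles, cfg, fish_id="demo", group="wildtype")
print(f"analyzed {len(analysis.cycles)} cycles, rejected {len(analysis.rejected)}")

prof = analysis.profiles[0]
print(f"\ncurvature matrix C: {prof.C.shape[0]} body locations x {prof.C.shape[1]} frames")
peak_row = prof.C.argmax(axis=0)
print("row of the curvature peak per cycle frame (head=0 ... tail=19):")
print("  ", peak_row.tolist())

for (a, b), m in zip(cycles, analysis.metrics):
    print(
        f"cycle {a:>3}-{b:<3}: max curvature {m.max_curvature:5.2f} deg, "
        f"min tail offset {m.min_tail_offset:.3f}, travel {m.travel_distance:5.1f} px"
    )

print(
    "\nthe peak row drifting toward 19 shows the bending wave propagating\n"
    "head-to-tail; the three per-cycle scalars are what the group comparison\n"
    "consumes downstream."
)
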