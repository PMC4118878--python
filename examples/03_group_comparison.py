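"""Compare a 'stiff' cohort against wild-type, the full pipeline end to end.

Simulates two groups of swimmers — normal, and a phenotype with the body
wave amplitude halved (the kinematic signature of increased muscle
stiffness) — runs tracking, posture and cycle analysis on every video,
normalizes each metric to the wild-type mean and runs Student t-tests.
"""

import dataclasses

from zfswim import RunConfig, analyze_video, summarize_cohort
from zfswim.synthetic import SwimmerParams, generate_cohort

normal = SwimmerParams(
    body_length=90.0,
    width_profile=((0.0, 2.5), (0.08, 4.5), (0.35, 5.5), (1.0, 1.5)),
    amplitude=11.0,
    speed=160.0,
    noise_sd=2.0,
    image_size=(240, 420),
)
stiff = dataclasses.replace(normal, stiffness=0.5)

cohort = generate_cohort(n_fish=2, cycles_per_fish=3, normal_params=normal,
                         stiff_params=stiff, seed=3)
cfg = RunConfig()
analyses = [
    analyze_video(f.sequence, f.cycles, cfg, fish_id=f.fish_id, group=f.group)
    for f in cohort.fish
]
result = summarize_cohort(analyses, cfg, wildtype="wildtype")

print(result.comparison_table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(
    "\nrelative_mean divides each group's mean by the wild-type mean, so\n"
    "wild-type is 1 by construction. The stiff group bends less (relative\n"
    "max curvature < 1), keeps its tail closer to straight (relative min\n"
    "tail offset > 1) and covers less ground per cycle — each contrast\n"
    "tested against wild-type with a two-sided Student t at alpha 0.05."
)
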