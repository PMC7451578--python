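"""Healthy vs degraded cohorts: find the pairs that lost their alignment.

Two 10-subject cohorts are generated from the same 20-region bilateral
template; in the second, two homotopic couplings are reduced by 80%
(emulating disease-related loss of interhemispheric connectivity). Every
subject is thresholded, embedded and converted to an all-pairs alignment
matrix; ROI pairs are screened against three independent sets of random
U(0,1) connectivity models, and the surviving pairs are Welch-tested
between groups. The degraded pairs should dominate the significant set
with direction "decrease in alignment".
"""

import numpy as np

import eigenalign as ea
from eigenalign.synthetic import STUDY_DEGRADED, bilateral_study_spec

config = ea.PipelineConfig()
healthy = ea.generate_cohort(bilateral_study_spec(0.0, seed=1))
degraded = ea.generate_cohort(bilateral_study_spec(0.8, seed=2))

angles_h = ea.angle_stack(ea.run_group(healthy, config))
angles_d = ea.angle_stack(ea.run_group(degraded, config))

# three independent null sets (200 models each keeps this demo quick;
# the full-scale screen uses 1000)
nulls = ea.random_model_null(20, 200, n_sets=3, seed=7, config=config)
mask = ea.eligible_pairs(angles_d, angles_h, nulls, alpha=0.05)
print(f"pairs surviving the random-model screen: {mask.n_eligible_pairs} / 190")

res = ea.compare_alignment(angles_d, angles_h, mask, alpha=0.05)
sig = [(i, j) for i, j in res.tested_pairs() if res.significant[i, j]]
print(f"significant alignment changes (p <= 0.05): {len(sig)}")
for i, j in sig:
    marker = " <- degraded coupling" if (i, j) in STUDY_DEGRADED else ""
    print(
        f"  ROI {i + 1:2d} - ROI {j + 1:2d}: "
        f"{res.mean_b[i, j]:.2f} -> {res.mean_a[i, j]:.2f} rad, "
        f"p = {res.p[i, j]:.2g}, {res.direction_label(i, j)} in alignment{marker}"
    )

counts = res.roi_change_counts()
top = np.argsort(counts)[::-1][:4]
print("\nregions with most significant changes:", [int(r) + 1 for r in top])
print(
    "\nAngles grew at the degraded couplings (alignment decreased): the\n"
    "screen plus Welch test recovers exactly the planted disease effect."
)
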