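"""Generate a small synthetic cohort and inspect its ground truth.

Builds five-group digital brain phantoms with group-dependent arterial
transit time (ATT) prolongation and prints the mean grey-matter ATT per
group: the configured severity gradient should be visible directly in the
ground-truth maps.
"""

import numpy as np

from aslscov import CohortConfig, simulate_cohort

config = CohortConfig(
    group_sizes={"control": 3, "scd": 3, "amci": 3, "mmci": 3, "ad": 3},
    seed=11,
)
cohort = simulate_cohort(config)

print(f"simulated {len(cohort)} subjects on a {config.grid} grid")
print("\nmean GM ATT (s) per subject:")
for phantom, meta in cohort:
    gm = phantom.pv_gm >= 0.25
    att = phantom.att_true[gm].mean()
    print(f"  {meta['id']}  {meta['group']:<8s} age {meta['age']:5.1f}  "
          f"site {meta['site']}  ATT {att:.3f}")

by_group = {}
for phantom, meta in cohort:
    gm = phantom.pv_gm >= 0.25
    by_group.setdefault(meta["group"], []).append(phantom.att_true[gm].mean())
print("\ngroup means (s):")
for g in ("control", "scd", "amci", "mmci", "ad"):
    print(f"  {g:<8s} {np.mean(by_group[g]):.3f}")
print("\nATT rises with group severity (control -> AD): the transit-delay "
      "gradient that the spatial-CoV metric is designed to detect.")
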