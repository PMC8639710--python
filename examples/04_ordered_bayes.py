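"""Order-restricted Bayesian ANCOVA on a staged-severity cohort.

Simulates per-subject GM sCoV values under the pattern
[control = scd] < mci < ad, then compares the four standard order
restrictions against the covariates-only null with encompassing-prior
Bayes factors.  The generating pattern (M2) should attain the largest BF.
"""

from aslscov import bf_order_restricted, compare_restrictions, simulate_metric_records
from aslscov.ordered_bayes import STANDARD_RESTRICTIONS

df = simulate_metric_records(
    group_sizes={"control": 75, "scd": 75, "mci": 75, "ad": 75},
    group_means={"control": 50.0, "scd": 50.0, "mci": 53.0, "ad": 56.0},
    sd=6.0,
    seed=42,
    age_effect=0.2,
    sex_effect=1.0,
    site_effects={"site_b": 1.0, "site_c": -1.0},
)
print(f"simulated n = {len(df)} subjects, metric pattern 50/50/53/56 (sd 6)")

results = []
for name, restriction in STANDARD_RESTRICTIONS.items():
    res = bf_order_restricted(df, restriction, n_samples=4000, n_chains=4, seed=7)
    results.append(res)
    print(f"{name}: {restriction}  BF vs null = {res.bf_vs_null:10.3g}  "
          f"(posterior constraint prob {res.posterior_constraint_prob:.3f}, "
          f"prior {res.prior_constraint_prob:.4f}, "
          f"Rhat {res.rhat_max:.3f})")

best = max(results, key=lambda r: r.bf_vs_null)
print(f"\npreferred model: {best.restriction}")
print("\npairwise BFs (row model vs column model):")
print(compare_restrictions(results).round(2).to_string())
print("\nBF > 1 favours the row restriction; the generating pattern wins "
      "and the equality block is correctly preferred over the fully "
      "ordered alternative.")
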