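"""Synthetic cohort generation and the morphology-plaque statistics.

Generates one 364-artery cohort with the planted angle/tortuosity effect,
prints the group-comparison table (normality-gated tests) and the
multivariate logistic regression, then checks parameter recovery across
200 replicate cohorts.
"""

from vaoflow import CohortSpec, compare_groups, fit_logistic, generate_cohort
from vaoflow.clinical import replicate_or_recovery

spec = CohortSpec(seed=42)
cohort = generate_cohort(spec)
print(f"cohort: {len(cohort)} arteries, plaque prevalence "
      f"{cohort.plaque.mean():.3f}")

print("\nGroup comparison (plaque-free vs plaque):")
print(compare_groups(cohort).to_string(index=False))

print("\nMultivariate logistic regression (OR, Wald 95% CI):")
print(fit_logistic(cohort).to_string(index=False))

rec = replicate_or_recovery(n_replicates=200, spec=spec, base_seed=2024)
print(f"\nrecovery over {len(rec)} replicates: "
      f"mean angle OR {rec.or_angle_per_10deg.mean():.3f} "
      f"(planted {spec.or_angle_per_10deg}), "
      f"CI coverage {rec.cover_angle_per_10deg.mean():.3f}")

# The planted per-10-degree angle OR (1.84) and the severe-tortuosity OR
# (2.35) should be recovered without bias and with ~95% CI coverage,
# confirming the estimation pipeline is correctly calibrated.
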