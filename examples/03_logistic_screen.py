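"""Per-region simple logistic regression screen.

For each regional feature, fits outcome ~ intercept + feature on an AD/NC
cohort (no covariates) and reports the slope, its Wald standard error and
p-value, and the AU-ROC of the fitted probabilities — the single-feature
discriminant-power table of the pipeline.
"""

import cortexfuse as cf
from cortexfuse.evaluation import logistic_screen

table, _ = cf.generate_cohort(cf.CohortSpec(
    group_sizes={"NC": 85, "AD": 71}, seed=1))

rows = logistic_screen(table, "AD", "NC")
rows.sort(key=lambda r: r.p_value)

print(f"{'region':32s} {'mod':4s} {'beta':>8s} {'SE':>6s} "
      f"{'p':>8s} {'AUROC':>6s}")
for r in rows[:10]:
    print(f"{r.region:32s} {r.modality:4s} {r.beta:8.2f} {r.se:6.2f} "
          f"{r.p_value:8.1e} {r.auc:6.3f}")
# Negative betas: patients sit lower on atrophy/hypometabolism features.
# Shifted regions dominate the top of the table; unshifted ones drift
# toward p ~ uniform and AUROC ~ 0.5.
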