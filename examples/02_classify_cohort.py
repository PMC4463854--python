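"""PLS-LDA discrimination of a synthetic AD/NC cohort with LOOCV.

Draws a cohort at the study group sizes (85 NC / 71 AD) whose patient
group carries -1.5 SD shifts on 12 of the 24 multimodal regional features,
then evaluates the full pipeline — PRESS component selection, NIPALS PLS,
pooled-covariance LDA — by leave-one-out cross-validation.
"""

import cortexfuse as cf
from cortexfuse.evaluation import loocv

table, truth = cf.generate_cohort(cf.CohortSpec(
    group_sizes={"NC": 85, "AD": 71}, seed=1))

result = loocv(table, "AD", "NC")
roc = result.roc()

print(f"subjects: {len(result.true_labels)} "
      f"(positive class: {result.positive_class})")
print(f"LOOCV accuracy:    {100 * result.accuracy:.1f}%")
print(f"LOOCV sensitivity: {100 * result.sensitivity:.1f}%")
print(f"LOOCV specificity: {100 * result.specificity:.1f}%")
print(f"AU-ROC:            {roc.auc:.3f}")
# Accuracy and AUC near the mid-90s show the pipeline reaching the
# performance its signal supports; each subject was scored by a model that
# never saw it, including the component-count selection.
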