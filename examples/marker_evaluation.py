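"""Diagnostic evaluation: locked cut-offs and combined RF classifiers.

Single markers are thresholded at the cut-off maximising sensitivity +
specificity on the test cohort, then that cut-off is applied unchanged to
the validation cohort (a locked, prospective evaluation). Combined
classifiers are random forests trained on the test cohort and scored on
the validation cohort by majority vote.
"""

from fibroselect import (
    CohortConfig,
    ForestParams,
    auc_band,
    combined_classifier_eval,
    generate_cohort,
    locked_threshold_eval,
)

config = CohortConfig(seed=42)
test = generate_cohort(config, "test")
validation = generate_cohort(config, "validation")

genes = ["TGFB1", "MMP9", "TIMP2", "VIM"]

print("single markers (cut-off locked on the test stage):")
print("marker   testAUC band         cutoff   val.acc  sens   spec")
for marker, direction in [(g, "greater_is_positive") for g in genes] + [
    ("egfr", "less_is_positive"), ("scr", "greater_is_positive")
]:
    curve, metrics = locked_threshold_eval(test, validation, marker, direction)
    print(f"{marker:8s} {curve.auc:6.3f} {auc_band(curve.auc):12s} "
          f"{curve.best_cutoff:7.3g}  {metrics.accuracy:6.3f} "
          f"{metrics.sensitivity:.3f}  {metrics.specificity:.3f}")

table = combined_classifier_eval(
    test, validation,
    [genes, [*genes, "egfr"], [*genes, "scr"]],
    ForestParams(seed=42),
)
print("\ncombined RF classifiers (validation stage):")
for label, (_, row) in zip(
    ("4 mRNAs", "4 mRNAs + eGFR", "4 mRNAs + SCr"), table.iterrows()
):
    print(f"{label:15s} acc {row['accuracy']:.3f}  "
          f"sens {row['sensitivity']:.3f}  spec {row['specificity']:.3f}")
# Combining markers trades a little of the genes' sensitivity for the
# covariates' specificity, lifting overall accuracy above any single
# marker.
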