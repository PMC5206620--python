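# Methods

## Problem setting

Renal fibrosis — tubulointerstitial fibrosis (TIF) and glomerulosclerosis
(GS) — is the common endpoint of progressive chronic kidney disease, and
biopsy is the only direct measurement. mRNAs shed into urinary sediment
(TGF-β axis, matrix-turnover and EMT markers) change early, which makes a
targeted qPCR panel an attractive non-invasive screen. The statistical
problem is to select, from a 61-gene panel measured on a modest two-stage
cohort, the genes that carry TIF information, and to quantify how well
they (alone and combined with kidney-function covariates) classify TIF in
an independent stage.

`fibroselect` implements that workflow end to end: ΔΔCt preprocessing,
semiquantitative histology scoring, a random forest with out-of-bag (OOB)
error and permutation importance, iterative importance-ranked feature
elimination with an early stop, and a locked-threshold diagnostic
evaluation layer — plus a cohort generator that emulates the study's
data structure so the whole pipeline is testable without patient data.

## ΔΔCt preprocessing (`expression`)

Relative expression is `2^-(Ct_target - Ct_ref)` with `Ct_ref` the
arithmetic mean of the six reference genes (GAPDH, B2M, OAZ1, RPL27,
HRPT1, ACTB); averaging Ct values is geometric-mean normalisation in
linear space. No calibrator sample is subtracted: urinary-sediment panels
report per-sample relative abundance, and the resulting magnitudes
(10⁻²–10⁰ for most genes) match what such assays report. Two conventions
exist for reactions that never cross threshold; both are exposed
(`ct_floor=None` leaves the value missing, `ct_floor=N` imputes cycle N).
The genomic-DNA control flags contamination when it amplifies below 35
cycles (a conventional late-cycle bound); flagged samples are reported,
never dropped silently. Expressions are invariant to any constant Ct
offset applied to a whole profile, which is the property that makes the
multi-reference normalisation meaningful; the test suite asserts it.

## Histology scoring (`histology`)

GS: each glomerulus is graded 0–4 by percent sclerotic area (0 = 0%,
(0,25] = 1, (25,50] = 2, (50,75] = 3, (75,100] = 4) and the specimen
score is the unweighted mean grade — the natural reading of a
"weighted average of all grades", with each glomerulus carrying weight
one. TIF: percent fibrotic interstitium maps to grade 0–3 with bounds at
5, 25 and 50%; grade 0 is absence of TIF and grades 1–3 pool into the TIF
class. The published integer anchors leave non-integer percentages
unassigned (e.g. 5.5% falls between "no more than 5%" and "6–25%"); the
graders use half-open bins anchored at the printed integers so the
functions are total and monotone. Specimens with fewer than 20 glomeruli
are scored with a warning rather than rejected. Healthy volunteers are
never biopsied: their histology fields are missing by design and their
TIF label is 0 regardless of any stored grade.

## Random forest (`forest`)

Binary-classification and regression CART ensembles, written against the
canonical algorithm: each tree grows on a bootstrap draw of n samples
with replacement; each node draws a fresh uniform subset of `mtry`
features and takes the split maximising Gini impurity decrease
(classification) or variance reduction (regression), with thresholds at
midpoints of consecutive distinct values; growth stops at purity, below
the minimum node size, or when no split improves the criterion. Defaults
follow the standard implementation: 500 trees, `mtry = ⌊√p⌋` / 1
(classification) and `max(1, ⌊p/3⌋)` / 5 (regression). Ties in the split
criterion break toward the lower feature index, then the lower threshold,
making every forest a pure function of `(X, y, params, seed)`; one master
seed spawns an independent RNG stream per tree so results cannot depend
on execution order. Vote ties (exactly half the trees) resolve to the
lexicographically smaller class label.

OOB machinery: a sample's OOB prediction aggregates only trees whose
bootstrap omitted it (majority vote / mean); the OOB error is computed
over samples with at least one OOB tree, and the report counts any
uncovered samples (practically nonexistent at 500 trees, where each
sample is OOB for ≈ e⁻¹ of trees).

Permutation importance: for each tree, the accuracy (or MSE) on its OOB
samples is compared with the value after permuting one feature's column
within those samples; mean decrease in accuracy (MDA) averages the drop
over all trees, and `%IncMSE = 100 · mean(MSE_perm − MSE) / mean(MSE)`.
Only features a tree actually uses are permuted — other features cannot
change its predictions — so a feature used by no tree scores exactly
zero. MDA is reported raw (unscaled) because elimination consumes the
ranking; division by the between-tree standard error is available behind
`scale=True`.

Correctness anchors: the split finder is tested against brute-force
enumeration; a single tree with `mtry = p` and no bootstrap reproduces an
exhaustively computed greedy CART on all small instances; label-permuted
data yields chance-level OOB error. On permuted labels the OOB error of a
forest sits a few points *above* the majority-class rate (trees chase
noise); the null-calibration test therefore checks the mean over 20 runs
against the majority rate within three per-run standard deviations.

## Iterative elimination (`selection`)

The selection loop trains a forest on the full candidate set, records the
OOB error, ranks features by MDA (classification, TIF label) or %IncMSE
(regression, GS score), retains the top `⌈p/2⌉`, and repeats. Starting
from 61 genes the halving schedule runs 61 → 31 → 16 → 8 → 4, reaching a
four-gene panel after four iterations. A validation cohort is trained in
parallel — its own forest, its own OOB error — and the loop stops early
when the error rebounds (strictly increases versus the immediately
preceding iteration; `test_rebound` consults the test cohort only,
`both_rebound` requires both cohorts to rise). The selected feature set
is the one with the smallest test-cohort OOB error among iterations
completed before the stop, tie-broken toward the later (smaller) set.
Elimination is always driven by the test cohort's importance ranking; the
validation cohort participates only in the stopping decision.

Two caveats are deliberate documentation rather than silent behaviour:

* **Early-stop leakage.** Letting the validation cohort's error influence
  when selection stops leaks validation information into model choice.
  `blind=True` runs the loop on the test cohort alone.
* **Selection optimism.** The minimum OOB error along an elimination path
  is biased low, because each elimination step keeps exactly the features
  that look best on the same data that scores them. On label-permuted
  cohorts (61 genes, n = 76) the full-panel OOB error sits at chance but
  the selected-set error drops to ≈ 0.30 before the rebound fires. The
  selected *panel* is still meaningful; the selected-iteration *error* is
  not an unbiased performance estimate — that is what the held-out
  validation stage is for. The test suite asserts this optimism as
  documented behaviour.

With the default calibration (per-gene AUC ≈ 0.75, study sample sizes)
the procedure places all four planted TIF genes in the selected set in
roughly three quarters of seeded runs; the misses occur when a spuriously
label-correlated noise gene — precisely the kind elimination enriches
for — outranks a true marker at the 8→4 step. An independently scripted
run of the same protocol over the reference R forest implementation on
identical cohorts reproduces that rate, so it is a property of the
procedure at these effect sizes, not of this implementation.

## Diagnostic evaluation (`evaluation`)

ROC curves enumerate one operating point per distinct score (thresholds
at midpoints, ±∞ sentinels); the trapezoidal AUC is numerically identical
(≤ 1e−12) to the tie-corrected Mann–Whitney `U/(n₁n₂)`, and the test
suite asserts the identity on random instances. The best cut-off
maximises sensitivity + specificity, ties broken toward higher
specificity and then toward the threshold calling more samples negative.
Markers where disease lowers the value (eGFR) use the
`less_is_positive` orientation; `auto` picks the orientation with
AUC ≥ 0.5. AUC bands are half-open upward ([0.7, 0.8) = moderate, ≥ 0.9 =
excellent), with values below 0.6 labelled "uninformative". AUC
confidence intervals use a seeded stratified percentile bootstrap (2000
resamples) rather than the DeLong variance formula — simpler, and
adequate at these cohort sizes.

The two-stage protocol is enforced structurally: `locked_threshold_eval`
derives the cut-off from the test cohort object alone and only then
touches validation labels. Combined classifiers train a forest per
feature set on the test cohort (expression on the log2 scale, covariates
untransformed) and call the validation cohort by majority vote
(`vote_cutoff` exposes other operating points on the vote fraction).

Rank statistics: Spearman r is the Pearson correlation of average-ranked
data with the two-sided t approximation on n−2 df; Mann–Whitney U comes
from average-rank sums with an exact enumeration p-value when n₁+n₂ ≤ 12
and no ties, otherwise the normal approximation with tie and continuity
corrections. Both are cross-checked against independent library
implementations in the tests.

## Synthetic cohorts (`synthetic`)

The generator reproduces the study's structure, with all parameters in
one config:

* **Design.** Test stage 42 TIF / 34 no-TIF (14 healthy), validation
  stage 28 TIF / 21 no-TIF (8 healthy). TIF grades within the TIF group
  follow a (0.5, 0.3, 0.2) mixture over grades 1–3 (mild fibrosis
  dominates among biopsied early-CKD patients); percent fibrotic area is
  drawn uniformly within the grade's bin; no-TIF CKD sits in [0, 5]%.
  GS scores track TIF grade (rank correlation ≈ 0.5) through a linear
  link with Gaussian noise, clipped to [0, 4].
* **Expression.** log2 expression of gene g is
  `baseline_g + δ_g·tif_grade + γ_g·gs_score + ε`, lognormal in linear
  space as qPCR fold-change data are. Baselines are a fixed property of
  the panel spanning the 10⁻²–10⁰ decade. Noise is unit-SD on the log2
  scale with optional equicorrelation (ρ = 0.2 by default) emulating
  shared-pathway co-expression; independence mode serves the
  null-calibration tests. Four genes carry TIF effects (TGFB1, MMP9,
  TIMP2, VIM) and four carry GS effects (VIM, TGFB1, CCL5, PODXL;
  γ = 0.6 log2-units per GS unit).
* **Effect calibration.** `calibrate_effect` solves
  `Σ_g p_g Φ(δg / (√2 σ)) = AUC` for δ over the grade mixture (closed
  form `δ = √2 σ Φ⁻¹(AUC)` in the two-group case). The default δ targets
  a single-gene AUC of 0.75, mid-range for real urinary fibrosis markers;
  the large-n test verifies the empirical AUC lands within ±0.03.
* **Covariates.** SCr and 24-h protein are lognormal and eGFR normal,
  each linked monotonically to TIF grade with intercepts near the
  no-TIF medians of real cohorts (SCr ≈ 63 μmol/L, eGFR ≈ 106
  mL/min/1.73 m²) and dispersions set so eGFR discriminates TIF at
  AUC ≈ 0.78 and protein stays weak (≈ 0.6) — the regime in which
  "combined beats single" comparisons are meaningful. Healthy volunteers
  get eGFR ≥ 90, normal SCr, trace proteinuria, and expression drawn
  from the no-TIF CKD distribution (configurable offset, default 0).
* **Ct inversion.** `generate_ct_profiles` maps a cohort back to Ct
  space (reference genes at a nominal Ct, targets at
  `Ct_ref − log2(expression)`), giving an exact algebraic round trip
  through the ΔΔCt converter when reference noise is zero.

What the generator does **not** model: disease subtypes, medication
effects, assay-plate batch structure, censored/undetermined Ct patterns
correlated with expression level, and non-lognormal tails. Tests passing
on these cohorts demonstrate the machinery and its statistical
calibration, not clinical performance on real patients.

## Pipeline (`pipeline`, CLI)

`run_pipeline` executes selection → marker statistics → locked-threshold
validation → combined classifiers → GS regression, writing a fixed bundle
(`selection_trace.csv/.json`, `marker_stats.csv`, `marker_roc/*.csv`,
`locked_validation.csv`, `table2_summary.csv`, `gs_regression.csv`,
`gs_correlations.csv`, `run_manifest.json`). One structured log line per
stage records the derived seed and headline numbers; the manifest holds
everything needed for bit-identical reproduction. Stage isolation keeps
validation labels unread before stage 3 except through the early-stop
check (and not at all under `--blind`). A full run on the default
synthetic cohorts takes well under a minute on one CPU.

## Problem sizes used in tests

The stochastic suites run at the study's own scale (76/49 samples,
61 genes, 500-tree forests) with 20 seeded repetitions for the recovery
and calibration experiments, 100 random instances for the AUC ≡ U
identity, 50 for the cut-off oracle, and n = 5000 single-stage draws for
large-sample calibration checks. Reduced tree counts (100–150) appear
only in tests whose property does not depend on ensemble size.

## Known limitations

* The forest is binary-classification only; no class weights, surrogate
  splits, or proximity measures.
* Spearman p-values use the t approximation throughout the cohort-size
  range; exact permutation is not implemented.
* The bootstrap AUC CI can differ from DeLong intervals in small, highly
  unbalanced cohorts.
* At realistic effect sizes the elimination procedure recovers the full
  planted panel in most but not all runs (see the selection section);
  users should treat a selected panel from one cohort as a candidate
  set, to be confirmed on an independent stage — exactly the role of the
  two-stage design.
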