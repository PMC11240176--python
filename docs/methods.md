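# Methods

## Scope and model

`imbalmetrics` studies how binary-classifier evaluation metrics respond to
class imbalance when the *per-class score distributions are held fixed*.
Datasets are generated by drawing the positive and negative scores
independently from fixed distributions, with the composition (prevalence
π = P/(P+N)) controlled separately. Under this design the ROC curve is an
imbalance-free description of the classifier, while everything built on
precision (the PR curve, PR-AUC, F1, MCC) mixes classifier skill with the
composition of the particular dataset.

### Classifier families

* **binormal** — negatives ~ N(0,1), positives ~ N(μ,1). ROC-AUC has the
  closed form Φ(μ/√2); the presets `worst`/`middle`/`best` use μ = 0.5, 1.0
  and 1.5 (AUC ≈ 0.638, 0.760, 0.856). Unit variance is assumed for both
  classes; the closed form and its use as a test oracle depend on it.
* **beta** — positives ~ Beta(α₊, β₊), negatives ~ Beta(α₋, β₋). The
  presets `good_ER` (α₊=1, β₊=1; α₋=1, β₋=4) and `bad_ER` (α₊=4, β₊=1;
  α₋=1, β₋=1) are a matched pair for early-retrieval analysis: their
  analytic ROC curves are TPR = FPR^(1/4) and TPR = 1−(1−FPR)⁴, both with
  full AUC exactly 4/5, but with McClish-corrected partial AUC at
  FPR_max = 0.1 of 0.7105 vs 0.5689 (exact integrals:
  ∫₀^t x^(1/4) dx = (4/5)t^(5/4) and t − (1−(1−t)⁵)/5).
* **no_skill** — both classes ~ N(0,1); the chance reference
  (ROC-AUC 0.5, PR-AUC π).
* **bimodal_standin** — a fixed mixture emulating the score distribution a
  trained predictor produces on an imbalanced residue-labelling problem:
  positives ~ Beta(8,3); negatives a 0.8/0.2 mixture of Beta(1.5,10)
  (the easy low-scoring bulk) and Beta(5,3) (a hard tail overlapping the
  positives). These constants are fixed in code. The resulting ROC-AUC is
  ≈ 0.94 and the minimum negative score sits far below the positive range,
  which the type II enrichment experiments rely on. It emulates only the
  *shape* of such a score distribution — not residue-level correlation,
  per-antibody grouping, or calibration of a real model — so conclusions
  from it concern the metric arithmetic, not any particular predictor.

### Composition

An `ImbalanceSpec` is a P:N ratio plus a total size. P = round(π·total_n)
(banker's rounding), clipped so both classes are non-empty; for the preset
ratios 1:99 / 1:9 / 1:1 at total_n = 10,000 this gives exactly
(100, 9 900), (1 000, 9 000), (5 000, 5 000).

## Estimators

* **Curves** are built from cumulative TP/FP counts at the unique observed
  scores in descending order, so tied instances always move between
  operating points together. The predicted-positive convention is
  score ≥ threshold, chosen so a threshold at the maximum observed score
  still predicts a non-empty positive set (the convention standard curve
  constructors use).
* **ROC-AUC** is the trapezoidal area under the ROC curve (with a (0,0)
  anchor). It equals the tie-corrected Mann-Whitney statistic
  (#{pos>neg} + ½#{pos=neg})/(P·N); the package carries an exhaustive
  pair-counting implementation as an independent oracle and the test suite
  asserts equality to 1e−12.
* **PR-AUC** is average precision, Σ_k (R_k − R_{k−1})·P_k over unique
  thresholds. Trapezoidal interpolation is deliberately not used in PR
  space: precision's denominator changes along the curve, so linear
  interpolation between PR points is invalid. No anchor point is added in
  PR space; the first measured threshold defines the first point, so
  precision is never evaluated over an empty prediction set (an undefined
  precision is represented as an explicit `None` marker at the
  operating-point level, never silently 0 or 1).
* **Partial ROC-AUC** restricts the trapezoidal area to FPR ∈ [0, fpr_max],
  linearly interpolating TPR at the boundary, and standardizes via
  0.5·(1 + (pAUC − A_min)/(A_max − A_min)) with A_min = fpr_max²/2 (chance)
  and A_max = fpr_max (perfection), so chance maps to 0.5 and perfection to
  1 regardless of fpr_max. The default fpr_max = 0.1 reflects a 10%
  acceptable false-positive rate; comparable values should only be changed
  by orders of magnitude if changed at all. With very few negatives
  (≲ 100) only a handful of operating points fall inside the window and
  the estimate acquires a visible coarse-grid bias — see the enrichment
  study note below.
* **Single-threshold metrics** (default threshold 0.5): F1, G-mean =
  √(TPR·(1−FPR)) and MCC. Degenerate denominators (no predictions, a
  one-sided contingency margin) map to 0 by the usual convention, keeping
  extreme thresholds computable.
* **PPV identity**: precision = TPR·π/(TPR·π + FPR·(1−π)). The test suite
  asserts exact agreement between this identity and precision computed
  from counts at every threshold — precision is a re-weighting of an ROC
  operating point by prevalence, nothing more.

## PR-AUC transforms

Three affine corrections against the chance baseline π are provided:
marginal (AUC − π), normalized (AUC/π) and min-max ((AUC − π)/(1 − π),
with min = π and max = 1 — the canonical min-max anchors; the negative
result below holds for any affine-in-π variant). None of them is
imbalance-invariant: the PR-AUC's dependence on π is non-linear and
classifier-specific, and the experiment grid demonstrates the failure
quantitatively.

## Negative-data enrichment

* **Type I** resamples the negative class at random to a target ratio —
  without replacement when shrinking (a true subsample), with replacement
  when growing — preserving the expected negative score distribution.
  "Random over/undersampling" alone leaves the direction unspecified;
  the subsample/resample split is chosen because it preserves
  the empirical distribution both ways.
* **Type II** appends exact copies of the single lowest-scoring negative,
  deterministically, and can therefore only lower the prevalence. The
  exact effect on the AUC is the pair-counting identity
  AUC_new = (1−f)·AUC_orig + f·a, where f is the appended fraction of the
  negatives and a the fraction of positives ranked above the copied score;
  when the copies fall below the positive score range (a ≈ 1) the ROC-AUC
  is driven toward 1 while every (recall, precision) step — and hence the
  average precision — is exactly unchanged. Appended copies tie with the
  original minimum; all curve math routes through unique-threshold
  grouping and the ½-tie convention, so massive ties are handled exactly.

## Experiment grids and problem sizes

`run_grid` evaluates classifiers × imbalances × repeats and returns a tidy
long-format table (one metric value per row) with the per-repeat child
seed recorded; child seeds derive from the master seed via
`numpy.random.SeedSequence` spawning, so any single repeat can be rerun in
isolation. Summaries report median, mean, IQR and count per cell (median
for distribution-location claims, mean where an averaged estimate is the
quantity of interest).

Defaults mirror the study design: total_n 10,000, imbalances
{1:99, 1:9, 1:1}, 1,000 repeats, fpr_max 0.1, fixed threshold 0.5. The
test suite runs the same grid at 200 repeats, for which the Monte-Carlo
standard error of a median ROC-AUC cell is ≈ 0.002 at 1:99 — comfortably
inside the 0.01 flatness tolerance the invariance assertions use.

The enrichment study applies both ladders to the bimodal stand-in at base
ratio 3:7 (π = 0.30, close to a realistic "native" composition of roughly
one positive per 2–3 negatives) and base size 10,000, the canonical
dataset size used throughout. The type I ladder spans 1:99 → 9:1; the
type II ladder 3:7 → 1:99. The 9:1 undersampling rung keeps only ~P/9
negatives; at much smaller base sizes the partial AUC there is estimated
from so few operating points that a coarse-grid bias of order 0.02
appears, which is why the base size matches the main grid rather than
being scaled down.

## Known limitations

* Simulated scores are i.i.d. within class; real score sets (e.g.
  per-residue predictions grouped by protein) are correlated, so real
  Monte-Carlo variability is underestimated by these conditions.
* The bimodal stand-in is a synthetic surrogate; quantitative values on it
  (AUC ≈ 0.94 etc.) characterize the stand-in, not any published model.
* No statistical tests are attached to the grid contrasts; the assertions
  are tolerance-based, with tolerances derived from the U-statistic /
  binomial standard errors at the configured repeat counts.
* Exotic partial-area variants (concentrated ROC, log-scaled FPR axes) are
  out of scope.
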