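# imbalmetrics

Tools for studying how binary-classifier evaluation metrics respond to
class imbalance. The package simulates classifier score distributions at a
controlled positive:negative composition, builds ROC and precision-recall
curves, and computes the associated summaries — trapezoidal ROC-AUC,
average-precision PR-AUC, the McClish-standardized partial ROC-AUC for
early retrieval, fixed-threshold metrics (F1, G-mean, MCC), baseline
transforms of the PR-AUC, and two negative-data enrichment operators — so
that the imbalance-(in)sensitivity of each metric can be measured rather
than assumed. It is aimed at anyone evaluating classifiers on imbalanced
data (e.g. per-residue binding-site prediction, epitope prediction,
species distribution modelling) who needs to know which reported numbers
transfer across datasets with different compositions.

## The quantities at its core

With P positives, N negatives and prevalence π = P/(P+N):

* **ROC-AUC** — trapezoidal area under the (FPR, TPR) curve; equals the
  tie-corrected Mann-Whitney statistic (#{pos>neg} + ½#{pos=neg})/(P·N).
  For the binormal model (negatives ~ N(0,1), positives ~ N(μ,1)) it has
  the closed form Φ(μ/√2). Invariant to π when the per-class score
  distributions are fixed.
* **PR-AUC** — average precision Σ_k (R_k − R_{k−1})·P_k over unique
  thresholds (not trapezoidal: PR space does not interpolate linearly).
  Its chance baseline is π, and its value moves with π in a
  classifier-specific, non-removable way.
* **Partial ROC-AUC (ROC-AUC_0.1)** — trapezoidal area restricted to
  FPR ≤ FPR_max (default 0.1), standardized as
  0.5·(1 + (pAUC − FPR_max²/2)/(FPR_max − FPR_max²/2)) so chance maps to
  0.5 and perfection to 1. Separates classifiers by early-retrieval
  behaviour that the full AUC cannot see, while staying
  imbalance-invariant.
* **PPV identity** — precision = TPR·π/(TPR·π + FPR·(1−π)): every PR point
  is an ROC point re-weighted by prevalence.

See `docs/methods.md` for the full model, estimator conventions,
enrichment operators and limitations.

## Worked example

```python
from imbalmetrics import (
    ClassifierSpec, ImbalanceSpec, simulate,
    roc_auc, pr_auc, partial_roc_auc, analytic_binormal_auc,
)

spec = ClassifierSpec.preset("middle")        # positives ~ N(1, 1)
for ratio in ("1:99", "1:1"):
    imb = ImbalanceSpec.from_string(ratio, 10_000)
    data = simulate(spec, imb, seed=7)
    print(ratio,
          f"roc_auc={roc_auc(data).value:.4f}",
          f"pr_auc={pr_auc(data).value:.4f}",
          f"roc_auc_0.1={partial_roc_auc(data, 0.1).value:.4f}")
print("analytic", f"{analytic_binormal_auc(1.0):.4f}")
```

prints

```
1:99 roc_auc=0.7382 pr_auc=0.0270 roc_auc_0.1=0.5641
1:1 roc_auc=0.7582 pr_auc=0.7511 roc_auc_0.1=0.6024
analytic 0.7602
```

The same classifier, scored on datasets that differ only in composition:
both ROC-AUC estimates sit near the analytic value Φ(1/√2) ≈ 0.7602 and
near each other, while the PR-AUC collapses from 0.75 to 0.03 as the
prevalence drops from 0.5 to 0.01 — the PR-AUC is a property of the
(classifier, dataset) pair, not of the classifier.

The same pipeline is available from the shell:

```
imbalmetrics simulate --classifier middle --imbalance 1:99 --seed 7 scores.tsv
imbalmetrics metrics scores.tsv            # JSON with all metrics
imbalmetrics grid --repeats 200 results.csv
imbalmetrics report results.csv summary.csv
```

`grid` runs the full simulation grid (classifiers × imbalances × seeded
repeats) into a tidy table; `report` summarizes it per cell (median, mean,
IQR, n). `enrich` applies type I (random negative resampling) or type II
(lowest-negative duplication) enrichment to any two-column
`label<TAB>score` table, including your own.

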