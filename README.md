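# ependysurv

Survival prediction for methylation-profiled ependymoma cohorts.

Ependymomas comprise ten molecularly defined types (EPN-PFA, EPN-PFB,
EPN-ZFTA, EPN-YAP, EPN-MYCN, MPE, SP-EPN, PF-SE, ST-SE, SP-SE) with widely
differing outcomes, yet outcome heterogeneity *within* a type remains
large. This package implements, as a tested and reusable pipeline, a
framework for predicting binary five-year progression-free survival
(relapse vs. no evidence of disease, NED) from DNA methylation array data,
copy-number profiles and clinical covariates, and for comparing that
prediction against the type/subtype-based estimates used in current
clinical practice. It is aimed at computational biologists working with
450k/EPIC beta-value matrices and time-to-event annotations.

## What it computes

**Preprocessing.** Samples failing detection-*p* QC (*p* > 0.05) are
dropped; probes are restricted to those shared by both array generations;
blacklisted probes (sex chromosomes, SNPs, cross-reactive) are excluded;
probes with a platform batch effect (|Δmean| > 0.2 **and** Welch two-sided
*t*-test *p* < 0.01 after Bonferroni correction) are removed.

**CNV status calling.** Per-arm log-ratios are called GAIN/LOSS/BALANCED at
a threshold of 0.1 (strict inequality), focal genes at 0.4, giving the
prognostic categories: 1q gain / 6q loss / combined (EPN-PFA) and CDKN2A/B
single or combined loss (EPN-ZFTA).

**Survival machinery.** Kaplan–Meier product-limit estimator
Ŝ(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ), the k-sample log-rank test with
hypergeometric variance, and binarization at a horizon (default 60
months): relapse if the event occurs within the horizon, NED if follow-up
reaches it event-free, indeterminate (excluded, counted) if censored
before it.

**Predictors**, all evaluated on one shared class-balanced outer-fold
structure:

1. *KM type / KM subtype classifier* — Ŝ(60) per molecular (sub)type on the
   training folds; a test sample is called NED iff its (sub)type's
   Ŝ(60) ≥ 0.5.
2. *Nested-CV SVM* — 10×10 nested cross-validation; in each outer loop the
   10,000 most variable CpGs are recomputed on training data only; a grid
   with linear and RBF kernels, C = 2⁻⁵…2⁵ and γ = 2⁻⁵…2⁵ × 1/√(#CpG), is
   scored by pooled inner out-of-fold log loss; probability scores come
   from a Platt-type sigmoid on training decision values. A reject option
   withholds scores in [0.3, 0.7].
3. *Clinical + CNV logistic regression* — maximum-likelihood fit of relapse
   on age group, sex, resection extent, 1q gain, 6q loss, CDKN2A loss and
   CDKN2B loss (complete cases).
4. *Integrated stacked model* — per outer fold, a logistic regression on
   the SVM's inner out-of-fold scores plus the clinical/CNV covariates,
   applied to the outer-test SVM scores; same reject option.

**Evaluation.** Confusion matrices (relapse = positive class), accuracy and
balanced accuracy (macro-average of the two recalls), coverage after
rejection, Kaplan–Meier curves of the predicted groups with log-rank
separation, reliability (calibration) tables, and a dimensionality
saturation sweep over the feature count.

**Synthetic cohorts.** Because real cohorts of this kind are large
controlled-access downloads, the package ships a first-class generator
that emulates the assumed statistical structure: ten types in realistic
proportions with type-specific CpG signatures, a platform batch shift on a
CpG subset, exponential event times calibrated so that
λ = −ln(S₆₀)/60 reproduces each type's five-year PFS, multiplicative
covariate hazard ratios (1q gain, 6q loss, combined CDKN2A/B loss,
subtotal resection, male sex), and independent uniform censoring. A known
outcome-linked CpG signal can be injected to measure detection power.

## Worked example

```python
from ependysurv import CohortConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    cohort=CohortConfig(n_samples=300, n_cpgs=1500, n_informative=300,
                        n_batch_cpgs=75, seed=7),
    k_outer=5, k_inner=5, top_k=400,
    c_exponents=[-3, -1, 1, 3], gamma_exponents=[-3, -1, 1, 3], seed=7,
)
report = run_pipeline(cfg)
print(f"labeled {report['n_labeled']} of {report['n_samples']} "
      f"({report['n_indeterminate']} indeterminate at 60 months)")
print(f"batch CpGs removed: {report['filter_report']['n_batch_removed']}")
for tag in ("km_type", "km_subtype", "svm", "svm_reject",
            "clinical", "integrated", "integrated_reject"):
    m = report["models"][tag]
    print(f"{tag:18s} balanced acc {m['balanced_accuracy']:.3f}  "
          f"coverage {m['coverage']:.2f}  log-rank p {m['logrank_p']:.2e}")
```

prints

```
labeled 254 of 300 (46 indeterminate at 60 months)
batch CpGs removed: 75
km_type            balanced acc 0.696  coverage 1.00  log-rank p 1.20e-11
km_subtype         balanced acc 0.631  coverage 1.00  log-rank p 4.73e-08
svm                balanced acc 0.686  coverage 1.00  log-rank p 1.96e-11
svm_reject         balanced acc 0.668  coverage 0.68  log-rank p 1.96e-07
clinical           balanced acc 0.613  coverage 1.00  log-rank p 1.83e-03
integrated         balanced acc 0.686  coverage 1.00  log-rank p 1.58e-10
integrated_reject  balanced acc 0.746  coverage 0.56  log-rank p 3.29e-09
```

Reading this: of 300 simulated tumours, 254 have a determinate five-year
status (46 were censored before 60 months and are excluded from training
and scoring). All 75 platform-shifted CpGs were caught by the batch
filter. Each model then predicts relapse-within-five-years out of fold;
balanced accuracy is the mean of the two class recalls, coverage the
fraction of samples retained after the reject option, and the log-rank *p*
measures how well the predicted groups separate the actual
progression-free survival curves. The integrated model with rejection
scores best here, at the price of abstaining on 44% of cases.

The same pipeline is exposed on the command line:

```bash
ependysurv simulate --seed 7 --n-samples 300 --out cohort/
ependysurv cnv-call --cnv cohort/cnv.tsv --out calls.tsv
ependysurv predict --mode km-type --cohort-dir cohort/ --seed 7 --out preds.tsv
ependysurv evaluate --predictions preds.tsv --sheet cohort/samples.tsv
ependysurv run-all --seed 7 --out master_report.json
```

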