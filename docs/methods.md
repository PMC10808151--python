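# Methods

This note documents the statistical model behind `ependysurv`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Outcome definition

The prediction target is binary five-year progression-free survival.
Given a time-to-event record (t, δ) with t in months and δ = 1 if
progression was observed:

* **RELAPSE** — δ = 1 and t ≤ 60: progression within five years;
* **NED** — t ≥ 60: follow-up reached the horizon event-free. An event
  *after* 60 months still counts as NED, so the label is exactly
  "progression within five years";
* **INDETERMINATE** — δ = 0 and t < 60: censored before the horizon. These
  records carry no usable label. They are excluded from classifier
  training and scoring and counted in every report, so the effective n is
  always visible. (Alternatives — imputation or last observation carried
  forward — would inject label noise whose magnitude depends on the
  censoring mechanism; exclusion keeps the label clean at the cost of a
  smaller, potentially selected, training set.)

The horizon is a parameter: 60 months for PFS, 120 for the ten-year OS
variant of the analysis.

## Survival machinery

`km_fit` implements the product-limit estimator
Ŝ(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ) over distinct observed event times, with
the standard tie convention that events precede censorings at equal times
(a record censored at t is still at risk for events at t). `km_at`
evaluates the right-continuous step function; values beyond the last
observed time carry the last value forward and are flagged as
extrapolated.

`logrank` is the k-sample test: per pooled event time, the observed minus
expected events per group with the multivariate hypergeometric variance;
the statistic is zᵀV⁻¹z over the first k−1 groups (pseudo-inverse when V
is singular), referred to χ² with k−1 degrees of freedom.

`km_confidence_at` gives the pointwise 95% interval on the log(−log)
scale — the default construction in standard survival software, chosen
for its small-sample coverage. When no event has occurred by t the
Greenwood variance is degenerate (zero width at Ŝ = 1); an exact
zero-event bound is used instead: with m subjects still at risk at t, the
lower limit is (α/2)^(1/m). The symmetric convention applies at Ŝ = 0.
These intervals exist for the parameter-recovery checks; no confidence
band over time is provided.

## Preprocessing

Filters run in a fixed order, each idempotent, with telescoping counts in
a `FilterReport`: detection-p sample QC (samples with p > 0.05 dropped;
p = 0.05 exactly is kept), platform probe intersection, blacklist
exclusion, batch-effect filter. The batch filter removes a CpG only when
**both** conditions hold: |mean(EPIC) − mean(450k)| > 0.2 *and* Welch
two-sided t-test p × (number of CpGs entering this stage) < 0.01. The
conjunction matters: removing on effect size or significance alone would
strip either noisy or merely well-measured probes. Welch (unequal
variances) is used because platform groups differ in size and technical
variance; Bonferroni multiplies by the post-blacklist CpG count since
that is the family actually tested. Variance ranking for feature
selection breaks ties lexicographically by CpG id so results are
order-invariant; callers must pass training samples only (the nested CV
does this per outer fold).

## Copy-number status

Arm calls use |log-ratio| > 0.1, focal calls > 0.4, both strict: a value
exactly at the threshold is BALANCED. No heterozygous/homozygous
distinction is made. Derived categories partition every profile:
1q/6q status ∈ {balanced, isolated 1q gain, isolated 6q loss, combined}
and CDKN2A/B status ∈ {flat, CDKN2A-only loss, CDKN2B-only loss, combined
loss}; gains at the CDKN2A/B loci map to flat because the prognostic
categories concern losses only. The default arm set is the 44 autosomal
arms 1p..22q; a caller-supplied arm-definition file (arm, chromosome,
start, end) can restrict it. Input is summarized per-arm/per-gene
log-ratios; bin-level segmentation is upstream of this package.

## Predictors

All models share one `FoldAssignment`: a stratified outer partition
(per-fold class counts deviate from the overall proportions by at most
one sample per class) with stratified inner partitions of each outer
training set, all keyed by sample id and deterministic given the seed.
Defaults are 10×10; analyses in this repository use 5×5 at desk-scale n.

**KM classifier.** Per training (sub)type, Ŝ(60) via the product-limit
estimator; test samples of that (sub)type are called NED iff Ŝ(60) ≥ 0.5
(the tie goes to NED, matching a "probability threshold of 0.5" on the
survivor scale). A (sub)type unseen in training, or with no events and no
follow-up reaching the horizon, falls back to the pooled all-training
estimate; the fallback is logged. The reported relapse score is
1 − Ŝ(60).

**Nested-CV SVM.** Per outer fold: the top-k (default 10,000) most
variable CpGs are recomputed on outer-training samples only; every grid
configuration (11 linear C values 2⁻⁵..2⁵ plus 11×11 RBF C×γ with
γ = 2⁻⁵..2⁵ × 1/√k; 132 configurations) is fitted on each inner training
split and scored on the inner validation split; the configuration with
minimal *pooled* inner out-of-fold log loss wins (pooling is invariant to
unequal fold sizes, unlike averaging per-fold losses; ties go to the
first configuration in grid order). The winner is refit on the full outer
training set and scored on the outer test fold. Probability scores are a
Platt-type sigmoid — a lightly regularized logistic fit on training
decision values — which is monotone, deterministic and cheap; no internal
cross-validation is used for calibration. Kernels are precomputed once
per outer fold (Gram and squared-distance matrices), so each grid point
costs one SVM solve. For the stacked model, the inner out-of-fold scores
of the winning configuration are retained per outer-training sample.
Labels tie at 0.5 toward RELAPSE for the score-based models.

The result also carries a sha256 digest of each fold's training inputs
(selected CpG ids, training matrix bytes, labels) as a mechanical
anti-leakage witness: mutating outer-test labels or features must leave
every digest, chosen configuration and inner score unchanged.

**Reject option.** A prediction is kept iff its relapse score is strictly
below 0.3 or strictly above 0.7; the boundary values themselves are
rejected. Coverage (kept/total) is always reported alongside.

**Clinical + CNV logistic model.** Maximum-likelihood logistic fit
(statsmodels) of relapse on age group (reference < 4 years; dummies for
4–18 and > 18), male sex, subtotal resection, and the binary lesions 1q
gain, 6q loss, CDKN2A loss, CDKN2B loss. Complete cases only; dropped
rows are counted. Zero-variance covariates are removed with a warning.
If the ML fit fails to converge or separates perfectly, an L2-penalized
fit supplies coefficients and the model is flagged non-converged —
predictions are still emitted.

**Integrated stack.** One logistic model *per outer fold* on the SVM's
inner out-of-fold score plus the clinical/CNV covariates of the outer
training set, applied to outer-test samples using their outer-fold SVM
scores. Per-fold fitting was chosen over a single cross-fold fit for
strict leakage safety: no stacked coefficient ever sees a sample whose
score it will be applied to. If the SVM score is constant it is dropped
as zero-variance and the stack reduces exactly to the clinical model.

## Evaluation

RELAPSE is the positive class everywhere. Balanced accuracy is the
macro-average of the two class recalls (the standard two-class
definition); it is reported as undefined when a truth class is absent.
Rejected and indeterminate samples never enter confusion counts, and
reliability-table row counts sum to the scored n. KM-by-prediction
stratifies the *full* follow-up records (not the binarized labels) by
predicted group. The dimensionality sweep reruns the nested CV at each
feature count and reports the pooled inner log loss of the winning
configuration, averaged over outer folds; saturation of its decline
justifies the feature-count choice.

## Synthetic cohort generator

The generator defines the study conditions for every test in this
repository.

* **Type mix** — the ten molecular types with proportions 969 : 308 :
  228 : 181 : 143 : 119 : 26 : 17 : 17 : 15 (EPN-PFA, EPN-PFB, EPN-ZFTA,
  MPE, SP-EPN, PF-SE, ST-SE, EPN-MYCN, EPN-YAP, SP-SE) out of 2023, the
  composition of a large retrospective ependymoma cohort.
* **Event times** — exponential per sample: memoryless is the simplest
  law consistent with a single survivor fraction per type, and it gives
  the closed-form calibration λ = −ln(S₆₀)/60 per month (OS analogously
  at 120 months). Default five-year PFS: PFA 0.42, PFB 0.77, ZFTA 0.48,
  MPE 0.68, SP-EPN 0.84, PF-SE 0.82. EPN-MYCN follows from a median PFS
  of 31 months under the exponential law (2^(−60/31) ≈ 0.26). EPN-YAP
  (0.80), ST-SE and SP-SE (0.90) have no published five-year PFS at
  comparable scale; the values chosen reflect indolent behaviour of
  subependymoma and the generally favourable course of YAP-fusion
  tumours.
* **Covariates** — act multiplicatively on the hazard (proportional
  hazards). Defaults: 1q gain 1.8, 6q loss 1.9, combined CDKN2A/B loss
  2.0 (back-computed from printed stratum survivor fractions via the
  ratio of −ln S, e.g. ln 0.28/ln 0.49 ≈ 1.8), subtotal resection 1.5 and
  male sex 1.2 (direction from univariate cohort findings; magnitudes are
  round plausible values, not estimates). Lesion prevalences: 1q/6q
  categories 74/15/6/5% within EPN-PFA, CDKN2A/B categories 62/25/10/3%
  within EPN-ZFTA, small background rates elsewhere.
* **CNV log-ratios** — lesions draw uniformly from ±[0.25, 0.8] (arms)
  and −[0.5, 1.2] (genes); balanced features draw narrow noise
  (±0.08 arms, ±0.2 genes) that cannot cross the calling thresholds, so
  calling recovers the injected lesions exactly — by construction, which
  is what makes the caller testable against truth.
* **Beta values** — each CpG has a baseline mean in [0.15, 0.85]; each
  type owns an equal share of `n_informative` CpGs whose mean is redrawn
  for that type; draws come from a beta distribution with concentration
  30 around the cell mean (unimodal on (0,1), sd ≈ 0.09 at mean 0.5).
  Batch CpGs add `batch_shift` (default 0.3) for EPIC samples, clipped to
  [0, 1] with the clip count recorded; their baselines are drawn in the
  unsaturated range so the platform mean difference actually equals the
  configured shift — the generator's own contract.
* **Subtypes** — label mixtures per type with multiplicative hazard
  modifiers near 1 (PFA-1c at 1.9 echoing its 1q/6q enrichment). Subtype
  labels deliberately carry *no* methylation signature of their own:
  emulating the internal structure of, e.g., the nine PFA subtypes is out
  of scope. Consequently subtype information is visible to the KM
  classifiers but not to the SVM on these cohorts.
* **Censoring** — independent uniform on (0, 240] months. Censoring rates
  and follow-up distributions per type are not published for the
  motivating cohort; the uniform administrative window is a configurable
  assumption, not an inference.
* **Seeding** — one integer seed streams to named Philox sub-generators
  (types, clinical, cnv, beta, survival, censoring), so identical
  configurations are bit-identical and components are independently
  reproducible.

`inject_known_signal(cohort, effect)` shifts a 50-CpG block (chosen from
background CpGs, recorded in the truth map) by +effect/2 for
eventual-relapse and −effect/2 for eventual-NED samples; effect 0 is the
identity. This provides a tunable, truth-labeled signal for measuring
detection power of the nested CV.

**What passing tests show — and what they do not.** The generator
reproduces the *statistical skeleton* the analysis assumes: calibrated
marginal survival per type, proportional covariate effects, a platform
batch shift, type-level methylation signatures, exact CNV truth. It does
not emulate probe chemistry, normalization artefacts, correlated CpG
blocks, intratumoral heterogeneity, informative censoring, or
subtype-specific methylation. Tests passing on these cohorts therefore
validate the pipeline's correctness and leakage hygiene, not the clinical
accuracy attainable on real tumours.

## Problem sizes and numerical choices

Analyses and tests in this repository run at desk scale: cohorts of
100–2,000 samples, 50–2,000 CpGs, top-k 200–500, 3×3 to 5×5 folds, and a
reduced C/γ grid (exponents −3, −1, 1, 3) — sizes chosen so the full
suite and the acceptance script complete quickly on a single CPU while
exercising every code path; the full 10×10/132-configuration protocol is
the default of the public API. Other conventions: variance ties break
lexicographically; grid ties break toward the earlier configuration; log
loss clips probabilities to [1e−15, 1−1e−15]; survival times are floored
at 1e−6 months; the master report serializes with sorted keys so a rerun
with the same seed is byte-identical.

## Known limitations

* The exponential law cannot represent non-constant hazards (e.g. early
  relapse peaks); calibration holds only at the anchored horizon.
* PFS and OS are drawn independently per sample, so OS can precede PFS in
  a simulated record; analyses treat the endpoints separately.
* The Platt calibration is fitted on the same data that trained the SVM,
  which can make scores slightly overconfident relative to a
  cross-validated calibration; the reliability table makes this visible.
* Complete-case analysis for the clinical models assumes covariates are
  missing completely at random.
* With all hazard ratios at their defaults, per-type marginal survival is
  slightly below the configured baseline (covariate lesions raise the
  average hazard); the parameter-recovery check therefore runs with
  hazard ratios at 1, where the baseline is the marginal.
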