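# Methods

This note documents the statistical model behind `confaudit`, the design
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## zlog transformation

Concentrations are mapped through
z(x) = (ln x − m) / s with m = (ln L + ln U)/2 and s = (ln U − ln L)/3.92,
where (L, U) is a healthy-population reference interval interpreted as the
2.5th/97.5th percentiles; 3.92 = 2 × 1.96 makes z(L) = −1.96 and
z(U) = +1.96. Natural logarithms are used throughout (the reference-interval
convention; any common log base cancels in the ratio up to the fixed span).
The transform is strictly increasing, exactly invertible, and invariant to
a change of concentration units. When an analyte has no published lower
limit it is set to 15% of the upper limit. Defaults: CA125 (5.25, 35) U/mL,
HE4 (21, 140) pmol/L. Reference limits are always supplied, never estimated
from the data — that is the transform's entire point: robustness to the
pathological tail.

## Classification protocol

Binary linear-logistic models minimize ½‖w‖² + C·Σᵢ ωᵢ·logloss_i with
C = 1 (penalty weighed equally with the error term) and balanced class
weights ωᵢ = n/(2·n_class(i)). The fit is delegated to scikit-learn's
LogisticRegression (lbfgs, tol 1e-10, max_iter 10 000), whose objective is
exactly this expression; the tight tolerance makes the convex fit
effectively deterministic across platforms. Balanced weighting with weight
C is equivalent to duplicating the minority class d = n_maj/n_min times
with the error weight rescaled to C·n/(2·n_maj); the test suite verifies
both routes against direct minimization of the written objective.

Evaluation is k-fold stratified cross-validation (k = 5) repeated r = 10
times; repeat j shuffles folds with seed `base_seed + j`, and each sample's
score is the mean of its r held-out predictions. The reported model is a
full-cohort refit, scored unchanged on the external validation cohort.
Screening keeps healthy + cancer samples, diagnostic keeps benign + cancer;
cancer is always the positive class and the score is the predicted
probability of cancer. Protein zlog features enter unstandardized (a
standardization flag exists for multi-feature models, default off, with the
coefficients always folded back to the raw feature scale); training-set
per-feature sample SDs are stored on the model so importances are
reproducible from the serialized JSON alone.

The restricted refit drops every sample whose ID prefix matches the
excluded prefix before both cross-validation and the full refit; nothing
else changes.

## Batch audit

Single-feature discrimination is the Mann–Whitney AUC with midranks for
ties, reported as a′ = max(a, 1−a) so a feature anti-correlated with the
target is not hidden; 0.5 is therefore the minimum reportable value and
a′ > 0.75 (strict) flags a feature as important. Three contexts are
screened: cancer prediction in screening and diagnostic label sets (within
one sample prefix, to keep the technical artifact out of the biological
question) and prefix prediction among discovery-cohort cancer samples
(which isolates the technical artifact, since the biology is held fixed).

Feature ordering uses the classical equal-variance one-way F test across
prefix groups within cancer samples, ascending in p; with two groups
F = t² against the pooled-variance t test. A feature identical across
groups is assigned F = 0, p = 1 and sorts last. The heatmap deliverable is
the standardized (default sample-SD, n−1; population-SD optional) matrix in
that column order, as TSV; image rendering is cosmetic and out of scope.
Per-batch composition tables flag *leakage* (a batch containing both
discovery and validation samples) and *homogeneity* (a batch containing a
single condition, the precondition for perfect confounding).

## Feature importance

A feature's scaled coefficient divides the raw coefficient by the feature's
training-set SD, and its importance is |scaled| / Σ|scaled| (fractions sum
to one; exactly-zero coefficients contribute exactly zero). The
conventional standardized coefficient — multiplying by the SD, equal to the
coefficient the model would carry after z-scoring the feature — is exposed
as an explicitly labeled alternative (`multiply_by_sd`); the two modes are
never mixed within one comparison, and the pipeline writes each comparison
in both modes under distinct file names.

The modes differ in more than scale. Multiply-by-SD is invariant to a
change of a feature's units; divide-by-SD is not (its invariance is to
joint rescaling of coefficient and SD). More consequentially for this
audit: a batch offset *inflates the affected features' training SD* (≈1.47
at a 3-SD offset carried by 42 of 276 training samples), so dividing by the
SD cancels almost exactly the coefficient mass that the confounding
induced. On synthetic cohorts the summed copy-number importance therefore
*rises* slightly after restricted retraining under divide-by-SD (the
smaller restricted training set, 234 vs 276, also inflates noise
coefficients across all 39 copy-number features), while under the
standardized-coefficient mode it falls in essentially every seed. The
confounding-recovery checks accordingly use the standardized mode; the
divide mode remains the default for single-model tables as the formulation
this package's importance accounting is defined by.

## Clinical operating points

With negatives' scores n₁ ≤ … ≤ n_N and positives called by score > t, the
minimal threshold achieving specificity ≥ φ is the ⌈φN⌉-th negative order
statistic; the achieved specificity is reported in count form k/N (182
negatives at φ = 0.99 give 181/182 = 99.5%). The alternative
zero-false-positive rule (t = max negative score, the 100%-specificity
convention) is implemented as a labeled option; it tracks a single healthy
outlier, whereas the minimal-floor threshold moves by at most one order
statistic — the robustness argument for the default. PPV is
sens·p / (sens·p + (1−spec)(1−p)) with prevalence defaulting to 0.00145;
a zero denominator returns 0 with a warning. For a single-marker logistic
model the score threshold converts back through z = (logit(t) − b)/w and
the inverse zlog to a concentration.

## Synthetic cohorts

The generator emulates a two-cohort case-control study whose batch
structure perfectly confounds one sample subset with case status. All
randomness flows from one `numpy` Generator seeded by a single integer, so
(spec, seed) reproduces tables bit for bit.

**Structure.** Default counts preserve every documented marginal of the
emulated study: 85 affected ("PGDX") samples, all discovery, 42 cancer +
43 benign, confined to batches 1–16 with one condition per batch (a flag
can mix one batch); 394 unaffected ("CGPL") samples in batches 17–38, with
182 discovery healthy, 52 discovery cancer, 60 discovery benign and a
100-sample validation cohort (40 healthy / 30 benign / 30 cancer).
Validation condition counts and the discovery benign split are not
published; they are package defaults chosen to give both contexts usable
class sizes. In the default leakage mode, discovery and validation samples
share the later batches, reproducing the audited design flaw; disabling it
separates the batch ranges.

**Proteins.** Protein values are generated on the zlog scale as bivariate
normal with unit SD, correlation 0.57 (the published discovery-cohort
correlation of the two zlog features; attained only approximately in the
pooled cohort, since condition shifts add shared variance), and
per-condition location shifts, then inverted to concentrations (hence
log-normal and strictly positive). The default shifts were derived once,
in closed form, from the published performance figures rather than tuned:
with unit-variance classes, a single feature's screening AUC is
Φ(Δ/√2), and the two-feature logistic direction is Σ⁻¹Δ. Cancer shifts
(2.2, 2.1) give single-protein screening AUCs ≈ 0.94/0.93 (both "above
0.9"), a two-protein separation d ≈ 2.43 (population AUC ≈ 0.96, matching
the published CV AUC), and a CA125:HE4 coefficient ratio ≈ 1.2 (published:
1.25/1.02). Benign shifts (1.1, 0.3) reproduce the published *diagnostic*
ordering — HE4 (gap 1.8, AUC ≈ 0.90) separating benign from cancer better
than CA125 (gap 1.1, AUC ≈ 0.79). This places the benign HE4 shift below
the benign CA125 shift; the opposite ordering cannot reproduce the
published diagnostic AUCs, which is why it was adopted.

**Copy number.** 39 arm-level scores (autosomal arms minus the five
acrocentric short arms) are standard normal, with an additive +0.3-SD
cancer effect on six arms recurrently altered in high-grade serous disease
(small enough that no single feature clears the 0.75 screening flag, as
observed in the emulated data) and an additive −3-SD batch offset on 17
arms (including 11p, 18p, 19q, the three reported near-perfect prefix
discriminators; the full identity of the 17 is illustrative, as the
published analysis names only those three) for affected-batch samples. An
optional shared-factor equicorrelation exists for robustness experiments
(default 0: independent features). Fragmentation PCs, when requested, are
pure noise.

**What passing tests show — and don't.** The synthetic cohorts demonstrate
that the audit machinery *detects a batch effect of the modeled form and
magnitude* and that the modeled confounding inflates cross-validation
performance. Real immunoassay and sequencing data add measurement error,
heavy tails, inter-feature correlation, and batch effects that are neither
additive nor uniform across samples; none of these are modeled, so passing
tests certify the pipeline's statistical logic, not the detectability of
every real-world artifact.

## Problem sizes and numerics

The multi-seed confounding checks run 20 paper-scale cohorts (479 samples,
41 features; 5×10-fold CV per model), chosen as the smallest replication
count at which a one-sided sign test on a ~90%-consistent direction is
conclusively significant. Optimizer tolerance is 1e-10 on the logistic
objective; AUC ties use midranks everywhere; exact score ties in threshold
scans resolve by the order-statistic rule (ties can only raise the achieved
specificity). Degenerate inputs — single-class labels, empty contexts,
zero-variance features with nonzero coefficients, all-zero models,
exclusions that empty a class — raise descriptive errors rather than
propagating NaNs.

## Known limitations

* The published cfDNA-panel reference models were sparse
  (regularization-tuned); this package's dense L2 model at C = 1 spreads
  nonzero coefficients over all features, so printed importance
  percentages of those reference models (e.g. a ~69%/24% protein/copy-
  number split) are not reproduced, only the directional claims.
* No batch-effect *correction* is provided (the audit diagnoses; it does
  not adjust), and no confidence intervals accompany sensitivity/PPV point
  estimates.
* The optional adapter surface reads only the package's own TSV layout;
  external repositories must be mapped to it by the caller.
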