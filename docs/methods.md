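# Methods

`dyadsync` implements a complete motion-synchrony diagnostic-classification
pipeline for dyadic interview videos: motion energy extraction, windowed
cross-lagged synchrony with a surrogate (pseudodyad) null, dyad-level
feature engineering, repeated nested cross-validated linear SVM
classification with permutation inference and feature-stability analysis,
and post-hoc clinical statistics. This note records the model choices, the
parameters that matter, and what the synthetic-data experiments do and do
not establish.

## Motion energy

Movement in a region of interest (ROI) is quantified per frame transition
as the **count** of pixels whose 8-bit gray intensity changes by strictly
more than a threshold τ (default τ = 8 gray levels) between consecutive
frames. A count, not a summed magnitude, is used: downstream SD scaling
removes the unit either way, and the count matches the classical
motion-energy definition. Color input is collapsed to gray with BT.601
luma weights (0.299 R + 0.587 G + 0.114 B). The four canonical ROIs are
participant/administrator × head/body; ROIs are half-open pixel rectangles
and must not overlap within a person.

**Movement quantity** is the fraction of frame transitions with nonzero
motion energy. The natural denominator ambiguity (number of frames vs
number of transitions = frames − 1) is resolved in favor of the transition
count, since that is the length of the series actually inspected; the
frame-count variant is available via `denominator="frames"`. For a
5-minute clip the two differ by < 0.02 %.

Video input is adapted through lexicographically ordered PNG/JPEG image
directories; the default frame rate is 29.95 fps and is configurable
everywhere (recording equipment in this domain commonly runs at 29.95 or
29.97 fps).

## Preprocessing and windowed cross-lagged synchrony

Each raw series is divided by its own standard deviation (removing
room/camera amplitude units) and smoothed with a **centered moving average
of 0.5 s** whose window shrinks symmetrically at the series edges, so the
length is preserved. A constant (zero-variance) series cannot be SD-scaled
and raises a degenerate-input error.

Synchrony between two series is the windowed cross-lagged correlation: for
window start *t* (stepping by the step size) and lag ℓ on a symmetric
grid, the entry is |atanh(r)| where *r* is the Pearson correlation of
`a[t, t+w)` with `b[t+ℓ, t+ℓ+w)`. Parameters:

| setting | interpersonal | intrapersonal |
|---|---|---|
| window *w* | 60 s | 30 s |
| step | 30 s | 15 s |
| lag range | ±5 s | ±5 s |
| lag increment | 1 s | 1 s |

Numerical choices:

- seconds → samples via `round(sec × fps)` (29.95 fps makes non-integer
  spans unavoidable otherwise);
- the lag increment of 1 s follows the common windowed-cross-correlation
  tooling convention and is configurable;
- *r* is clipped to |r| ≤ 1 − 10⁻⁷ before atanh, so entries are finite
  (the in-fold "infinite value" pruning therefore never fires on this
  path, but remains implemented);
- a window in which either series has zero variance (no movement) yields
  an undefined correlation; the entry is marked missing (NaN) and excluded
  from all downstream summaries;
- only window starts for which **every** lag of the grid stays inside both
  series are used — leading/trailing windows that would need out-of-range
  samples are dropped rather than padded, avoiding partial-window bias.

**Pseudodyads.** The chance-level baseline pairs a participant series with
an administrator series from a *different* dyad (role-preserving, so any
role-specific signal structure survives), sampling pairings uniformly
without replacement (individuals recur across pairings); the default is
500 pseudodyads. Real and surrogate per-dyad mean synchrony are compared
with Welch's t-test. On i.i.d.-noise cohorts the real and pseudodyad
distributions are statistically indistinguishable (KS calibration in the
test suite).

## Feature engineering

Each synchrony matrix collapses to seven order-free summary statistics
over all non-missing entries pooled across windows and lags: min, max,
mean, median, SD (ddof = 1), skew and kurtosis. Skew is the adjusted
Fisher–Pearson sample skewness and kurtosis the bias-corrected Fisher
*excess* kurtosis; a linear SVM only sees these through monotone 0–1
scaling, so the convention choice cannot change rank structure, but it is
recorded here and in output metadata. Constant matrices give SD = 0 and
NaN higher moments, which the in-fold pruning removes.

The behavioral feature vector has exactly **25** entries in a fixed,
documented column order: 7 head-synchrony + 7 body-synchrony +
7 intrapersonal (participant head–body) + 4 movement quantities. The
demographic variant appends full-scale IQ (possibly missing) and sex
(coded 0 = male, 1 = female; the direction is immaterial after 0–1
scaling) for **27**. Age is carried as metadata and is never a feature —
it is residualized inside CV folds.

Missing IQ is imputed by k-nearest-neighbor imputation (Euclidean
distance, unweighted mean of donors; k = 5 by default since no value is
canonical) — always fit on training rows only.

## Classification

The classifier is a linear soft-margin SVM (LIBSVM C-SVC, hinge loss,
solver tolerance 10⁻⁶) with per-class misclassification weights
w_c = N/(2 n_c) (inverse prevalence) to correct class imbalance.

**Nested CV.** Outer loop (CV2): 10 stratified folds × 10 repetitions;
inner loop (CV1): 10 stratified folds, one repetition. Stratification
keeps per-fold class counts within one sample of proportionality. For each
outer fold the inner loop grid-searches C over
{0.0156, 0.0312, 0.0625, 0.125, 0.25, 0.5, 1, 2, 4, 8, 16}, maximizing
mean inner-validation balanced accuracy (BAC); ties prefer the smallest C
(strongest regularization). All preprocessing — 0–1 scaling from training
extrema (test values clipped), pruning of zero-variance/non-finite
training columns, kNN imputation (demographic variant), and per-feature
least-squares age residualization — is fit on the training partition of
each split and applied unchanged to its test partition.

The winning inner models score the held-out outer fold, so each dyad
collects (outer repetitions × inner folds) decision scores — 100 under the
default scheme — from models that never saw it in training or tuning. The
**pooled score is the median** (the mean is exposed as an option; ensemble
summaries are sometimes displayed as means elsewhere, and the two orderings
rarely differ); its sign is the predicted label. An explicit leakage audit
re-checks every pooled score against the recorded training-row sets of the
contributing models.

Metrics: sensitivity, specificity, BAC = (sens + spec)/2, accuracy,
PPV/NPV, AUC (rank statistic of pooled scores), number needed to diagnose
NND = 1/(sens + spec − 1), positive likelihood ratio
PLR = sens/(1 − spec), and the diagnostic odds ratio by the standard
cross-product formula DOR = (tp·tn)/(fn·fp). NND/PLR/DOR are +∞ when their
denominators vanish. Note that on the published worked-example confusion
counts the standard DOR formula gives 3.3 (autism vs controls) and 1.6
(the broader neurodevelopmental grouping), not the printed 2.4/1.5; the
package computes the standard formula.

**Permutation test.** Labels are permuted B times (B = 1000 at full
scale); each permutation reruns the entire nested CV with a fresh,
permutation-specific fold plan, and p = (1 + #{BAC_perm ≥ BAC_obs})/(B+1).

**Feature stability.** The cross-validation ratio for feature *j* is the
per-outer-fold median of the inner-model weights divided by their standard
error, summed over outer folds and divided by the number of folds;
|CVR| ≥ 2 corresponds roughly to p ≤ .05. Sign-based consistency tests the
number of positive weight signs among the models retaining the feature
against a fair coin (two-sided binomial), reported as −log10 p (1.3 is the
p = .05 line) with Benjamini–Hochberg FDR flags at α = .05. Features
pruned in some folds enter only through the models that retained them,
with retained counts reported; a zero-SE fold (identical weights)
contributes a flagged, capped ratio.

## Post-hoc statistics

Group comparisons use Welch's unequal-variance t-test, computable from
group summaries (n, mean, SD) alone, with Bonferroni–Holm adjustment
across a comparison family (which tests form a family is a configuration
input, not hard-coded). Cohen's d defaults to the unweighted
root-mean-variance denominator √((s₁² + s₂²)/2); the n-weighted pooled
variant is an option. Sex-by-group independence uses the Yates
continuity-corrected chi-square. Decision-score correlations against the
clinical battery (ADOS-2 calibrated severity scores SA/RRB/Total and
ADI-R domains A/B/C — consumed as inputs, never computed) are Pearson
correlations with Benjamini–Hochberg FDR across the battery; dyads missing
a scale are dropped for that scale only.

## Synthetic cohorts

The generator emulates the *structure* the analysis assumes, not human
kinematics. Per dyad, a stationary AR(1) latent u_t (per-sample
coefficient φ = 0.95) drives the participant; the administrator's latent
is v_t = ρ·u_{t−k} + √(1−ρ²)·q_t with lag k (default 1 s) and coupling ρ,
so ρ is the latent lagged cross-correlation. Head and body share their
person's latent with weight 0.6 (intrapersonal coordination) plus an
independent AR(1) component. Observed counts are a shot-noise transform —
Poisson with log link, rate = 2·exp(latent) — giving nonnegative,
heavy-tailed series with exact zeros (roughly 20 % zero frames). Zeros are
essential: with a continuous observation model the movement-quantity
features would be identically 1.

Defaults: clip length sampled uniformly from 5:15–14:37 min (matching the
heterogeneity of real interview excerpts) at 29.95 fps; group couplings
ρ = 0.2 (autism group) vs 0.4 (clinical controls) — reduced synchrony in
the autism group, with the magnitude a free parameter since no empirical
effect size is available for this contrast; clinical scores drawn from
group-shifted truncated normals whose means/SDs mirror a published
module-3 clinical sample (e.g. ADI-R A 17.6 ± 6.4 vs 6.3 ± 5.5); IQ
missing completely at random at 16 %, whole ADI-R rows at 10 %; sex
0.20/0.24 female.

Monte-Carlo properties verified in the test suite: mean |Fisher Z| is
strictly increasing in ρ; the modal lag recovers the configured k; at
ρ = 0 real dyads are indistinguishable from pseudodyads; a strong coupling
contrast (0.1 vs 0.5, n = 40/group) is detectable end to end, while the
default contrast at n = 20/group yields single-cohort BAC estimates
scattering roughly between 0.38 and 0.70 (mean ≈ 0.58 across seeds) —
deliberately in the weak-signal regime where proof-of-concept clinical
classifiers operate.

What passing these tests does **not** show: anything about real videos —
camera noise, lighting, occlusion, pose variation, conversational
structure, or the dependence of motion energy on distance from camera are
all outside the generator.

A toy video renderer closes the loop for the extraction stage: one bright
square blob per ROI moves horizontally in proportion to a driving signal,
so pixel changes are confined to ROIs by construction and the extracted
motion energy must rank-correlate with the absolute driver increments.

## Problem sizes used in tests and the acceptance script

The published headline result (BAC 63.4 % on 94 real dyads) cannot be
recomputed without the original videos; the acceptance layer therefore
combines exact worked-example identities from printed tables with
synthetic property suites. Simulation sizes are the package's own choices
to keep the suites fast while retaining statistical power: null-BAC
calibration at n = 94 (56/38) with a 10-fold × 3-repetition outer loop and
5 inner folds; permutation type-I calibration at B = 50 over 20 replicates
(the full procedure uses B = 1000); the end-to-end run at 40 dyads,
5-minute series, 10 × 3 outer CV. Several statistical suites use reduced
frame rates (5–10 fps) — the methods are fps-agnostic by construction.

## Known limitations

- Container video decoding is out of scope; the canonical input is an
  image-sequence directory (or precomputed series CSVs).
- No dynamic time warping, wavelet coherence, peak-picking trajectory
  features, or vocal-output analysis.
- The pseudodyad comparison uses Welch's t-test on per-dyad means; other
  choices (e.g. rank tests) are defensible and not implemented.
- Calibrated severity score conversion for ADOS-2 raw scores is consumed
  as input, never computed.
- The generator's group contrast is a free parameter; synthetic BAC levels
  must not be read as estimates of real-world classification performance.
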