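# Methods

## Feature definitions and conventions

The unit of analysis is a single 2D tumor slice with a binary ROI mask;
features depend only on the in-ROI intensities, never on pixels outside
the mask or on pixel order.

* **Mean / SD** are computed on the raw intensities; SD uses the unbiased
  1/(N−1) estimator.
* **Skewness / kurtosis** use population (1/N) central moments in both
  numerator and denominator: skewness = m₃/m₂^{3/2}, kurtosis = m₄/m₂²
  (non-excess; a Gaussian ROI gives ≈ 3). They are computed on the raw,
  undiscretized intensities: binning first would only discard information,
  and the Gaussian limit of the raw-moment versions is the natural
  reference point. With zero variance both are undefined and returned as
  NaN with a warning rather than an exception, so constant phantoms flow
  through the pipeline.
* **Discretization** resamples the in-ROI intensities into equally spaced
  bins spanning [min, max], assigning a value to bin
  ⌊(x − min)/width⌋ with the maximum clipped into the last bin. The bin
  count is not standardized across the texture-analysis literature and
  commercial packages rarely document theirs; the default here is 32,
  configurable, and recorded in every output row (`n_bins_used`). A
  zero-range ROI puts all mass in one bin (no error).
* **Uniformity** is Σ P(i)² — bounded in (0, 1], 1/k for a flat k-bin
  histogram. An index-weighted variant Σ i·P(i)² is retained behind
  `uniformity_mode="printed"` for auditability; it is not bounded by 1
  and is not used anywhere in the pipeline.
* **Entropy** is −Σ P(i) log₂ P(i) in bits, 0·log 0 := 0; bounded by
  log₂(n_bins).
* **Energy** is defined as the mean squared min-max-normalized intensity,
  (1/N) Σ x̃², x̃ ∈ [0,1] within the ROI. The raw sum Σ X(i)² (available
  as `energy_mode="printed"`) grows without bound with ROI size and
  intensity scale and cannot be compared across patients; the normalized
  form is bounded in [0, 1] and is what every other stage consumes. A
  constant ROI is assigned energy 1.0, consistent with the fully ordered
  histogram (uniformity 1, entropy 0).

## Phantom generator

First-order features see only the marginal intensity distribution, so a
phantom whose in-ROI marginal is controlled exactly is — for this pipeline
— statistically equivalent to a real slice. Each phantom is built by
smoothing white noise (Gaussian kernel, default scale 2 px, which sets a
tumor-like spatial correlation) and rank-transforming the in-ROI pixels
onto a discrete target marginal (histogram matching, exact up to
tie-breaking). The ROI is an ellipse, default semi-axes 25 × 18 px in a
64 × 64 image (~1.4 × 10³ ROI pixels); intensities span 100–350 arbitrary
T2-weighted units.

The target marginal is a two-component mixture over 32 equally spaced
levels: a single bright peak holding mass *f* (the "concentration") plus
a uniform floor holding 1 − *f*. One latent parameter therefore moves all
the response-relevant features together: raising *f* raises uniformity,
energy and kurtosis and lowers entropy and SD. The cohort defaults are

| group | mean *f* (pre) |
|---|---|
| pCR (TRG 1) | 0.60 |
| TRG 1–2, non-pCR | 0.50 |
| TRG 3–5 | 0.40 |

with between-patient SD 0.10, an early-treatment shift of −0.12 (the
histogram broadens under therapy), and a per-patient bright-peak position
drawn from 0.81–0.94 of the intensity range (this decorrelates energy,
which tracks peak position, from uniformity/entropy, which track *f*,
without swamping the concentration effect). These values were calibrated
once, by design, so that a default 59-patient cohort (15 pCR / 44
non-pCR; 30 TRG 1–2 / 29 TRG 3–5 — the emulated study structure) shows
the joint directional pCR signal (uniformity/energy higher, entropy lower
in responders, all p < 0.05) in well over 80% of seeds; they are stored
as the generator defaults and not adjusted per run.

The second rater's contour is simulated by thresholding the signed
distance to the ROI boundary against a smooth random field of amplitude
`rater_jitter` (default 1 px): every boundary point moves by at most the
jitter, jitter 0 is exactly the identity, and larger jitter monotonically
lowers the interobserver ICC. All randomness descends from a single
master seed through a seed sequence; identical seeds give bit-identical
cohorts.

**What the phantoms do not emulate:** spatially structured pathology
(necrosis, mucin lakes), Rician acquisition noise, intensity
non-uniformity fields, inter-scanner variation, or the mildly
right-skewed intensity histograms typical of real T2W tumors (the
peak-plus-floor family is left-skewed). Passing tests on phantoms
establishes that the *pipeline* is correct and well calibrated — not that
the texture features predict response in real patients.

## Statistical procedures

* **ICC**: two-way random-effects, absolute-agreement, single-measurement
  ICC(2,1), computed from the two-way ANOVA mean squares; 95% CI by the
  McGraw–Wong F construction with a Satterthwaite denominator df. This
  variant is chosen because interobserver agreement between
  interchangeable raters is the question — systematic rater offsets must
  count against agreement. The variant label is recorded in every output.
  Agreement bands: 0–0.20 poor, 0.21–0.40 fair, 0.41–0.60 moderate,
  0.61–0.80 good, 0.81–1.00 excellent (half-open on the left; negative
  estimates are bucketed poor with a warning). Simulation at the study
  size (59 subjects × 2 raters) puts the CI's true coverage at ≈ 0.946.
* **Rater averaging**: features are averaged across the rater set per
  (patient, timepoint) before any group analysis.
* **Paired pre-vs-early comparisons**: two-sided Wilcoxon signed-rank,
  zeros dropped (the classical Wilcoxon convention), exact null for ≤ 25
  nonzero tie-free differences, tie-corrected normal approximation
  otherwise.
* **Responder-vs-nonresponder comparisons**: two-sided Mann–Whitney U,
  exact for two tie-free groups of ≤ 8, tie-corrected normal
  approximation otherwise. Summaries are median (Q1–Q3) with linearly
  interpolated quartiles.
* **Multiplicity**: no correction across the 7 parameters × 2 timepoints
  by default (each parameter is reported as its own hypothesis, as is
  conventional in exploratory biomarker tables); Holm adjustment is
  available via `holm=True` / `--holm`.
* **ROC**: empirical AUC via the Mann–Whitney pair-counting identity
  (ties ½); direction oriented so AUC ≥ 0.5 and reported as a `>` or `≤`
  rule; cutoff maximizes the Youden index with the smallest threshold on
  ties; 95% CI from the DeLong structural-components variance. Reported
  sensitivity/specificity are re-derived by applying the cutoff to the
  data (self-consistency is a tested invariant).
* **Feature combination**: features univariately significant at α
  (Mann–Whitney gate, configurable) enter a logistic regression fitted by
  IRLS (binomial GLM). IRLS with pseudo-inverse linear algebra is used
  deliberately: histogram features extracted from matched-marginal
  phantoms can be nearly collinear, where a Newton step on the raw
  Hessian fails. Backward elimination removes the largest Wald p > α per
  step (likelihood-ratio variant behind `criterion="lr"`) until all
  retained features are significant; an empty final set returns a flagged
  intercept-only model. Quasi-complete separation is detected from fitted
  |log-odds| > 25 and reported as a warning naming the worst feature.
* **AUC comparison**: paired DeLong test for correlated ROC curves;
  single-feature scores are orientation-corrected before comparison so
  AUCs are compared on the tabulated (≥ 0.5) scale.
* **No train/test split**: the design this pipeline emulates reports
  apparent performance; every AUC row is labelled `apparent`.

## Numerical and degenerate-input choices

Binning uses the explicit floor formula rather than a generic histogram
routine so that the implementation and its brute-force test oracle share
one boundary convention exactly. Constant ROIs propagate (sd 0, entropy
0, uniformity 1, energy 1, NaN shape statistics with warnings) instead of
erroring. A mask perturbation that would empty the ROI retries at half
jitter, then errors. All-identical ICC input returns 1 with a degenerate
CI and a warning; all-zero paired differences return p = 1 with a
warning. CSV tables round-trip at 12 significant digits and carry a
`# config_hash=… seed=…` stamp (the hash excludes the output directory,
so identical analyses are byte-identical wherever they are written).

## Problem sizes used by the test suite

Unit tests run on reduced cohorts (8–16 patients). The calibration checks
use the emulated study sizes: 59 patients (30/29 TRG, 15/44 pCR) for the
directional study emulation across 100 seeds; 59 × 2 measurements and
2000 replicates for ICC recovery/coverage; 2000 replicates for rank-test
type-I error at n = 30 vs 29 and n = 59 pairs; 50 datasets × 2000
bootstrap draws for the DeLong cross-check.

## Known limitations

Single-slice, 2D, first-order only — no GLCM/GLRLM or filtered textures,
no 3D extraction, no DWI/DCE parameters. Two raters exactly. The
univariate gate into the multivariable model is the rank-test p-value
(a univariate-logistic gate would also be defensible; the gate is
configurable). Apparent performance only; with 7 candidate features and
59 patients the combined model's AUC is optimistic by construction and
should be read as an upper bound.
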