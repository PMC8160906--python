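# Methods

This note records the model, the estimator settings, the synthetic-cohort
design and the numerical choices behind `somnoscreen`, in enough detail to
re-derive every default.

## Signals and spectra

Input signals are maneuver-labeled breath phases (mouth/nose ×
inspiration/expiration) sampled at nominally 10,240 Hz.  Each annotated
segment is sliced half-open `[start, end)`, de-meaned and rescaled to unit
maximum absolute amplitude, so every downstream sound feature measures
spectral *shape* and is exactly invariant to recording gain.  A sampling
rate above 3,600 Hz (twice the 1,800 Hz analysis-band edge) is enforced.

Power spectra use Welch's method with a 1,024-sample Hann window (100 ms at
the nominal rate), 50% overlap and constant detrending, giving a 10 Hz bin
spacing that resolves the catalog's 5 Hz-granular band edges to the nearest
bin.  Spectra are normalized to unit total power over 75–1,800 Hz; the
per-subject, per-maneuver spectrum is the mean of the (≤ 5) per-breath
spectra so every breath carries equal weight.  Band limits are treated as
closed intervals on bin centers.  Band means, ratios and differences are
computed on linear power (the catalog does not specify a scale; linear is
the simplest reading and the choice is recorded here for sensitivity
analysis); band slopes are computed on dB power, with power floored at
1e-12 of the spectrum maximum so an exact-zero bin cannot produce an
infinite slope.  Peak frequencies (both the zero-crossing variant, which
smooths with a 5-bin moving average and takes the first +→− sign change of
the first difference, and the plain variant, which takes the first local
maximum above 10% of the band maximum) are refined to sub-bin resolution by
a parabola through the peak bin and its neighbors.  Without this
refinement, peak features collapse onto a handful of grid values across
subjects, and the downstream outlier-removal + t-test stage becomes wildly
anticonservative on such quasi-discrete data (see *Feature selection*).

## Bispectra

The bispectrum B(f₁,f₂) — the 2-D Fourier transform of the third-order
cumulant — vanishes for Gaussian signals and peaks at bifrequencies whose
phases are quadratically coupled.  The estimator is the indirect
(cumulant-based) conventional one:

* internal decimation to 5,120 Hz (the analysis content ends at 1,800 Hz;
  the bifrequency grid still reaches 2,560 Hz, covering the `2f–f` line up
  to f = 1,070 Hz);
* 1,024-sample records, per-record mean removal, biased third-order
  cumulant on |τ₁|,|τ₂| ≤ 128 lags, averaged across records.  Averaging the
  *cumulant* (not the magnitude) is what cancels non-phase-coupled
  content — a single-record magnitude estimate cannot distinguish coupled
  from uncoupled tones on one realization, because a fixed phase mismatch
  enters only as a fixed cosine factor;
* Parzen lag window as the symmetry-preserving triple product
  w(τ₁)w(τ₂)w(τ₁−τ₂);
* 256-point 2-D FFT → 20 Hz bifrequency grid (the narrowest catalog band,
  1,050–1,120 Hz, spans ≥ 3 bins); the magnitude on the non-negative
  quadrant is kept, and the cumulant is explicitly symmetrized so the
  grid's swap symmetry holds to machine precision.

Per-subject grids are the mean of per-breath magnitude grids.  Features use
|B|, not bicoherence: the catalog gives no normalization, and magnitude is
the conventional output of this estimator class.  Region conventions:
"positive diagonal" is f₁=f₂; "negative diagonal" of a band [f₁,f₂] is the
anti-diagonal {(f, f₁+f₂−f)}; the `2f–f` and `0.5f–f` lines keep only
on-grid points; weights are |B| at the nearest grid node.  Where the
catalog lists distinct "weight center" and "first-order moment" features on
the same region, the weight center is the (interpolated) weighted median
and the first-order moment the weighted mean — the minimal pair of distinct
location statistics; the second-order moment is the weighted variance about
the weighted mean.  The interpolated median (piecewise-linear CDF with mass
centered on each node, inverted at 0.5) is used instead of a raw
"first node past cumulative 0.5" rule for the same anti-discreteness reason
as the parabolic peak refinement.  "Total" regions span 0–1,800 Hz.

The Higuchi fractal dimension uses kmax = 8 and is clipped to [1, 2], the
attainable range for sampled real curves; the per-subject value averages
the per-breath estimates.

## Feature catalog

The registry maps each label F1–F79 to (source maneuver, operator,
parameters) and is shipped both in code and as versioned YAML
(`registry.yaml`); a self-check verifies the count, band ordering and
maneuver assignments.  Band limits that print in descending order are
stored ordered (printing order is typographic).  Composite features
(difference or ratio of two band means) are encoded as composition entries.
Feature computation is a pure function of its inputs; any per-feature
failure is recorded as missing with a reason, never silently zero.

## Threshold determination

PSG values are variance-stabilized: sample skewness ≤ −0.5 → squared,
≥ 0.5 → log (shifted by +1 only when zeros are present), otherwise
unchanged.  The observed range of the scaled values is divided into 20
equal parts; the 19 interior cut points are the candidates (the printed
worked example — range [0.5, 7] → 0.825, 1.15, …, 6.675 — fixes the
interior-points convention).  Each candidate is scored by the spectral gap:
per maneuver, group mean dB spectra over 75–1,800 Hz with pointwise 95%
confidence bands (mean ± 1.96·SE); over the bins where the two bands are
disjoint, the mean distance between the nearer boundaries; zero if none;
averaged over the maneuvers with ≥ 2 subjects per group.  dB spectra are
used because group comparison on a log scale stabilizes variance across
subjects.  Among candidates leaving ≥ 20 subjects on each side the largest
gap wins, ties toward the smaller threshold; an optional physiological
override picks the nearest eligible candidate instead.

Because the threshold is itself learned, the five blind-test
configurations are stratified on a provisional median split of the scaled
values; each configuration then learns its own threshold from its 80%
training/validation subjects only (the scan never sees a test fold), and
the reported threshold is the modal selection across configurations.  With
thresholds constrained to keep ≥ 20 of ~96 training subjects per side,
selections concentrate near the middle of the distribution, so the
provisional stratification is close to the final one.

## Feature selection

Three stages, training data only: (1) de-duplication — for each feature
pair with |Pearson r| ≥ 0.95, the member with the lower |r| against the
scaled PSG values is dropped; (2) per-group outlier removal by Tukey fences
(outside Q1 − 1.5·IQR, Q3 + 1.5·IQR), removed entries becoming missing for
that feature only; (3) Welch two-sample t-test gate at p ≤ 0.05 (Welch
because the groups differ in size and variance).  Constant columns and
features with < 3 non-missing values in either group are dropped with a
logged reason.  Trimming before testing is mildly anticonservative in
general; on a zero-effect cohort the full stage retains about 5–7% of the
sound features, which the test suite checks by seeded calibration.

## Bilinear modeling

For k ∈ {3,4,5} features the model has all pairwise products, all linear
terms and an intercept — C(k,2) + k + 1 coefficients (7 for k = 3; no
triple products, which overfit cohort-scale n).  Design columns are
standardized before the products are formed, so coefficient magnitudes are
comparable across features with different units; the raw-scale
parametrization is recovered analytically (`raw_coefficients_`).  Fits
require ≥ 5 complete cases per coefficient; rank-deficient designs drop
the combination rather than erroring.  Exhaustive enumeration over the
selected features is capped at 20,000 combinations (seeded subsample
beyond the cap).  Models are ranked lexicographically by |Spearman ρ|
descending (absolute value: a strongly anti-correlated model is as useful
to a two-class screen), then overlap percentage ascending — overlap being
the share of subjects whose predictions fall inside the closed intersection
of the two groups' prediction ranges — with a deterministic label-order
tie-break; the top 20 survive.

## Classification

Each surviving model's scalar output feeds a repeated-holdout random
forest: per iteration a stratified 65/35 train/validation split and a
small forest (25 trees, depth ≤ 4 — the input is one-dimensional, so large
forests add nothing), with validation confusions pooled across iterations;
the iteration count is interpreted as the number of holdout rounds (1,200
by default) since the repeated 65/35 split is what the count attaches to.
The frozen classifier is the majority vote of all iteration forests and is
applied exactly once to the blind-test fold.  Pooled-confusion metrics
equal mean per-iteration metrics here because stratified splits fix the
per-iteration class counts.  Admissible models need accuracy ≥ 70% and
sensitivity/specificity ≥ 50% on validation and test (inclusive).  Three-
model combinations vote per subject over cast (non-missing) votes; ties go
to the abnormal class, the screening-conservative direction; a subject
with no cast votes is excluded and reduces coverage (coverage = share of
subjects with at least one vote; with fewer than three admissible models
the best single model is used, logged).  Combinations are scored by
(coverage, then blind-test accuracy); the five configurations' metrics are
averaged, with min/max retained.  Every reported metric quadruple derives
from a stored confusion matrix.

All randomness descends from one run-level seed through documented
`SeedSequence` paths per (parameter, fold, model, iteration).

## Synthetic cohorts

The generator produces the statistical structure the pipeline consumes and
nothing more — it is filtered noise, not an airway simulation:

* **Severity**: lognormal(0, 0.5); its z-scored log drives all effects.
* **Sounds**: per breath, Gaussian noise shaped in the frequency domain by
  two broad resonances (~200/240 Hz and ~820/900 Hz depending on maneuver)
  over a decaying floor.  Each subject draws anatomical resonance shifts
  (SD 25 and 60 Hz), width and gain factors — real airways differ between
  people, and without this variation peak-location features are degenerate
  across subjects; small breath-to-breath wobble (SD 4/8 Hz) is added.
  Severity shifts band gain by (−2.5, +2.5, +2.5, +2.5) dB per severity SD
  in the four gap bands 150–300, 720–900, 1,050–1,120, 1,450–1,700 Hz
  (low-frequency power falls and high-frequency power rises with
  severity), with raised-cosine 30 Hz edges.  A quadratically coupled tone
  triple (180, 220, 400 Hz; φ₃ = φ₁+φ₂, phases redrawn per breath) with
  amplitude 0.15 + 0.08·z times the noise RMS makes bispectral features
  informative.  Five breaths of 1.2 s per maneuver.
* **Anthropometrics**: neck circumference 41.5 + 2.2·z ± 3.5 cm and BMI
  32.5 + 2·z ± 4.5 kg/m² (severity-linked, matching typical cohort
  contrasts); age severity-neutral (50 ± 10); sex via a logistic link
  (log-odds 0.1 + 0.6·z); Mallampati from a thresholded latent.
* **PSG parameters**: "Total Arousal Index" = 24·exp(0.55·z + ε),
  ε ~ N(0, 0.3), clipped to [0, 130] — lognormal-shaped and strongly
  severity-linked (Spearman ρ with severity ≈ 0.88 at default noise);
  "Mean SpO2% Total TST" = 94 − 1.6·z + N(0, 0.9), clipped to [75, 100].
  A warning fires if clipping touches > 20% of values.
* `CohortSpec.null()` zeroes every sound and anthropometric effect while
  keeping the PSG links, for calibration experiments.

What passing tests on these cohorts do **not** show: robustness to real
recording artifacts (swallowing, motion, ambient noise), to heterogeneous
airway pathology beyond two shifted resonances, to breath-phase annotation
errors, or to cohort confounding between anthropometrics and sounds beyond
the shared severity scalar.  Results on synthetic cohorts bound the
pipeline's correctness, not its clinical performance.

## Problem sizes

Cohort-level tests and the acceptance script run 120-subject cohorts with
the default generator but scaled-down search/ensemble settings (100
holdout rounds of 10 trees at depth 3, top 12 models, 2,000-combination
cap); these choices keep a full run in the low minutes on one CPU and were
verified to give the same qualitative behavior as the full-size constants,
which remain the library defaults.  The QPC check uses a 36 s realization;
calibration and recovery checks use 20 seeded repetitions.

## Known limitations

* Automatic breath-phase segmentation is out of scope; annotations are an
  input.
* The five-configuration stratification is provisional-median based (see
  above), a pragmatic resolution of the circularity between learned
  thresholds and stratified folds.
* The overlap statistic uses range intersection, sensitive to extreme
  predictions; it is only a ranking tie-breaker after |ρ|.
* Validation metrics of the final 3-model vote are computed on
  training/validation subjects with frozen ensembles and carry mild
  resubstitution optimism; blind-test metrics are the honest numbers.
* p ≤ 0.05 selection is per-feature with no multiplicity correction,
  matching the screening design; the null calibration quantifies the
  consequence.
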