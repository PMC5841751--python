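# Methods

## The model

A mid-thigh CT cross-section contains three soft-tissue populations with
distinct X-ray attenuation: fat (−200 to −10 HU), loose connective /
water-equivalent tissue (−9 to 40 HU), and normal muscle (41 to 200 HU).
The package models a subject's whole HU distribution as the sum of two
skewed and one standard Gaussian quasi-density:

    f(x) = Σ_{i=1..3}  N_i / (σ_i √(2π)) · exp(−(x−μ_i)²/(2σ_i²))
                        · erfc(α_i (x−μ_i) / (σ_i √2)),     α_2 ≡ 0

Each component integrates to its amplitude `N_i` (the odd erf part of the
erfc factor integrates to zero against the even Gaussian), so amplitudes
are tissue mass fractions when the curve is fitted to a unit-area density.
The centre (connective) component is constrained to a plain Gaussian,
leaving 11 free parameters: 3 amplitudes, 3 locations, 3 widths, 2
skewnesses.

Sign convention: the erfc form makes positive α skew a component towards
*lower* HU; it is the negative of the standard skew-normal shape
parameter. The sampling counterpart (`ntra.cohort.sample_component`) uses
the two-correlated-normals construction with shape −α, and the analytic
component mean is μ − σ·(α/√(1+α²))·√(2/π).

## Preprocessing

Raw CT numbers are mapped to HU by the scanner's affine calibration
`HU = CT × 2.26625 − 190` (applied exactly once; inputs already in HU are
flagged and skipped). Values are binned into 128 uniform bins over
[−200, 200] HU — the union of the three tissue domains — with half-open
bins, the last bin closed, and out-of-range pixels counted and reported
rather than dropped.

Counts are smoothed into an empirical density by convolution with a
Gaussian kernel. No specific smoother is canonical for this task; the
Gaussian kernel was chosen as the simplest integral-conserving
non-parametric option, with default bandwidth 2 bin widths (6.25 HU).
The kernel and bandwidth are recorded in the histogram metadata and are
overridable. After smoothing the curve is rescaled to exact unit area
(or to the in-range pixel count in count mode, so amplitudes proxy
areas).

## Fitting

The 11 parameters are estimated by bound-constrained nonlinear least
squares on the smoothed density at the 128 bin centres
(`scipy.optimize.least_squares`, trust-region reflective). Box
constraints enforce identifiability: each μ_i is confined to its tissue
domain (which also orders μ_1 < μ_2 < μ_3 and prevents label switching),
σ_i ∈ [bin width, 100 HU], α_i ∈ [−20, 20], N_i ∈ [0, 1.05 × total
mass]. The start point is a per-domain method of moments (mass, centroid,
spread of the density restricted to each domain; numerically empty
domains fall back to a 1e−6 amplitude floor at the domain midpoint).
Additional restarts jitter the start point with a seeded generator
(default 4 starts total); the best sum of squared errors wins, and
convergence failure of all restarts is flagged, never silent.

Because the fitted target is a *smoothed* density, the model curve is
convolved with the same smoothing kernel inside the objective
(`match_smoothing=True`). Without this, the smoothing bandwidth leaks
into the fitted widths and, through the width–skew coupling of
overlapping components, occasionally displaces locations by several HU.
With it, the recovered parameters describe the underlying distribution:
median location error ≈ 0.25 HU and median relative amplitude error ≈ 1%
at 10⁵ pixels per subject (recomputed by `scripts/acceptance.py`).
Tolerances default to 1e−10 (xtol/ftol/gtol); fitting raw normalised
counts instead of the smoothed density is available via `use_counts` but
is not the validated path.

## Standard CT metrics

Lean tissue is every in-range pixel strictly above the fat threshold
(default −10 HU, the upper edge of the fat domain — the "maximal density
of fat"); fat is the rest. Areas are pixel counts × pixel area (mm²);
slice thickness does not enter a cross-sectional area. Lean attenuation
is the mean HU of lean pixels and is NaN-flagged when no lean pixels
exist. Because "average HU" conventions differ, both the lean-only mean
and the whole-section mean are emitted.

## Discretization

The number of covariate classes comes from Sturges' rule,
k = ⌈log₂ n + 1⌉; both the raw value and the ceiling are returned, since
cohort tables conventionally report raw values such as 11.4. Covariates are discretized
by exact 1-D k-means: in one dimension the optimal clusters are
contiguous runs of the sorted values, so a dynamic program over the
sorted order finds the global within-cluster-SSE optimum deterministically
— no seed sensitivity, verified against exhaustive partition enumeration.
An L1 (k-medoids) objective is available through the same DP. Age is
stratified by equal-frequency binning (bin sizes differ by at most one,
larger bins first) because its truncated range makes distance-based
clustering inappropriate. Missing values are excluded per covariate
before discretization.

## Binned regression

Within each covariate bin the covariate and every imaging parameter are
averaged (mean by default; median available), giving k points per
(covariate, parameter) pair. Simple OLS with the covariate on the x-axis
yields an R² per pair; pairs with R² ≥ 0.85 (inclusive; |R| mode
available) are selected. For each covariate, a multiple regression of
the binned covariate on its selected parameters is reported with the
ANOVA decomposition and overall F-test.

Two numerical guards apply to the multiple fit. Exactly collinear
predictors are skipped greedily in descending-R² order (fat and lean
area always sum to the section area, so at most one of them can enter).
And the predictor count is capped to preserve at least 5 residual
degrees of freedom (configurable via `min_residual_df`): a near-saturated
model with 1 residual df has an essentially powerless F-test (p ≈ 0.05
despite R ≈ 0.9997), whereas with the cap the same data give p < 1e−5.
No multiple-testing correction is applied; raw p-values are reported
along with the number of tests.

## Synthetic cohort

No public data accompany the method, so the generator is the ground-truth
oracle for every stage. A single latent health factor h ~ U(0, 1) drives
each subject: fat amplitude and width decrease with h, muscle amplitude
increases, the connective location shifts to higher HU (shifts are
centred so h = 0.5 reproduces the base parameters N = (0.30, 0.15, 0.55),
μ = (−60, 10, 52), σ = (25, 12, 14), α = (−2, 0, 1.5)). Pixels are drawn
from the resulting mixture (component choice multinomial in N_i/ΣN_i).
Covariates are affine in h plus Gaussian noise, with physiological signs:
gait speeds and strength rise with health, up-and-go time, cholesterol
and BMI fall. A slope-zero "decoy" covariate exercises the null branch of
the selection rule. Defaults are 1000 subjects at 10⁴ pixels each —
enough that the binned regressions are noise-dominated by neither stage —
and everything is deterministic under the spec seed (byte-identical
output tables).

What the generator does *not* emulate: multi-factor physiology (each
covariate loads on the same single factor), age/sex effects on the
distribution, scanner drift, beam hardening, partial-volume mixing at
tissue boundaries, or spatial structure (pixels are exchangeable).
Passing tests therefore demonstrate that the estimator and pipeline
recover the structure they assume, not that real cohorts satisfy those
assumptions.

## Degenerate inputs and tie-breaks

Empty pixel sets, inverted HU ranges, non-positive bandwidths and
identically-zero densities are rejected with specific errors. A covariate
with zero variance in its bins is rejected in the simple fit; a constant
*response* returns slope 0, R² 0. Equal-frequency ties are broken by
stable sort order. In the pipeline, unreadable subject files are skipped
and logged; more than 10% failures aborts the run.

## Problem sizes

The default validation workloads are 50 recovery fits at 10⁵ pixels each
and one 1000-subject cohort at 10⁴ pixels; together they run in a few
minutes on one CPU, which keeps the analysis reproducible at desk scale.

## Known limitations

- Reported parameter uncertainties are not computed (no bootstrap /
  Hessian-based errors on the 11 parameters).
- Heavily overlapping connective and muscle components can trade mass
  (relative amplitude errors above 5% in a small minority of random
  ground truths) even though locations stay accurate.
- The CT→HU calibration pair (2.26625, −190) is scanner-specific; DICOM
  inputs use their own rescale fields when present.
- Age/sex adjustment of the regressions is out of scope.
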