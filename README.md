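# ntra — nonlinear trimodal regression analysis of CT muscle radiodensity

Age-related muscle degeneration (sarcopenia) shifts the Hounsfield-unit
(HU) distribution of a mid-thigh CT cross-section: fat infiltration moves
mass to negative HU, and the muscle peak weakens and broadens. Standard
CT metrics summarise this with a fat/lean area split and a mean
attenuation. `ntra` instead fits the **entire radiodensitometric
distribution** with a trimodal quasi-probability model,

    f(x) = Σ_{i=1..3}  N_i / (σ_i √(2π)) · e^{−(x−μ_i)²/(2σ_i²)}
                        · erfc(α_i (x−μ_i)/(σ_i √2)),      α₂ ≡ 0,

whose three components occupy the fat [−200, −10], loose-connective
[−9, 40] and muscle [41, 200] HU domains. The 11 free parameters
(amplitudes N, locations μ, widths σ, skewnesses α₁, α₃) quantify tissue
mass, quality and asymmetry per subject. The package then correlates
these parameters — alongside the standard CT metrics — with clinical
covariates (gait speeds, timed up-and-go, isometric leg strength,
cholesterol, BMI) via exact 1-D k-means discretization (k from Sturges'
rule), binned linear regression, an R² ≥ 0.85 selection rule, and
multiple regression with ANOVA/F-tests.

It is aimed at quantitative-imaging and sarcopenia researchers who have
per-subject pixel sets (delimited text or DICOM + mask) and a covariate
table, and at methodologists who want a fully synthetic, ground-truthed
cohort to probe the estimator.

## Worked example

```python
import numpy as np
from ntra import (CohortSpec, PixelSet, build_histogram, smooth_histogram,
                  fit_ntra, standard_metrics, generate_subject)

# one synthetic subject with known ground truth
spec = CohortSpec(pixels_per_subject=100_000)
pixels, truth = generate_subject(latent_health=0.3, spec=spec, seed=21)

hist = smooth_histogram(build_histogram(pixels))   # 128 bins, unit area
fit = fit_ntra(hist, seed=0)
m = standard_metrics(pixels)                       # fat threshold −10 HU

print("true  mu:", truth.mu)
print("fitted mu:", np.round(fit.params.mu, 2), " R² =", round(fit.r_squared, 6))
print("fat/lean area:", m.fat_area, "/", m.lean_area,
      " lean mean HU:", round(m.lean_mean_hu, 2))
```

Output:

```
true  mu: [-60.    8.4  52. ]
fitted mu: [-60.36   8.52  52.25]  R² = 0.999999
fat/lean area: 34045.0 / 65955.0  lean mean HU: 34.53
```

The fitted locations land within half an HU of the generating truth
(note the connective peak sits at 8.4 HU for this below-average subject —
the generator shifts it down with poor health); the fat/lean split says
34% of the section area is at or below −10 HU, and the lean pixels
average ≈ 34.5 HU.

From the shell, the same pipeline end to end:

```sh
ntra simulate --n-subjects 100 --seed 1 --outdir sim
ntra run-all --pixel-dir sim/pixels --covariates sim/covariates.csv \
     --outdir out --seed 1
```

`out/` then contains per-subject `parameters.csv` (11 model parameters +
R² + standard metrics), `assignments.csv` and `bin_summary.csv`
(discretization), `regressions.csv` (per covariate × parameter: slope,
intercept, R², p), `selection.csv` (the R² ≥ 0.85 incidence table),
`multiple_regression.json` (coefficients, multiple R, ANOVA, F, p per
covariate) and a `manifest.json` with content hashes and per-covariate
participation counts.

## Layout

- `ntra.radiodensity` — CT→HU conversion, 128-bin histograms, kernel smoothing
- `ntra.model` — trimodal density, domain-based initialisation, bounded fit
- `ntra.ct_standards` — fat/lean areas, lean and whole-section attenuation
- `ntra.discretization` — Sturges' rule, exact 1-D k-means, equal-frequency bins
- `ntra.regression` — bin aggregation, OLS, selection rule, multiple regression
- `ntra.cohort` — synthetic cohort generator with ground truth
- `ntra.pipeline` / `ntra.cli` — orchestration, config, `ntra` command

See `docs/methods.md` for the model's assumptions, numerical choices and
limitations.
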