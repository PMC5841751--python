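"""Synthetic cohort generator with known ground truth.

Emulates the inputs of a population CT muscle-quality study: per-subject
mid-thigh HU pixel sets drawn from a trimodal skewed-Gaussian mixture,
plus a covariate table (gait speeds, timed up-and-go, leg strength,
cholesterol, BMI, age, sex).  A single latent "health" factor in [0, 1]
drives both the per-subject distribution parameters and the covariates,
so every downstream stage — model fitting, discretization, binned
regression, selection — has an exact ground truth to be checked against.

Coupling signs follow the physiology the analysis is meant to detect:
healthier subjects have less fat mass and more muscle mass, a connective
peak at higher HU, faster gait, stronger knee extension, shorter
up-and-go times, lower cholesterol and lower BMI.  A slope-zero "decoy"
covariate is included by default so the null branch of the selection rule
is exercised too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import NTRAParameters
from .radiodensity import PixelSet

# latent_health enters each covariate as: value = intercept + slope*h + N(0, sd)
#                       intercept  slope   noise sd   unit
DEFAULT_COUPLINGS = {
    "gsn":   (0.80,    0.60,  0.05),   # normal gait speed, m/s
    "gsf":   (1.20,    0.80,  0.07),   # fast gait speed, m/s
    "tug":   (16.0,   -8.00,  0.50),   # timed up-and-go, s
    "str":   (250.0,  200.0, 15.00),   # isometric knee extension, N
    "schol": (6.50,   -1.50,  0.12),   # total cholesterol, mmol/L
    "bmi":   (32.0,   -8.00,  0.60),   # body mass index, kg/m^2
    "decoy": (0.0,     0.00,  1.00),   # pure noise, no coupling
}


def default_base_params() -> NTRAParameters:
    """Population-centre trimodal parameters (mass fractions sum to 1)."""
    return NTRAParameters(
        N=np.array([0.30, 0.15, 0.55]),
        mu=np.array([-60.0, 10.0, 52.0]),
        sigma=np.array([25.0, 12.0, 14.0]),
        alpha=np.array([-2.0, 0.0, 1.5]),
    )


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic cohort."""

    n_subjects: int = 1000
    pixels_per_subject: int = 10_000
    seed: int = 0
    base_params: NTRAParameters = field(default_factory=default_base_params)
    couplings: dict = field(default_factory=lambda: dict(DEFAULT_COUPLINGS))
    age_range: tuple[float, float] = (66.0, 96.0)
    sex_ratio: float = 0.5
    # linear shifts of the trimodal parameters per unit latent health
    d_n_fat: float = -0.24
    d_n_muscle: float = 0.24
    d_mu_connective: float = 8.0
    d_sigma_fat: float = -6.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.pixels_per_subject < 1:
            raise ValueError("cohort sizes must be positive")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must lie in (0, 1)")
        for name, (b0, b1, sd) in self.couplings.items():
            if not (np.isfinite(b0) and np.isfinite(b1)):
                raise ValueError(f"non-finite coupling for {name}")
            if sd < 0:
                raise ValueError(f"negative noise sd for {name}")
        # the healthiest and least healthy subjects must still be valid models
        for h in (0.0, 1.0):
            subject_params(h, self)


def subject_params(latent_health: float, spec: CohortSpec) -> NTRAParameters:
    """Trimodal parameters of a subject at a given latent health.

    Shifts are centred so latent_health = 0.5 reproduces the base
    parameters exactly.
    """
    h = float(latent_health) - 0.5
    base = spec.base_params
    N = base.N + np.array([spec.d_n_fat, 0.0, spec.d_n_muscle]) * h
    mu = base.mu + np.array([0.0, spec.d_mu_connective, 0.0]) * h
    sigma = base.sigma + np.array([spec.d_sigma_fat, 0.0, 0.0]) * h
    return NTRAParameters(N=N, mu=mu, sigma=sigma, alpha=base.alpha.copy())


def sample_component(
    n: int, mu: float, sigma: float, alpha: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n HU values from one skewed-Gaussian component.

    Uses the two-correlated-normals construction of a skew-normal variate
    with shape parameter -alpha (the erfc sign convention skews positive
    alpha towards lower HU): with delta = a / sqrt(1 + a^2),
    x = mu + sigma * (delta*|u0| + sqrt(1-delta^2)*u1).
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = -float(alpha)
    delta = a / np.sqrt(1.0 + a * a)
    u0 = rng.standard_normal(n)
    u1 = rng.standard_normal(n)
    z = delta * np.abs(u0) + np.sqrt(1.0 - delta * delta) * u1
    return mu + sigma * z


def sample_mixture(
    n: int, params: NTRAParameters, rng: np.random.Generator
) -> np.ndarray:
    """Draw n pixels from the trimodal mixture (weights = N_i / sum N)."""
    weights = params.N / params.total_mass
    counts = rng.multinomial(n, weights)
    parts = [
        sample_component(int(c), params.mu[i], params.sigma[i], params.alpha[i], rng)
        for i, c in enumerate(counts)
        if c > 0
    ]
    pixels = np.concatenate(parts)
    rng.shuffle(pixels)
    return pixels


def generate_subject(
    latent_health: float, spec: CohortSpec, seed: int,
    subject_id: str = "S0000",
) -> tuple[PixelSet, NTRAParameters]:
    """Generate one subject's pixel set and its true model parameters."""
    params = subject_params(latent_health, spec)
    rng = np.random.default_rng(seed)
    pixels = sample_mixture(spec.pixels_per_subject, params, rng)
    return (
        PixelSet(subject_id=subject_id, values=pixels, unit="hounsfield"),
        params,
    )


def generate_cohort(
    spec: CohortSpec, outdir: str | Path | None = None
) -> tuple[list[PixelSet], pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort: pixel sets, covariate table, truth table.

    Fully deterministic under ``spec.seed`` (byte-identical tables on
    repeat).  When ``outdir`` is given, writes one pixel CSV per subject
    plus ``covariates.csv`` and ``truth.csv``.
    """
    master = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    subject_seeds = master.generate_state(spec.n_subjects, dtype=np.uint32)

    health = cohort_rng.uniform(0.0, 1.0, spec.n_subjects)
    age = cohort_rng.uniform(*spec.age_range, spec.n_subjects)
    sex = np.where(cohort_rng.uniform(size=spec.n_subjects) < spec.sex_ratio, "M", "F")

    width = max(4, len(str(spec.n_subjects)))
    ids = [f"S{i:0{width}d}" for i in range(1, spec.n_subjects + 1)]

    pixel_sets: list[PixelSet] = []
    truth_rows = []
    for i, sid in enumerate(ids):
        pset, params = generate_subject(
            float(health[i]), spec, int(subject_seeds[i]), subject_id=sid
        )
        pixel_sets.append(pset)
        truth_rows.append(
            {
                "subject_id": sid,
                "latent_health": health[i],
                **{f"N{j+1}": params.N[j] for j in range(3)},
                **{f"mu{j+1}": params.mu[j] for j in range(3)},
                **{f"sigma{j+1}": params.sigma[j] for j in range(3)},
                "alpha1": params.alpha[0],
                "alpha3": params.alpha[2],
            }
        )

    cov = {"subject_id": ids, "age": age, "sex": sex}
    for name, (b0, b1, sd) in spec.couplings.items():
        noise = cohort_rng.normal(0.0, sd, spec.n_subjects) if sd > 0 else 0.0
        cov[name] = b0 + b1 * health + noise
    covariates = pd.DataFrame(cov)
    truth = pd.DataFrame(truth_rows)

    if outdir is not None:
        outdir = Path(outdir)
        pix_dir = outdir / "pixels"
        pix_dir.mkdir(parents=True, exist_ok=True)
        for pset in pixel_sets:
            np.savetxt(pix_dir / f"{pset.subject_id}.csv", pset.values, fmt="%.4f")
        covariates.to_csv(outdir / "covariates.csv", index=False, float_format="%.6g")
        truth.to_csv(outdir / "truth.csv", index=False, float_format="%.6g")

    return pixel_sets, covariates, truth


def random_parameters(rng: np.random.Generator) -> NTRAParameters:
    """Draw a realistic random ground-truth parameter set.

    Ranges keep each component well inside its tissue domain with
    physiologically plausible widths and inward skews; used for parameter
    recovery studies.
    """
    N = rng.dirichlet([4.0, 2.0, 5.0])
    mu = np.array(
        [rng.uniform(-90, -40), rng.uniform(0, 30), rng.uniform(45, 60)]
    )
    sigma = np.array(
        [rng.uniform(15, 30), rng.uniform(8, 15), rng.uniform(10, 16)]
    )
    alpha = np.array([rng.uniform(-3.0, -0.5), 0.0, rng.uniform(0.5, 2.5)])
    return NTRAParameters(N=N, mu=mu, sigma=sigma, alpha=alpha)
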