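"""The trimodal skewed-Gaussian radiodensity model and its fitting routine.

A soft-tissue HU distribution is modelled as the sum of three
quasi-probability components — fat, loose connective / water-equivalent
tissue, and muscle — each of the form

    phi(x; N, mu, sigma, alpha)
        = N / (sigma * sqrt(2*pi)) * exp(-(x-mu)^2 / (2*sigma^2))
          * erfc(alpha * (x - mu) / (sigma * sqrt(2)))

so that the integral of each component equals its amplitude ``N`` (the
odd erf part integrates to zero against the even Gaussian).  The centre
component is constrained to a plain Gaussian (alpha = 0), leaving 11 free
parameters: three amplitudes, three locations, three widths and two
skewnesses.  Note the erfc convention: positive ``alpha`` skews the
component towards lower HU (it is the negative of the standard
skew-normal shape parameter).

Fitting is bound-constrained nonlinear least squares of the model against
the smoothed empirical density at the bin centres, with each location
confined to its tissue attenuation domain; that ordering constraint is
what makes the three components identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.special import erfc

from .radiodensity import HUHistogram

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)

#: Number of free parameters of the trimodal model (3 N + 3 mu + 3 sigma +
#: 2 alpha; the centre skewness is pinned at zero).
N_FREE_PARAMETERS = 11


@dataclass(frozen=True)
class TissueDomains:
    """Disjoint, ascending HU intervals occupied by the three tissues."""

    fat: tuple[float, float] = (-200.0, -10.0)
    connective: tuple[float, float] = (-9.0, 40.0)
    muscle: tuple[float, float] = (41.0, 200.0)

    def __post_init__(self) -> None:
        ivals = self.intervals
        for lo, hi in ivals:
            if not lo < hi:
                raise ValueError(f"degenerate tissue interval ({lo}, {hi})")
        for (_, hi), (lo, _) in zip(ivals[:-1], ivals[1:]):
            if not hi < lo:
                raise ValueError("tissue intervals must be disjoint and ascending")

    @property
    def intervals(self) -> list[tuple[float, float]]:
        return [self.fat, self.connective, self.muscle]


@dataclass
class NTRAParameters:
    """The 11-parameter state of the trimodal model.

    Component index 0 is fat, 1 connective/water-equivalent, 2 muscle.
    ``alpha[1]`` is identically zero.
    """

    N: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        for name in ("N", "mu", "sigma", "alpha"):
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must have exactly 3 entries")
        if np.any(self.N < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(self.sigma <= 0):
            raise ValueError("widths must be positive")
        if self.alpha[1] != 0.0:
            raise ValueError("centre component skewness is fixed at zero")
        if not (self.mu[0] < self.mu[1] < self.mu[2]):
            raise ValueError("locations must be ordered mu_fat < mu_conn < mu_muscle")

    def to_vector(self) -> np.ndarray:
        """Pack the 11 free entries: N1..3, mu1..3, sigma1..3, alpha1, alpha3."""
        return np.concatenate(
            [self.N, self.mu, self.sigma, [self.alpha[0], self.alpha[2]]]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "NTRAParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_FREE_PARAMETERS,):
            raise ValueError(f"expected {N_FREE_PARAMETERS} free parameters")
        return cls(
            N=vec[0:3],
            mu=vec[3:6],
            sigma=vec[6:9],
            alpha=np.array([vec[9], 0.0, vec[10]]),
        )

    @property
    def total_mass(self) -> float:
        return float(self.N.sum())

    def component_means(self) -> np.ndarray:
        """Analytic mean of each component: mu - sigma*delta*sqrt(2/pi)."""
        delta = self.alpha / np.sqrt(1.0 + self.alpha**2)
        return self.mu - self.sigma * delta * np.sqrt(2.0 / np.pi)


@dataclass
class FitResult:
    params: NTRAParameters
    r_squared: float
    sse: float
    n_iterations: int
    converged: bool
    n_restarts_used: int = 1
    restart_sse: list[float] = field(default_factory=list)


def component_density(x, N: float, mu: float, sigma: float, alpha: float):
    """Evaluate one skewed-Gaussian quasi-density component.

    The integral over the real line equals ``N``; the density is
    non-negative everywhere.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    return N / (sigma * _SQRT2PI) * np.exp(-0.5 * z**2) * erfc(alpha * z / _SQRT2)


def trimodal_density(x, params: NTRAParameters):
    """Pointwise sum of the three tissue components."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for i in range(3):
        out = out + component_density(
            x, params.N[i], params.mu[i], params.sigma[i], params.alpha[i]
        )
    return out


def initialize_from_domains(
    hist: HUHistogram, domains: TissueDomains = TissueDomains()
) -> NTRAParameters:
    """Method-of-moments start point: per-domain mass, centroid, spread.

    A domain with zero mass gets a small amplitude floor and its midpoint
    as location rather than failing.
    """
    if hist.density is None:
        raise ValueError("histogram density not populated; smooth it first")
    x = hist.bin_centers
    d = hist.density
    w = hist.bin_width

    N0, mu0, s0 = [], [], []
    for lo, hi in domains.intervals:
        sel = (x >= lo) & (x <= hi)
        mass = float(np.sum(d[sel]) * w)
        if mass <= 1e-6:  # numerically empty domain
            N0.append(1e-6)
            mu0.append(0.5 * (lo + hi))
            s0.append(max(w, (hi - lo) / 4.0))
            continue
        m = float(np.sum(x[sel] * d[sel]) * w / mass)
        var = float(np.sum((x[sel] - m) ** 2 * d[sel]) * w / mass)
        N0.append(mass)
        mu0.append(min(max(m, lo), hi))
        s0.append(max(np.sqrt(var), w))
    return NTRAParameters(
        N=np.array(N0), mu=np.array(mu0), sigma=np.array(s0), alpha=np.zeros(3)
    )


def default_bounds(
    hist: HUHistogram, domains: TissueDomains, total_mass: float
) -> tuple[np.ndarray, np.ndarray]:
    """Box constraints enforcing trimodal identifiability.

    Locations are confined to their tissue domains, widths to
    [bin width, 100 HU], skewnesses to [-20, 20] and amplitudes to
    [0, total mass].
    """
    w = hist.bin_width
    lo = np.array(
        [0.0, 0.0, 0.0]
        + [domains.fat[0], domains.connective[0], domains.muscle[0]]
        + [w, w, w]
        + [-20.0, -20.0]
    )
    hi = np.array(
        [total_mass, total_mass, total_mass]
        + [domains.fat[1], domains.connective[1], domains.muscle[1]]
        + [100.0, 100.0, 100.0]
        + [20.0, 20.0]
    )
    return lo, hi


def fit_ntra(
    hist: HUHistogram,
    init: NTRAParameters | str = "auto",
    domains: TissueDomains = TissueDomains(),
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-10,
    max_iter: int = 5000,
    n_restarts: int = 4,
    seed: int = 0,
    use_counts: bool = False,
    match_smoothing: bool = True,
) -> FitResult:
    """Fit the 11-parameter trimodal model to a smoothed HU density.

    Minimises the sum of squared residuals between the model and the
    empirical density at the bin centres under box constraints, restarting
    from jittered initialisations and keeping the best solution.  The
    centre skewness is held at zero throughout.  Non-convergence of every
    restart is reported via ``converged=False``, never silently.

    When the target density was kernel-smoothed (``hist.bandwidth`` set)
    and ``match_smoothing`` is true, the model curve is convolved with the
    same kernel inside the objective, so the recovered parameters describe
    the underlying distribution rather than its smoothed image — otherwise
    the smoothing bandwidth would leak into the fitted widths.

    ``use_counts`` fits the raw normalised counts instead of the smoothed
    density (offered as an option, not the validated default).
    """
    if use_counts:
        y = hist.counts / (hist.counts.sum() * hist.bin_width)
    else:
        if hist.density is None:
            raise ValueError("histogram density not populated; smooth it first")
        y = hist.density
    if y.size < 32:
        raise ValueError("need density on at least 32 bins")
    if not np.any(y > 0):
        raise ValueError("density is identically zero; nothing to fit")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    x = hist.bin_centers
    total_mass = float(np.trapezoid(y, x))
    if bounds is None:
        lo, hi = default_bounds(hist, domains, 1.05 * total_mass)
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
        if lo.shape != (N_FREE_PARAMETERS,) or hi.shape != (N_FREE_PARAMETERS,):
            raise ValueError("bounds must each have 11 entries")
        if np.any(lo >= hi):
            raise ValueError("invalid bounds: lower >= upper")

    if isinstance(init, str):
        if init != "auto":
            raise ValueError(f"unknown init {init!r}")
        if hist.density is None:  # counts mode on an unsmoothed histogram
            init_hist = replace(hist, density=y)
        else:
            init_hist = hist
        init = initialize_from_domains(init_hist, domains)
    x0 = np.clip(init.to_vector(), lo + 1e-12, hi - 1e-12)

    kernel_sigma_bins = 0.0
    if match_smoothing and not use_counts and hist.bandwidth is not None:
        kernel_sigma_bins = hist.bandwidth / hist.bin_width

    def residuals(vec: np.ndarray) -> np.ndarray:
        # inlined model evaluation; avoids dataclass validation in the hot loop
        n1, n2, n3, m1, m2, m3, s1, s2, s3, a1, a3 = vec
        model = (
            n1 / (s1 * _SQRT2PI)
            * np.exp(-0.5 * ((x - m1) / s1) ** 2)
            * erfc(a1 * (x - m1) / (s1 * _SQRT2))
            + n2 / (s2 * _SQRT2PI) * np.exp(-0.5 * ((x - m2) / s2) ** 2)
            + n3 / (s3 * _SQRT2PI)
            * np.exp(-0.5 * ((x - m3) / s3) ** 2)
            * erfc(a3 * (x - m3) / (s3 * _SQRT2))
        )
        if kernel_sigma_bins > 0:
            model = gaussian_filter1d(model, kernel_sigma_bins, mode="constant")
        return model - y

    rng = np.random.default_rng(seed)
    best = None
    restart_sse: list[float] = []
    any_converged = False
    for r in range(n_restarts):
        if r == 0:
            start = x0
        else:
            jitter = rng.normal(0.0, 0.1, size=x0.size) * (hi - lo)
            start = np.clip(x0 + jitter, lo + 1e-12, hi - 1e-12)
        res = least_squares(
            residuals,
            start,
            bounds=(lo, hi),
            method="trf",
            xtol=tol,
            ftol=tol,
            gtol=tol,
            max_nfev=max_iter,
        )
        sse = float(np.sum(res.fun**2))
        restart_sse.append(sse)
        any_converged = any_converged or (res.status > 0)
        if best is None or sse < best[1]:
            best = (res, sse)

    res, sse = best
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 0.0
    params = NTRAParameters.from_vector(res.x)
    return FitResult(
        params=params,
        r_squared=max(min(r2, 1.0), 0.0),
        sse=sse,
        n_iterations=int(res.nfev),
        converged=bool(any_converged),
        n_restarts_used=n_restarts,
        restart_sse=restart_sse,
    )


def refit(hist: HUHistogram, result: FitResult, **kwargs) -> FitResult:
    """Refit starting from a previous solution (idempotence check helper)."""
    return fit_ntra(hist, init=result.params, n_restarts=1, **kwargs)
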