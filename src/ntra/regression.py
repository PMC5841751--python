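"""Binned regression of imaging parameters against clinical covariates.

Subjects are grouped into covariate bins (from the discretization stage);
within each bin the covariate and every imaging parameter are averaged,
giving one (x, y) point per bin.  Per-parameter ordinary least squares on
these binned points yields an R² per (covariate, parameter) pair;
parameters crossing a fidelity threshold (default R² ≥ 0.85) are then
assembled into a multiple regression of the covariate on the selected
parameters, reported with its ANOVA table and overall F-test.

No multiple-testing correction is applied; raw p-values are reported
together with the number of tests performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_SELECTION_THRESHOLD = 0.85


@dataclass
class BinnedSeries:
    """Per-bin aggregated (covariate, imaging parameter) pairs."""

    covariate_name: str
    parameter_name: str
    x: np.ndarray  # per-bin covariate representative, strictly monotone
    y: np.ndarray  # per-bin mean of the imaging parameter
    bin_n: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.bin_n = np.asarray(self.bin_n, dtype=int)
        if not (self.x.size == self.y.size == self.bin_n.size):
            raise ValueError("x, y and bin_n must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("bin representatives must be strictly increasing")

    @property
    def k(self) -> int:
        return self.x.size


@dataclass
class RegressionResult:
    covariate_name: str
    parameter_name: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass
class MultipleRegressionResult:
    covariate_name: str
    parameter_names: list[str]
    coefficients: np.ndarray  # intercept first
    multiple_r: float
    f_statistic: float
    p_value: float
    df: tuple[int, int]  # (model, residual)
    anova: dict = field(default_factory=dict)


def aggregate_bins(
    labels: np.ndarray,
    covariate: np.ndarray,
    parameters: pd.DataFrame,
    covariate_name: str = "covariate",
    statistic: str = "mean",
) -> list[BinnedSeries]:
    """Aggregate per-subject parameters within covariate bins.

    ``labels`` are 1-based bin indices aligned with ``covariate`` and the
    rows of ``parameters``.  Each bin contributes the mean (or median for
    ``statistic="medoid"``) covariate as x and the corresponding
    aggregated parameter as y; series are ordered by x.
    """
    labels = np.asarray(labels, dtype=int)
    covariate = np.asarray(covariate, dtype=float)
    if not (labels.size == covariate.size == len(parameters)):
        raise ValueError("labels, covariate and parameters must align")
    if statistic not in ("mean", "medoid"):
        raise ValueError(f"unknown aggregation statistic {statistic!r}")
    agg = "mean" if statistic == "mean" else "median"

    frame = parameters.copy()
    frame["_x"] = covariate
    frame["_bin"] = labels
    grouped = frame.groupby("_bin")
    sizes = grouped.size()
    empty = [b for b in range(1, int(labels.max()) + 1) if b not in sizes.index]
    if empty:
        raise ValueError(f"empty covariate bin(s) after joining: {empty}")
    means = getattr(grouped, agg)()
    order = np.argsort(means["_x"].to_numpy())

    out = []
    for col in parameters.columns:
        out.append(
            BinnedSeries(
                covariate_name=covariate_name,
                parameter_name=str(col),
                x=means["_x"].to_numpy()[order],
                y=means[col].to_numpy()[order],
                bin_n=sizes.to_numpy()[order],
            )
        )
    return out


def linear_fit(series: BinnedSeries) -> RegressionResult:
    """Ordinary least squares of the binned parameter on the covariate."""
    if series.k < 3:
        raise ValueError("need at least 3 bins for a linear fit")
    if np.ptp(series.x) == 0 or np.var(series.x) == 0:
        raise ValueError("zero variance in covariate bins")
    if np.var(series.y) == 0:
        # constant response: zero slope, no explained variance
        return RegressionResult(
            series.covariate_name, series.parameter_name,
            slope=0.0, intercept=float(series.y[0]), r_squared=0.0, p_value=1.0,
        )
    fit = stats.linregress(series.x, series.y)
    return RegressionResult(
        covariate_name=series.covariate_name,
        parameter_name=series.parameter_name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def select_high_fidelity(
    results: list[RegressionResult],
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
    on: str = "r2",
) -> pd.DataFrame:
    """Parameter × covariate incidence table of high-fidelity relationships.

    A (covariate, parameter) pair is selected when its R² (or |R| with
    ``on="abs_r"``) is at least ``threshold``; the comparison is
    inclusive.  An empty selection is a legal outcome.
    """
    if on not in ("r2", "abs_r"):
        raise ValueError(f"unknown selection quantity {on!r}")
    rows = []
    for r in results:
        value = r.r_squared if on == "r2" else float(np.sqrt(r.r_squared))
        rows.append(
            {
                "covariate": r.covariate_name,
                "parameter": r.parameter_name,
                "r_squared": r.r_squared,
                "selected": bool(value >= threshold),
            }
        )
    return pd.DataFrame(rows)


def multiple_fit(
    covariate_bins: np.ndarray,
    selected_parameters: pd.DataFrame,
    covariate_name: str = "covariate",
) -> MultipleRegressionResult:
    """OLS of the binned covariate on the selected parameter bin-means.

    Reports the multiple correlation coefficient, the ANOVA decomposition
    and the overall F-test.  A rank-deficient predictor matrix is rejected
    with the collinear columns named.
    """
    y = np.asarray(covariate_bins, dtype=float)
    X = selected_parameters.to_numpy(dtype=float)
    k, p = X.shape
    if y.size != k:
        raise ValueError("covariate bins and parameter rows must align")
    if k <= p + 1:
        raise ValueError(
            f"need more observations than predictors + 1 (k={k}, p={p})"
        )
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns whose removal restores full rank
        collinear = []
        for j, name in enumerate(selected_parameters.columns):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(str(name))
        raise ValueError(f"rank-deficient predictor matrix; collinear columns: {collinear}")

    model = sm.OLS(y, design).fit()
    anova = {
        "ss_model": float(model.ess),
        "ss_resid": float(model.ssr),
        "ss_total": float(model.centered_tss),
        "df_model": int(model.df_model),
        "df_resid": int(model.df_resid),
        "ms_model": float(model.ess / model.df_model),
        "ms_resid": float(model.ssr / model.df_resid) if model.df_resid > 0 else float("nan"),
    }
    return MultipleRegressionResult(
        covariate_name=covariate_name,
        parameter_names=[str(c) for c in selected_parameters.columns],
        coefficients=np.asarray(model.params),
        multiple_r=float(np.sqrt(max(model.rsquared, 0.0))),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        df=(int(model.df_model), int(model.df_resid)),
        anova=anova,
    )
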