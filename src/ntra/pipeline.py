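"""End-to-end orchestration: pixels → model parameters → binned regression.

The pipeline runs, per subject, histogram construction, smoothing, the
trimodal fit and the standard CT metrics; discretizes each clinical
covariate; aggregates imaging parameters within covariate bins; fits
per-parameter linear regressions; applies the high-fidelity selection
rule; and runs a multiple regression of each covariate on its selected
parameters.  All outputs are plain CSV/JSON plus a manifest with content
hashes so a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ct_standards import DEFAULT_FAT_THRESHOLD, standard_metrics
from .discretization import equal_frequency_bins, kmeans_1d, sturges
from .model import fit_ntra
from .radiodensity import (
    DEFAULT_HU_RANGE,
    DEFAULT_N_BINS,
    PixelSet,
    build_histogram,
    read_pixel_csv,
    smooth_histogram,
)
from .regression import (
    DEFAULT_SELECTION_THRESHOLD,
    aggregate_bins,
    linear_fit,
    multiple_fit,
    select_high_fidelity,
)

logger = logging.getLogger("ntra")

PARAM_COLUMNS = [
    "N1", "N2", "N3", "mu1", "mu2", "mu3",
    "sigma1", "sigma2", "sigma3", "alpha1", "alpha3",
]
METRIC_COLUMNS = ["fat_area", "lean_area", "lean_mean_hu", "avg_hu"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated settings for a full pipeline run."""

    pixel_dir: str | None = None
    covariate_table: str | None = None
    output_dir: str = "ntra_out"
    # histogram
    n_bins: int = DEFAULT_N_BINS
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE
    bandwidth: float | str = "auto"
    normalize: bool = True
    # fit
    tol: float = 1e-10
    n_restarts: int = 4
    seed: int = 0
    # thresholds
    fat_threshold: float = DEFAULT_FAT_THRESHOLD
    selection_threshold: float = DEFAULT_SELECTION_THRESHOLD
    selection_on: str = "r2"
    # discretization
    k_override: int | None = None
    discretization_method: str = "kmeans_1d"
    covariate_columns: list[str] | None = None
    max_failure_fraction: float = 0.10
    # multiple regression: residual degrees of freedom to preserve; a
    # saturated model (df_resid ~ 1) makes the overall F-test powerless
    min_residual_df: int = 5

    def validate(self) -> None:
        if self.n_bins < 8:
            raise PipelineError("n_bins must be >= 8")
        lo, hi = self.hu_range
        if not lo < hi:
            raise PipelineError(f"inverted hu_range ({lo}, {hi})")
        if self.bandwidth != "auto" and float(self.bandwidth) <= 0:
            raise PipelineError("bandwidth must be positive")
        if self.n_restarts < 1:
            raise PipelineError("n_restarts must be >= 1")
        if not 0 < self.selection_threshold <= 1:
            raise PipelineError("selection_threshold must lie in (0, 1]")
        if self.k_override is not None and self.k_override < 2:
            raise PipelineError("k override must be >= 2")
        if self.discretization_method not in ("kmeans_1d", "equal_frequency"):
            raise PipelineError(
                f"unknown discretization method {self.discretization_method!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(path.read_text())
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            raise PipelineError(f"unsupported config format {path.suffix!r}")
        cfg = cls(**data)
        if isinstance(cfg.hu_range, list):
            cfg.hu_range = tuple(cfg.hu_range)
        return cfg


@dataclass
class PipelineResult:
    parameters: pd.DataFrame        # per-subject fitted parameters + metrics
    assignments: pd.DataFrame       # subject_id, covariate, bin_index
    bin_summary: pd.DataFrame
    regressions: pd.DataFrame       # covariate, parameter, slope, intercept, r2, p
    selection: pd.DataFrame
    multiple: dict                  # covariate -> multiple-regression report
    failures: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def fit_subject(
    pixels: PixelSet, config: PipelineConfig
) -> dict:
    """Run histogram → smooth → trimodal fit → standard metrics for one subject."""
    hist = build_histogram(pixels, n_bins=config.n_bins, hu_range=config.hu_range)
    hist = smooth_histogram(hist, bandwidth=config.bandwidth, normalize=config.normalize)
    fit = fit_ntra(
        hist,
        tol=config.tol,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )
    metrics = standard_metrics(
        pixels, fat_threshold=config.fat_threshold, hu_range=config.hu_range
    )
    p = fit.params
    return {
        "subject_id": pixels.subject_id,
        "N1": p.N[0], "N2": p.N[1], "N3": p.N[2],
        "mu1": p.mu[0], "mu2": p.mu[1], "mu3": p.mu[2],
        "sigma1": p.sigma[0], "sigma2": p.sigma[1], "sigma3": p.sigma[2],
        "alpha1": p.alpha[0], "alpha3": p.alpha[2],
        "r_squared": fit.r_squared,
        "converged": fit.converged,
        "fat_area": metrics.fat_area,
        "lean_area": metrics.lean_area,
        "lean_mean_hu": metrics.lean_mean_hu,
        "avg_hu": metrics.avg_hu,
    }


def analyze_cohort(
    pixel_sets: list[PixelSet],
    covariates: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    config = config or PipelineConfig()
    config.validate()

    t0 = time.perf_counter()
    rows, failures = [], []
    for pset in pixel_sets:
        try:
            rows.append(fit_subject(pset, config))
        except Exception as exc:  # pragma: no cover - defensive path
            failures.append(pset.subject_id)
            logger.warning("subject %s failed: %s", pset.subject_id, exc)
    if not rows:
        raise PipelineError("all subjects failed")
    if len(failures) > config.max_failure_fraction * len(pixel_sets):
        raise PipelineError(
            f"{len(failures)}/{len(pixel_sets)} subjects failed "
            f"(> {config.max_failure_fraction:.0%})"
        )
    params = pd.DataFrame(rows)
    logger.info(
        "fitted %d subjects in %.1f s", len(rows), time.perf_counter() - t0
    )

    merged = params.merge(covariates, on="subject_id", how="inner")
    if merged.empty:
        raise PipelineError("no overlap between pixel subjects and covariate table")
    dropped = len(params) - len(merged)
    if dropped:
        logger.info("dropped %d subjects without covariates", dropped)

    cov_cols = config.covariate_columns
    if cov_cols is None:
        cov_cols = [
            c for c in covariates.columns
            if c not in ("subject_id", "age", "sex")
        ]
    param_cols = PARAM_COLUMNS + METRIC_COLUMNS

    assign_rows, summary_rows, reg_results = [], [], []
    per_cov = {}
    for cov in cov_cols:
        values = merged[cov].to_numpy(dtype=float)
        ok = np.isfinite(values)
        vals = values[ok]
        sub = merged.loc[ok].reset_index(drop=True)
        if config.k_override is not None:
            k = config.k_override
        else:
            _, k = sturges(vals.size)
        if config.discretization_method == "equal_frequency":
            assignment = equal_frequency_bins(vals, k)
        else:
            assignment = kmeans_1d(vals, k, seed=config.seed)

        for sid, b in zip(sub["subject_id"], assignment.labels):
            assign_rows.append({"subject_id": sid, "covariate": cov, "bin_index": int(b)})
        for b in range(1, k + 1):
            seg = vals[assignment.labels == b]
            summary_rows.append(
                {
                    "covariate": cov, "bin_index": b, "n": int(seg.size),
                    "mean": float(seg.mean()), "min": float(seg.min()),
                    "max": float(seg.max()),
                }
            )

        series = aggregate_bins(
            assignment.labels, vals, sub[param_cols], covariate_name=cov
        )
        fits = [linear_fit(s) for s in series]
        reg_results.extend(fits)
        per_cov[cov] = (assignment, vals, sub, series, fits)

    selection = select_high_fidelity(
        reg_results, threshold=config.selection_threshold, on=config.selection_on
    )

    multiple = {}
    for cov, (assignment, vals, sub, series, fits) in per_cov.items():
        sel = selection[(selection.covariate == cov) & selection.selected]
        chosen = sel.sort_values("r_squared", ascending=False)["parameter"].tolist()
        if not chosen:
            multiple[cov] = {"selected": [], "note": "no parameter passed selection"}
            continue
        k = series[0].k
        x_bins = series[0].x
        by_name = {s.parameter_name: s.y for s in series}
        # build predictors greedily in r² order: keep enough residual df
        # for a meaningful F-test and skip columns that are exactly
        # collinear with those already included (e.g. fat + lean area sum
        # to a constant section area)
        max_pred = max(1, k - 1 - config.min_residual_df)
        kept, skipped = [], []
        ones = np.ones((k, 1))
        for name in chosen:
            if len(kept) >= max_pred:
                break
            cols = np.column_stack([ones] + [by_name[p] for p in kept + [name]])
            if np.linalg.matrix_rank(cols) == cols.shape[1]:
                kept.append(name)
            else:
                skipped.append(name)
        chosen = kept
        X = pd.DataFrame({name: by_name[name] for name in chosen})[chosen]
        try:
            mr = multiple_fit(x_bins, X, covariate_name=cov)
            multiple[cov] = {
                "selected": mr.parameter_names,
                "collinear_skipped": skipped,
                "coefficients": [float(c) for c in mr.coefficients],
                "multiple_r": mr.multiple_r,
                "f_statistic": mr.f_statistic,
                "p_value": mr.p_value,
                "df": list(mr.df),
                "anova": mr.anova,
            }
        except ValueError as exc:
            multiple[cov] = {"selected": chosen, "error": str(exc)}

    regressions = pd.DataFrame(
        [
            {
                "covariate": r.covariate_name,
                "parameter": r.parameter_name,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
            }
            for r in reg_results
        ]
    )
    return PipelineResult(
        parameters=params,
        assignments=pd.DataFrame(assign_rows),
        bin_summary=pd.DataFrame(summary_rows),
        regressions=regressions,
        selection=selection,
        multiple=multiple,
        failures=failures,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline entry point: read inputs, analyze, write outputs."""
    config.validate()
    if config.pixel_dir is None or config.covariate_table is None:
        raise PipelineError("pixel_dir and covariate_table are required")
    pixel_dir = Path(config.pixel_dir)
    if not pixel_dir.is_dir():
        raise PipelineError(f"pixel directory {pixel_dir} not found")
    covariates = pd.read_csv(config.covariate_table)
    if "subject_id" not in covariates.columns:
        raise PipelineError("covariate table must have a subject_id column")

    pixel_sets, unreadable = [], []
    for sid in covariates["subject_id"].astype(str):
        path = pixel_dir / f"{sid}.csv"
        if not path.is_file():
            unreadable.append(sid)
            logger.warning("missing pixel file for subject %s", sid)
            continue
        try:
            pixel_sets.append(read_pixel_csv(path, subject_id=sid))
        except Exception as exc:
            unreadable.append(sid)
            logger.warning("unreadable pixel file for %s: %s", sid, exc)
    if not pixel_sets:
        raise PipelineError("no readable subject pixel files")
    if len(unreadable) > config.max_failure_fraction * len(covariates):
        raise PipelineError(
            f"{len(unreadable)} of {len(covariates)} subject files unreadable"
        )

    result = analyze_cohort(pixel_sets, covariates, config)
    result.failures = unreadable + result.failures

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "parameters.csv": result.parameters,
        "assignments.csv": result.assignments,
        "bin_summary.csv": result.bin_summary,
        "regressions.csv": result.regressions,
        "selection.csv": result.selection,
    }
    files = {}
    for name, frame in tables.items():
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        files[name] = _sha256(path)
    mr_path = outdir / "multiple_regression.json"
    mr_path.write_text(json.dumps(result.multiple, indent=2, sort_keys=True))
    files["multiple_regression.json"] = _sha256(mr_path)

    per_cov_n = (
        result.assignments.groupby("covariate")["subject_id"].nunique().to_dict()
    )
    manifest = {
        "tool": "ntra",
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "n_subjects_fit": int(len(result.parameters)),
        "n_failures": len(result.failures),
        "failed_subjects": result.failures,
        "per_covariate_n": {k: int(v) for k, v in per_cov_n.items()},
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.manifest = manifest
    return result
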