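"""Unsupervised discretization of clinical covariates.

Continuous covariates (gait speeds, timed up-and-go, leg strength,
cholesterol, BMI) are split into k classes by exact one-dimensional
k-means; k comes from Sturges' rule, k = ceil(log2(n) + 1).  Age, being
truncated, is stratified by equal-frequency binning instead.

In one dimension the k-means optimum is always a partition of the sorted
values into contiguous runs, so it can be found exactly by dynamic
programming over the sorted order — no seeding, no local optima.  A
k-medoids (L1) objective is available as an option; both objectives share
the same DP because L1-optimal 1-D clusters are contiguous too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class BinAssignment:
    """Result of discretizing one covariate into k ordered bins.

    ``labels`` holds the 1-based bin index of every input observation, in
    input order.  Bins are numbered ascending by representative value
    (the bin mean), so bin 1 is the lowest covariate class.
    """

    labels: np.ndarray
    k: int
    bin_sizes: np.ndarray
    representatives: np.ndarray
    method: str
    sse: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.bin_sizes = np.asarray(self.bin_sizes, dtype=int)
        self.representatives = np.asarray(self.representatives, dtype=float)
        if self.bin_sizes.sum() != self.labels.size:
            raise ValueError("bin sizes must sum to the number of observations")

    @property
    def n(self) -> int:
        return self.labels.size


def sturges(n: int) -> tuple[float, int]:
    """Sturges' rule for the number of classes.

    Returns both the raw value ``log2(n) + 1`` (conventionally reported to
    one decimal) and its ceiling, the usable integer class count.
    """
    if n < 1:
        raise ValueError("population must be >= 1")
    raw = math.log2(n) + 1.0
    return raw, math.ceil(raw)


def _assemble(values: np.ndarray, order: np.ndarray, boundaries: list[int],
              method: str, sse: float) -> BinAssignment:
    """Turn contiguous segments of the sorted order into a BinAssignment."""
    k = len(boundaries) - 1
    labels = np.empty(values.size, dtype=int)
    sizes = np.empty(k, dtype=int)
    reps = np.empty(k, dtype=float)
    xs = values[order]
    for b in range(k):
        seg = order[boundaries[b]:boundaries[b + 1]]
        labels[seg] = b + 1
        sizes[b] = seg.size
        reps[b] = xs[boundaries[b]:boundaries[b + 1]].mean()
    return BinAssignment(labels=labels, k=k, bin_sizes=sizes,
                         representatives=reps, method=method, sse=sse)


def kmeans_1d(
    values, k: int, seed: int = 0, objective: str = "means"
) -> BinAssignment:
    """Exact 1-D k-means (or k-medoids) clustering.

    Solved by dynamic programming over the sorted values, so the
    within-cluster sum of squares (or of absolute deviations for
    ``objective="medoids"``) is the global optimum and the result is
    deterministic for a fixed input regardless of ``seed`` (the argument
    is accepted for interface compatibility with seeded refiners).
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct values ({n_distinct})"
        )
    if objective not in ("means", "medoids"):
        raise ValueError(f"unknown objective {objective!r}")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(starts: np.ndarray, end: int) -> np.ndarray:
        # cost of sorted segments [start, end] inclusive, vectorised in start
        if objective == "means":
            m = end - starts + 1
            t1 = s1[end + 1] - s1[starts]
            t2 = s2[end + 1] - s2[starts]
            return t2 - t1**2 / m
        med = (starts + end) // 2
        right = (s1[end + 1] - s1[med]) - (end - med + 1) * xs[med]
        left = (med - starts + 1) * xs[med] - (s1[med + 1] - s1[starts])
        return right + left

    # D[i] = optimal cost of sorted values 0..i in the current cluster count
    idx = np.arange(n)
    zero = np.array([0])
    D = np.array([seg_cost(zero, i)[0] for i in range(n)])
    back = np.zeros((k, n), dtype=int)
    for q in range(2, k + 1):
        D_new = np.full(n, np.inf)
        for i in range(q - 1, n):
            starts = idx[q - 1: i + 1]  # first index of the last cluster
            cand = D[starts - 1] + seg_cost(starts, i)
            j = int(np.argmin(cand))
            D_new[i] = cand[j]
            back[q - 1, i] = starts[j]
        D = D_new

    boundaries = [n]
    end = n - 1
    for q in range(k, 1, -1):
        start = int(back[q - 1, end])
        boundaries.append(start)
        end = start - 1
    boundaries.append(0)
    boundaries.reverse()
    return _assemble(x, order, boundaries, f"kmeans_1d[{objective}]",
                     float(D[n - 1]))


def equal_frequency_bins(values, k: int) -> BinAssignment:
    """Split sorted observations into k contiguous bins of near-equal size.

    Bin sizes differ by at most one; when n is not divisible by k the
    larger bins come first.  Ties are broken by stable sort order.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")

    base, rem = divmod(n, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    boundaries = [0]
    for s in sizes:
        boundaries.append(boundaries[-1] + s)
    order = np.argsort(x, kind="stable")
    return _assemble(x, order, boundaries, "equal_frequency", float("nan"))
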