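"""Bootstrap and Monte-Carlo machinery for matrix error and repeatability.

An estimated covariance matrix is never the population matrix; comparisons
of two estimates are therefore biased below 1 even when the populations
are identical.  Matrix repeatability — the expected self-similarity of an
estimate under resampling — quantifies this, and observed between-matrix
correlations are corrected by the geometric mean of the two
repeatabilities.  Repeatability can be computed by bootstrap over
individuals, parametric Monte-Carlo from the estimated matrix, or (for
correlation matrices) Cheverud's analytic expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .comparison import COMPARISON_METHODS, compare_matrices, corrected_correlation
from .core import (
    IndividualTable,
    TraitMatrix,
    ValidationError,
    as_generator,
    eigen,
    to_correlation,
)
from .estimation import calculate_matrix

__all__ = [
    "RepeatabilityEstimate",
    "bootstrap_stat",
    "monte_carlo_stat",
    "bootstrap_rep",
    "monte_carlo_rep",
    "alpha_rep",
    "corrected_correlation",
    "rarefaction",
    "extend_matrix",
    "suggest_extension_rank",
]


@dataclass
class RepeatabilityEstimate:
    value: float
    method: str  # alpha | bootstrap | montecarlo
    iterations: int | None = None
    comparison_method: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.value = float(np.clip(self.value, 0.0, 1.0))


def bootstrap_stat(data: IndividualTable, statistic: Callable,
                   iterations: int = 1000, rng=0) -> list:
    """Bootstrap distribution of a statistic of an IndividualTable.

    Individuals' rows are resampled with replacement; a statistic failure
    triggers a redraw, at most 10 times per iteration.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    g = as_generator(rng)
    out = []
    for _ in range(iterations):
        for attempt in range(10):
            rows = g.integers(0, data.n, size=data.n)
            try:
                out.append(statistic(data.subset(rows)))
                break
            except Exception:
                if attempt == 9:
                    raise
    return out


def monte_carlo_stat(m: TraitMatrix, sample_size: int, statistic: Callable,
                     iterations: int = 1000, rng=0) -> list:
    """Distribution of a statistic over MVN(0, m) datasets of a fixed size."""
    if not m.is_pd():
        raise ValidationError("Monte-Carlo sampling requires a positive-definite matrix")
    if sample_size < m.p + 1:
        raise ValidationError("sample_size must exceed the trait count")
    g = as_generator(rng)
    chol = np.linalg.cholesky(m.values)
    out = []
    for _ in range(iterations):
        x = g.standard_normal((sample_size, m.p)) @ chol.T
        out.append(statistic(x))
    return out


def _sample_cov(x: np.ndarray, labels) -> TraitMatrix:
    c = np.cov(x, rowvar=False)
    return TraitMatrix(c, labels, "covariance")


def bootstrap_rep(data: IndividualTable, comparison_method: str = "random_skewers",
                  iterations: int = 1000, rng=0,
                  correlation: bool = False) -> RepeatabilityEstimate:
    """Bootstrap matrix repeatability.

    Mean comparison between each bootstrap-resample covariance (or
    correlation) matrix and the full-data matrix.  Inflated for small
    samples — a high value from few individuals does not mean the matrix
    is well estimated.
    """
    if comparison_method not in COMPARISON_METHODS:
        raise ValidationError(f"unknown comparison method {comparison_method!r}")
    g = as_generator(rng)
    full = calculate_matrix(data)
    if correlation or comparison_method == "mantel":
        full = to_correlation(full)

    def stat(d: IndividualTable) -> float:
        m = calculate_matrix(d)
        if correlation or comparison_method == "mantel":
            m = to_correlation(m)
        return compare_matrices(m, full, comparison_method, rng=g).value

    values = bootstrap_stat(data, stat, iterations=iterations, rng=g)
    return RepeatabilityEstimate(
        value=float(np.mean(values)), method="bootstrap",
        iterations=iterations, comparison_method=comparison_method,
        extra={"sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0},
    )


def monte_carlo_rep(m: TraitMatrix, sample_size: int,
                    comparison_method: str = "random_skewers",
                    iterations: int = 1000, correlation: bool = False,
                    rng=0) -> RepeatabilityEstimate:
    """Parametric Monte-Carlo matrix repeatability.

    Datasets of ``sample_size`` MVN(0, m) draws are generated; the matrix
    re-estimated from each is compared with m itself; the mean comparison
    is the repeatability.  Needs no raw data, only the estimated matrix.
    """
    if comparison_method not in COMPARISON_METHODS:
        raise ValidationError(f"unknown comparison method {comparison_method!r}")
    g = as_generator(rng)
    target = to_correlation(m) if (correlation or comparison_method == "mantel") else m

    def stat(x: np.ndarray) -> float:
        est = _sample_cov(x, m.labels)
        if correlation or comparison_method == "mantel":
            est = to_correlation(est)
        return compare_matrices(est, target, comparison_method, rng=g).value

    values = monte_carlo_stat(m, sample_size, stat, iterations=iterations, rng=g)
    return RepeatabilityEstimate(
        value=float(np.mean(values)), method="montecarlo",
        iterations=iterations, comparison_method=comparison_method,
        extra={"sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
               "sample_size": sample_size},
    )


def alpha_rep(corr: TraitMatrix, n: int) -> RepeatabilityEstimate:
    """Cheverud's analytic repeatability of a correlation matrix.

    α = (σ²_r − ε²)/σ²_r over the p(p−1)/2 below-diagonal elements, with
    sampling-error variance ε² = (1 − r̄²)²/(n − 2).  Asymptotic: use only
    when the sample size exceeds the trait count.
    """
    if corr.role != "correlation":
        raise ValidationError("alpha repeatability is defined for correlation matrices")
    if n <= 2:
        raise ValidationError("need sample size > 2")
    low = corr.values[np.tril_indices(corr.p, k=-1)]
    var_r = float(np.var(low, ddof=1))
    mean_r = float(np.mean(low))
    eps2 = (1.0 - mean_r**2) ** 2 / (n - 2)
    value = 0.0 if var_r == 0 else (var_r - eps2) / var_r
    extra = {"var_r": var_r, "eps2": eps2}
    if n <= corr.p:
        extra["note"] = "sample size <= trait count: asymptotic formula unreliable"
    return RepeatabilityEstimate(value=value, method="alpha", extra=extra)


def rarefaction(data: IndividualTable, comparison_method: str = "random_skewers",
                sizes: list[int] | None = None, iterations: int = 100,
                rng=0, correlation: bool = False) -> dict[int, np.ndarray]:
    """Comparison of subsampled matrix estimates with the full-data estimate.

    For each size, ``iterations`` subsamples of that many individuals are
    drawn with replacement; the matrix estimated from each is compared with
    the full-data matrix.  Shows how inference would degrade at smaller n.
    """
    g = as_generator(rng)
    sizes = sizes if sizes is not None else list(range(data.p + 2, data.n + 1,
                                                       max(1, (data.n - data.p) // 8)))
    full = calculate_matrix(data)
    if correlation or comparison_method == "mantel":
        full = to_correlation(full)
    out: dict[int, np.ndarray] = {}
    for size in sizes:
        if size < 2 or size > data.n:
            raise ValidationError(f"rarefaction size {size} outside [2, n]")
        vals = []
        for _ in range(iterations):
            rows = g.integers(0, data.n, size=size)
            est = calculate_matrix(data.subset(rows))
            if correlation or comparison_method == "mantel":
                est = to_correlation(est)
            vals.append(compare_matrices(est, full, comparison_method, rng=g).value)
        out[size] = np.asarray(vals)
    return out


def extend_matrix(m: TraitMatrix, retained_rank: int) -> TraitMatrix:
    """Raise the trailing eigenvalues to the last retained one.

    Eigenvalues after position k* are replaced by λ_{k*}; eigenvectors are
    unchanged.  Noise-dominated small eigenvalues wreak havoc on inverse-
    based quantities (net selection gradients); extension leaves the
    phenotype distribution nearly unchanged while stabilizing the inverse.
    """
    if m.role != "covariance":
        raise ValidationError("extension applies to covariance matrices")
    if not (1 <= retained_rank <= m.p):
        raise ValidationError(f"retained rank must be in [1, {m.p}]")
    lam, vec = eigen(m)
    lam = lam.copy()
    lam[retained_rank:] = lam[retained_rank - 1]
    return m.with_values((vec * lam) @ vec.T)


def suggest_extension_rank(m: TraitMatrix, rel_drop: float = 1e-4) -> int:
    """Heuristic retained rank: smallest k with (λ_k − λ_{k+1})/λ₁ < rel_drop.

    A documented convenience only; the explicit rank argument of
    :func:`extend_matrix` is canonical.
    """
    lam, _ = eigen(m)
    drops = (lam[:-1] - lam[1:]) / lam[0]
    below = np.nonzero(drops < rel_drop)[0]
    return int(below[0] + 1) if below.size else m.p
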