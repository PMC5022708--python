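"""Pairwise matrix comparison: correlations and distances.

Matrix correlations measure structural similarity of two trait covariance
or correlation matrices:

* Random Skewers — mean cosine between the responses ``Aβ`` and ``Bβ`` of
  the Lande equation to shared random unit selection gradients.
* Mantel — element-wise Pearson correlation of the below-diagonal entries
  with a row/column permutation test (correlation matrices only: covariance
  scale differences inflate the correlation).
* Krzanowski — shared subspace of the leading principal components.
* PCA similarity — the Krzanowski sum extended to all components and
  weighted by eigenvalues, normalized so self-similarity is 1.

Matrix distances are nonnegative with 0 meaning identity:

* overlap — the misclassification probability between the two zero-mean
  Gaussian densities, mapped to a metric d = √(1 − 2q);
* riemann — the affine-invariant Riemannian metric √Σ log²λᵢ(A⁻¹B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    TraitMatrix,
    ValidationError,
    as_generator,
    check_same_shape,
    eigen,
    random_unit_vectors,
)

__all__ = [
    "ComparisonResult",
    "random_skewers",
    "mantel_cor",
    "krz_cor",
    "pca_similarity",
    "matrix_distance",
    "overlap_q",
    "compare_all",
    "COMPARISON_METHODS",
]


@dataclass
class ComparisonResult:
    method: str
    value: float
    p_value: float | None = None
    null_quantile_95: float | None = None
    significant: bool | None = None
    n_vectors: int | None = None
    permutations: int | None = None
    corrected_value: float | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def _lower(v: np.ndarray) -> np.ndarray:
    return v[np.tril_indices_from(v, k=-1)]


def random_skewers(a: TraitMatrix, b: TraitMatrix, n_vectors: int = 1000,
                   rng=0, betas: np.ndarray | None = None) -> ComparisonResult:
    """Random Skewers correlation: mean cos(Aβ, Bβ) over random unit β.

    Significance uses the empirical null of cosines between independent
    random unit-vector pairs in the same dimension: the comparison is
    significant when the observed mean exceeds the null's 95th percentile.
    A fixed β set may be supplied to share skewers across comparisons.
    """
    check_same_shape(a, b)
    g = as_generator(rng)
    if betas is None:
        betas = random_unit_vectors(a.p, n_vectors, g)
    else:
        n_vectors = betas.shape[0]
    ra = betas @ a.values
    rb = betas @ b.values
    num = np.einsum("ij,ij->i", ra, rb)
    den = np.linalg.norm(ra, axis=1) * np.linalg.norm(rb, axis=1)
    cosines = num / den
    value = float(cosines.mean())

    n_null = 10_000
    u = random_unit_vectors(a.p, n_null, g)
    v = random_unit_vectors(a.p, n_null, g)
    null = np.einsum("ij,ij->i", u, v)
    q95 = float(np.quantile(null, 0.95))
    p = float(np.mean(null >= value))
    return ComparisonResult(
        method="random_skewers", value=value, p_value=p,
        null_quantile_95=q95, significant=value > q95, n_vectors=n_vectors,
    )


def mantel_cor(a: TraitMatrix, b: TraitMatrix, permutations: int = 1000,
               rng=0) -> ComparisonResult:
    """Mantel correlation of below-diagonal elements with a permutation test.

    One random relabeling is applied jointly to rows and columns of ``b``
    per permutation; p = (1 + #{permuted ≥ observed})/(permutations + 1).
    Only defined for correlation matrices.
    """
    if a.role != "correlation" or b.role != "correlation":
        raise ValidationError(
            "Mantel comparison requires correlation matrices: covariance "
            "scale differences inflate the element-wise correlation"
        )
    check_same_shape(a, b)
    g = as_generator(rng)
    xa = _lower(a.values)
    xb_obs = _lower(b.values)
    if np.std(xa) == 0 or np.std(xb_obs) == 0:
        raise ValidationError(
            "constant below-diagonal elements: the Mantel correlation is "
            "undefined (no structure to compare)"
        )
    observed = float(stats.pearsonr(xa, xb_obs).statistic)
    count = 0
    for _ in range(permutations):
        perm = g.permutation(b.p)
        xb = _lower(b.values[np.ix_(perm, perm)])
        if stats.pearsonr(xa, xb).statistic >= observed:
            count += 1
    p = (1 + count) / (permutations + 1)
    return ComparisonResult(
        method="mantel", value=observed, p_value=p, permutations=permutations,
        significant=p < 0.05,
    )


def krz_cor(a: TraitMatrix, b: TraitMatrix, k: int | None = None) -> ComparisonResult:
    """Krzanowski subspace correlation of the leading k principal components.

    value = (1/k) Σᵢ Σⱼ cos²(Λᵢᴬ, Λⱼᴮ) over the first k eigenvectors of
    each matrix; 1 means identical subspaces, 0 orthogonal ones.  Default
    k = max(1, ⌊p/2⌋ − 1).
    """
    check_same_shape(a, b)
    p = a.p
    if k is None:
        k = max(1, p // 2 - 1)
    if not (1 <= k < p):
        raise ValidationError(f"subspace size k={k} must be in [1, p-1]")
    _, va = eigen(a)
    _, vb = eigen(b)
    c = va[:, :k].T @ vb[:, :k]
    return ComparisonResult(method="krz", value=float(np.sum(c**2) / k),
                            extra={"k": k})


def pca_similarity(a: TraitMatrix, b: TraitMatrix) -> ComparisonResult:
    """Eigenvalue-weighted PCA similarity over all principal-component pairs.

    value = Σᵢⱼ λᵢᴬλⱼᴮ cos²(Λᵢᴬ, Λⱼᴮ) / Σᵢ λᵢᴬλᵢᴮ with eigenvalues sorted
    descending in the denominator pairing, so self-similarity is exactly 1.
    """
    check_same_shape(a, b)
    wa, va = eigen(a)
    wb, vb = eigen(b)
    c2 = (va.T @ vb) ** 2
    num = float(wa @ c2 @ wb)
    den = float(np.sum(wa * wb))
    return ComparisonResult(method="pca_similarity", value=num / den)


def _overlap_q_oneway(cov_f: np.ndarray, cov_g: np.ndarray,
                      mean_f: np.ndarray, mean_g: np.ndarray,
                      draws: int, g: np.random.Generator) -> float:
    x = g.multivariate_normal(mean_f, cov_f, size=draws, method="cholesky")
    lf = stats.multivariate_normal(mean_f, cov_f).logpdf(x)
    lg = stats.multivariate_normal(mean_g, cov_g).logpdf(x)
    # g/(f+g) = 1/(1 + exp(lf - lg)), stable in log space
    ratio = 1.0 / (1.0 + np.exp(np.clip(lf - lg, -700.0, 700.0)))
    return float(np.mean(ratio))


def overlap_q(cov_a: np.ndarray, cov_b: np.ndarray, mc_draws: int = 10_000,
              rng=0, mean_a: np.ndarray | None = None,
              mean_b: np.ndarray | None = None) -> float:
    """Symmetrized misclassification probability between two Gaussians.

    q = ½[q(f→g) + q(g→f)] estimated by Monte Carlo; ½ when the
    distributions coincide, → 0 as they separate.  Means default to zero
    (the covariance-matrix-as-phenotype-distribution reading).
    """
    cov_a = np.asarray(cov_a, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    p = cov_a.shape[0]
    mean_a = np.zeros(p) if mean_a is None else np.asarray(mean_a, dtype=float)
    mean_b = np.zeros(p) if mean_b is None else np.asarray(mean_b, dtype=float)
    g = as_generator(rng)
    qfg = _overlap_q_oneway(cov_a, cov_b, mean_a, mean_b, mc_draws, g)
    qgf = _overlap_q_oneway(cov_b, cov_a, mean_b, mean_a, mc_draws, g)
    return (qfg + qgf) / 2.0


def matrix_distance(a: TraitMatrix, b: TraitMatrix, method: str = "riemann",
                    mc_draws: int = 10_000, rng=0) -> ComparisonResult:
    """Distance between two SPD matrices.

    ``overlap``: q = symmetrized Monte-Carlo estimate of the probability of
    misclassifying a draw between the zero-mean Gaussians with covariances
    A and B; d = √(1 − 2q); q = 1/2 for indistinguishable distributions.
    ``riemann``: d = √Σ log²λᵢ with λᵢ the eigenvalues of A⁻¹B; invariant
    under any change of basis (congruence).
    """
    check_same_shape(a, b)
    if not (a.is_pd() and b.is_pd()):
        raise ValidationError("matrix distance requires positive-definite inputs")
    if method == "riemann":
        lam = np.real(np.linalg.eigvals(np.linalg.solve(a.values, b.values)))
        if np.any(lam <= 0):
            raise ValidationError("A^{-1}B has non-positive eigenvalues")
        d = float(np.sqrt(np.sum(np.log(lam) ** 2)))
        return ComparisonResult(method="riemann", value=d)
    if method == "overlap":
        q = overlap_q(a.values, b.values, mc_draws=mc_draws, rng=rng)
        d = float(np.sqrt(max(1.0 - 2.0 * q, 0.0)))
        return ComparisonResult(method="overlap", value=d,
                                extra={"q": q, "mc_draws": mc_draws})
    raise ValidationError(f"unknown distance method {method!r}")


COMPARISON_METHODS = {
    "random_skewers": random_skewers,
    "mantel": mantel_cor,
    "krz": krz_cor,
    "pca_similarity": pca_similarity,
}


def compare_matrices(a: TraitMatrix, b: TraitMatrix, method: str,
                     rng=0, **kwargs) -> ComparisonResult:
    """Dispatch a pairwise comparison by method name."""
    if method not in COMPARISON_METHODS:
        raise ValidationError(f"unknown comparison method {method!r}")
    fn = COMPARISON_METHODS[method]
    if method in ("krz", "pca_similarity"):
        return fn(a, b, **kwargs)
    return fn(a, b, rng=rng, **kwargs)


def corrected_correlation(raw: float, rep_a: float, rep_b: float) -> float:
    """Matrix correlation corrected by the geometric mean of repeatabilities.

    raw/√(rep_a·rep_b), capped at 1.  With both repeatabilities 1 the
    observed correlation is unchanged.
    """
    if rep_a <= 0 or rep_b <= 0:
        raise ValidationError("repeatabilities must be positive to correct")
    if rep_a > 1 or rep_b > 1:
        raise ValidationError("repeatabilities cannot exceed 1")
    return min(raw / np.sqrt(rep_a * rep_b), 1.0)


def compare_all(matrices: list[TraitMatrix], method: str = "random_skewers",
                repeatabilities: list[float] | None = None, rng=0,
                names: list[str] | None = None, **kwargs) -> "pd.DataFrame":
    """All-pairs comparison table.

    Lower triangle: raw comparison values; upper triangle: repeatability-
    corrected values (when repeatabilities are given); diagonal: the
    repeatabilities themselves (1 when absent).
    """
    import pandas as pd

    k = len(matrices)
    ref = matrices[0]
    for m in matrices[1:]:
        check_same_shape(ref, m)
    reps = repeatabilities if repeatabilities is not None else [1.0] * k
    if len(reps) != k:
        raise ValidationError("need one repeatability per matrix")
    out = np.eye(k)
    np.fill_diagonal(out, reps)
    g = as_generator(rng)
    for i in range(k):
        for j in range(i):
            raw = compare_matrices(matrices[i], matrices[j], method,
                                   rng=g, **kwargs).value
            out[i, j] = raw
            out[j, i] = corrected_correlation(raw, reps[i], reps[j])
    names = names or [f"m{i}" for i in range(k)]
    return pd.DataFrame(out, index=names, columns=names)
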