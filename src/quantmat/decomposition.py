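"""Matrix decomposition: SRD, Riemannian mean, eigentensors, RS projection.

Selection Response Decomposition (SRD) splits the Lande response Aβ into
its per-trait terms A_ijβ_j and asks, trait by trait, whether two matrices
produce the same pattern of direct and correlated response.

Covariance matrices live on the manifold of symmetric positive-definite
matrices, not in a Euclidean space.  The eigentensor machinery therefore
first estimates the Fréchet (geometric) mean M of a sample — the matrix
minimizing the summed squared Riemannian distances — then maps every
member to the tangent space at M via f(X) = log(M^{-1/2} X M^{-1/2}),
where a principal-component analysis of the mapped matrices is legitimate.
The resulting orthonormal symmetric matrices (eigentensors) are the main
axes of variation of the sample; scores project back and forth through
the exponential map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    MatrixSample,
    TraitMatrix,
    ValidationError,
    as_generator,
    matrix_exp,
    matrix_log,
    matrix_sqrt,
    random_unit_vectors,
)

__all__ = [
    "SRDResult",
    "TensorBasis",
    "srd",
    "mean_matrix",
    "eigentensor_decomposition",
    "project_matrix",
    "revert_matrix",
    "rs_projection",
]


# ---------------------------------------------------------------------------
# Selection Response Decomposition
# ---------------------------------------------------------------------------

@dataclass
class SRDResult:
    trait_names: list[str]
    mu: np.ndarray          # per-trait mean correlation of response terms
    sigma: np.ndarray       # per-trait SD of those correlations
    centered_mu: np.ndarray
    flagged: list[str]      # traits with centered mean score below zero
    n_vectors: int
    seed: int | None = None


def srd(a: TraitMatrix, b: TraitMatrix, n_vectors: int = 1000, rng=0,
        betas: np.ndarray | None = None) -> SRDResult:
    """Selection Response Decomposition of two matrices.

    For each random unit β the per-trait response terms rᵢ = (A_ijβ_j)_j
    are correlated between the two matrices; μSRD_i and σSRD_i are the mean
    and SD over β of those correlations.  Traits whose centered mean score
    falls below zero (centering subtracts the across-trait mean) are
    flagged as diverging in their pattern of correlated selection.
    """
    from .core import check_same_shape

    check_same_shape(a, b)
    if a.p < 2:
        raise ValidationError("SRD needs at least 2 traits")
    g = as_generator(rng)
    if betas is None:
        betas = random_unit_vectors(a.p, n_vectors, g)
    else:
        n_vectors = betas.shape[0]
    if n_vectors < 2:
        raise ValidationError("SRD needs at least 2 selection gradients")

    # terms[i, k, j] = A[k, j] * beta[i, j]  (draw i, trait k)
    ta = a.values[None, :, :] * betas[:, None, :]
    tb = b.values[None, :, :] * betas[:, None, :]
    ta_c = ta - ta.mean(axis=2, keepdims=True)
    tb_c = tb - tb.mean(axis=2, keepdims=True)
    num = np.einsum("ikj,ikj->ik", ta_c, tb_c)
    den = np.sqrt(np.einsum("ikj,ikj->ik", ta_c, ta_c)
                  * np.einsum("ikj,ikj->ik", tb_c, tb_c))
    with np.errstate(invalid="ignore", divide="ignore"):
        cors = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    mu = cors.mean(axis=0)
    sigma = cors.std(axis=0, ddof=1)
    centered = mu - mu.mean()
    flagged = [a.labels[i] for i in range(a.p) if centered[i] < 0]
    return SRDResult(trait_names=list(a.labels), mu=mu, sigma=sigma,
                     centered_mu=centered, flagged=flagged, n_vectors=n_vectors,
                     seed=rng if isinstance(rng, int) else None)


# ---------------------------------------------------------------------------
# Riemannian mean and eigentensors
# ---------------------------------------------------------------------------

def mean_matrix(sample: MatrixSample, tol: float = 1e-10,
                max_iter: int = 100) -> TraitMatrix:
    """Fréchet (geometric) mean of SPD matrices by fixed-point iteration.

    M ← M^{1/2} exp(mean log(M^{-1/2} X_i M^{-1/2})) M^{1/2}, initialized
    at the arithmetic mean; converged when the Frobenius norm of the mean
    log term falls below ``tol``.  At the mean the tangent-space residual
    Σ log(M^{-1/2} X_i M^{-1/2}) vanishes.
    """
    mats = sample.as_array()
    for x in mats:
        if np.linalg.eigvalsh(x).min() <= 0:
            raise ValidationError("geometric mean requires positive-definite members")
    m = mats.mean(axis=0)
    for _ in range(max_iter):
        s = matrix_sqrt(m)
        s_inv = np.linalg.inv(s)
        logs = np.stack([matrix_log(s_inv @ x @ s_inv) for x in mats])
        step = logs.mean(axis=0)
        resid = np.linalg.norm(step, "fro")
        if resid <= tol:
            return TraitMatrix(m, sample.labels, sample.matrices[0].role)
        m = s @ matrix_exp(step) @ s
        m = (m + m.T) / 2
    raise ValidationError(
        f"geometric mean did not converge in {max_iter} iterations "
        f"(residual {resid:.3g})"
    )


def _sym_to_vec(x: np.ndarray) -> np.ndarray:
    """Vectorize a symmetric matrix preserving the Frobenius inner product.

    Diagonal entries as-is, off-diagonals scaled by √2, so the Euclidean
    dot product of two vectorized matrices equals ⟨A, B⟩_F.
    """
    p = x.shape[0]
    iu = np.triu_indices(p, k=1)
    return np.concatenate([np.diag(x), np.sqrt(2.0) * x[iu]])


def _vec_to_sym(v: np.ndarray, p: int) -> np.ndarray:
    out = np.diag(v[:p]).astype(float)
    iu = np.triu_indices(p, k=1)
    out[iu] = v[p:] / np.sqrt(2.0)
    out = out + np.triu(out, k=1).T
    return out


@dataclass
class TensorBasis:
    mean: TraitMatrix
    eigentensors: list[np.ndarray]       # orthonormal symmetric p×p matrices
    eigenvalues: np.ndarray              # descending
    scores: np.ndarray                   # sample × eigentensor
    labels: list[str] = field(default_factory=list)


def eigentensor_decomposition(sample: MatrixSample, tol: float = 1e-10,
                              max_iter: int = 100) -> TensorBasis:
    """Eigentensors of a sample of covariance matrices.

    Members are mapped to the tangent space at the Fréchet mean, vectorized
    preserving the Frobenius product, and the covariance of the vectorized
    maps across the sample eigendecomposed; eigenvectors un-vectorize into
    orthonormal symmetric eigentensors, and each member's scores are its
    Frobenius inner products with them.
    """
    if len(sample) < 2:
        raise ValidationError("eigentensor decomposition needs at least 2 matrices")
    m = mean_matrix(sample, tol=tol, max_iter=max_iter)
    s_inv = np.linalg.inv(matrix_sqrt(m.values))
    mapped = np.stack([_sym_to_vec(matrix_log(s_inv @ x.values @ s_inv))
                       for x in sample])
    cov = np.cov(mapped, rowvar=False)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # fix eigenvector sign as elsewhere: largest-magnitude entry positive
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    p = sample.p
    tensors = [_vec_to_sym(v[:, i], p) for i in range(v.shape[1])]
    scores = mapped @ v
    return TensorBasis(mean=m, eigentensors=tensors, eigenvalues=w,
                       scores=scores, labels=list(sample.labels))


def project_matrix(x: TraitMatrix, basis: TensorBasis) -> np.ndarray:
    """Scores of a matrix on an eigentensor basis (tangent space at its mean)."""
    if x.p != basis.mean.p:
        raise ValidationError("matrix dimension does not match the basis")
    s_inv = np.linalg.inv(matrix_sqrt(basis.mean.values))
    mapped = _sym_to_vec(matrix_log(s_inv @ x.values @ s_inv))
    v = np.column_stack([_sym_to_vec(t) for t in basis.eigentensors])
    return mapped @ v


def revert_matrix(scores: np.ndarray, basis: TensorBasis) -> TraitMatrix:
    """Reconstruct the SPD matrix with the given eigentensor scores.

    X = M^{1/2} exp(Σ sᵢ ETᵢ) M^{1/2}; the exponential map guarantees an
    SPD result for any finite scores.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if len(scores) > len(basis.eigentensors):
        raise ValidationError("more scores than eigentensors")
    tangent = sum(s * t for s, t in zip(scores, basis.eigentensors))
    if not isinstance(tangent, np.ndarray):
        tangent = np.zeros_like(basis.mean.values)
    s = matrix_sqrt(basis.mean.values)
    out = s @ matrix_exp(tangent) @ s
    return TraitMatrix((out + out.T) / 2, basis.mean.labels, basis.mean.role)


# ---------------------------------------------------------------------------
# Random-skewer projection over posterior samples
# ---------------------------------------------------------------------------

@dataclass
class RSProjectionResult:
    directions: np.ndarray           # n_vectors × p unit vectors
    intervals: np.ndarray            # population × direction × (lo, hi)
    flagged: list[tuple[int, int, int]]  # (direction, pop_i, pop_j)
    credible_level: float
    n_vectors: int


def rs_projection(samples: list[MatrixSample], n_vectors: int = 1000,
                  credible_level: float = 0.95, rng=0) -> RSProjectionResult:
    """Directions whose variance credibly differs between populations.

    For each random unit β, the posterior distribution of the variance
    β·Gβ is summarized per population by an equal-tailed credible interval;
    a direction is flagged for a population pair when their intervals do
    not overlap.
    """
    if len(samples) < 2:
        raise ValidationError("need at least 2 populations")
    p = samples[0].p
    for s in samples:
        if len(s) < 2:
            raise ValidationError("each population needs at least 2 posterior draws")
        if s.p != p:
            raise ValidationError("populations differ in dimension")
    g = as_generator(rng)
    betas = random_unit_vectors(p, n_vectors, g)
    lo_q = (1 - credible_level) / 2
    hi_q = 1 - lo_q
    n_pop = len(samples)
    intervals = np.empty((n_pop, n_vectors, 2))
    for k, s in enumerate(samples):
        arr = s.as_array()  # draws × p × p
        var = np.einsum("ij,djk,ik->di", betas, arr, betas)  # draws × n_vectors
        intervals[k, :, 0] = np.quantile(var, lo_q, axis=0)
        intervals[k, :, 1] = np.quantile(var, hi_q, axis=0)
    flagged = []
    for d in range(n_vectors):
        for i in range(n_pop):
            for j in range(i + 1, n_pop):
                lo_i, hi_i = intervals[i, d]
                lo_j, hi_j = intervals[j, d]
                if hi_i < lo_j or hi_j < lo_i:
                    flagged.append((d, i, j))
    return RSProjectionResult(directions=betas, intervals=intervals,
                              flagged=flagged, credible_level=credible_level,
                              n_vectors=n_vectors)
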