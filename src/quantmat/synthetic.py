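"""Synthetic data: random matrices, modular matrices, populations, radiations.

Every other module is testable from these generators alone — no external
datasets.  All generators are pure functions of their parameters and seed.
Random correlation matrices sample a requested range of integration
(measured by the coefficient of variation of eigenvalues), which common
naive sampling schemes fail to reach; they are intended for informal
tests, not as a calibrated null distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    IndividualTable,
    TraitMatrix,
    ValidationError,
    as_generator,
    eigen,
    to_correlation,
)

__all__ = [
    "random_matrix",
    "random_spd",
    "modular_matrix",
    "simulate_population",
    "simulate_radiation",
]


def random_spd(p: int, rng, eigenvalues: np.ndarray | None = None,
               labels: list[str] | None = None) -> TraitMatrix:
    """Random SPD covariance matrix: random orthogonal basis, given spectrum.

    Default spectrum is log-uniform on [0.1, 10] — well conditioned but
    anisotropic.
    """
    g = as_generator(rng)
    if eigenvalues is None:
        eigenvalues = np.exp(g.uniform(np.log(0.1), np.log(10.0), size=p))
    q = stats.ortho_group.rvs(p, random_state=g)
    v = (q * np.sort(eigenvalues)[::-1]) @ q.T
    labels = labels or [f"t{i+1}" for i in range(p)]
    return TraitMatrix((v + v.T) / 2, labels, "covariance")


def _icv_of(values: np.ndarray) -> float:
    lam = np.linalg.eigvalsh(values)
    return float(np.std(lam, ddof=1) / np.mean(lam))


def _corr_from_decay(p: int, c: float, q: np.ndarray) -> np.ndarray:
    """Correlation matrix with spectrum ∝ exp(−c·i/(p−1)) in basis q."""
    lam = np.exp(-c * np.arange(p) / (p - 1))
    cov = (q * lam) @ q.T
    d = 1.0 / np.sqrt(np.diag(cov))
    r = cov * np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2


def random_matrix(p: int, integration_range: tuple[float, float] = (0.2, 2.0),
                  rng=0, max_attempts: int = 100) -> TraitMatrix:
    """Random correlation matrix with integration in a requested range.

    Integration is the coefficient of variation of eigenvalues of the
    resulting correlation matrix.  Construction: a random orthogonal basis
    with an exponentially decaying spectrum; the decay rate is found by
    bisection (integration is monotone in it).  Raises after
    ``max_attempts`` bases if the range cannot be attained.
    """
    if p < 2:
        raise ValidationError("need at least 2 traits")
    lo, hi = integration_range
    if not (0 <= lo < hi):
        raise ValidationError("invalid integration range")
    g = as_generator(rng)
    target = (lo + hi) / 2
    labels = [f"t{i+1}" for i in range(p)]
    for _ in range(max_attempts):
        q = stats.ortho_group.rvs(p, random_state=g)
        c_lo, c_hi = 0.0, 60.0
        if _icv_of(_corr_from_decay(p, c_hi, q)) < lo:
            continue  # basis cannot reach the requested integration
        for _ in range(80):
            c = (c_lo + c_hi) / 2
            if _icv_of(_corr_from_decay(p, c, q)) < target:
                c_lo = c
            else:
                c_hi = c
        r = _corr_from_decay(p, (c_lo + c_hi) / 2, q)
        if lo <= _icv_of(r) <= hi:
            return TraitMatrix(np.clip(r, -1, 1), labels, "correlation")
    raise ValidationError(
        f"could not attain integration in {integration_range} after "
        f"{max_attempts} attempts")


def modular_matrix(p: int, modules: list[list[int]], r_within: float,
                   r_between: float, labels: list[str] | None = None) -> TraitMatrix:
    """Block-structured correlation matrix: r_within inside modules, r_between outside.

    Negative between-module correlations are allowed (size-removed residual
    matrices look like this) but not every combination is completable to a
    PSD correlation matrix — violations raise with the limiting eigenvalue.
    """
    if not (-1 < r_between < r_within < 1):
        raise ValidationError("need -1 < r_between < r_within < 1")
    assigned = sorted(i for mod in modules for i in mod)
    if assigned != list(range(p)):
        raise ValidationError("modules must partition range(p)")
    r = np.full((p, p), r_between)
    for mod in modules:
        for i in mod:
            for j in mod:
                r[i, j] = r_within
    np.fill_diagonal(r, 1.0)
    lam_min = np.linalg.eigvalsh(r).min()
    if lam_min < -1e-10:
        raise ValidationError(
            f"requested block structure is not PSD (min eigenvalue {lam_min:.3g})")
    labels = labels or [f"t{i+1}" for i in range(p)]
    return TraitMatrix(r, labels, "correlation")


def simulate_population(m: TraitMatrix, n: int, mean: np.ndarray | None = None,
                        rng=0, replicates: int = 1,
                        error_sd: float = 0.0) -> IndividualTable:
    """n individuals drawn from MVN(mean, m), optionally with noisy replicates.

    With ``replicates`` > 1 each individual's true value is measured that
    many times with i.i.d. N(0, error_sd²) measurement error per trait —
    error_sd = 0 gives perfectly repeatable measurements.
    """
    if not m.is_pd():
        raise ValidationError("population simulation requires an SPD matrix")
    g = as_generator(rng)
    mean = np.zeros(m.p) if mean is None else np.asarray(mean, dtype=float)
    truth = g.multivariate_normal(mean, m.values, size=n, method="cholesky")
    frames = []
    for rep in range(replicates):
        obs = truth if (replicates == 1 and error_sd == 0) else (
            truth + g.normal(0.0, error_sd, size=truth.shape) if error_sd > 0
            else truth.copy())
        df = pd.DataFrame(obs, columns=m.labels)
        df.insert(0, "individual", [f"ind{i+1}" for i in range(n)])
        if replicates > 1:
            df.insert(1, "replicate", rep + 1)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return IndividualTable(data)


def simulate_radiation(w: TraitMatrix, n_taxa: int, t_over_ne: float,
                       selection_vector: np.ndarray | None = None,
                       selection_scale: float = 0.0, rng=0) -> pd.DataFrame:
    """Taxon means diverging by drift: means ~ MVN(0, (t/Nₑ)·W).

    An optional deterministic displacement along ``selection_vector``
    (scaled per taxon by selection_scale × taxon index/n_taxa) models
    correlated directional selection on top of drift.
    """
    if t_over_ne < 0:
        raise ValidationError("t_over_ne must be nonnegative")
    g = as_generator(rng)
    if t_over_ne == 0:
        means = np.zeros((n_taxa, w.p))
    else:
        means = g.multivariate_normal(np.zeros(w.p), t_over_ne * w.values,
                                      size=n_taxa, method="cholesky")
    if selection_vector is not None and selection_scale != 0.0:
        v = np.asarray(selection_vector, dtype=float).ravel()
        v = v / np.linalg.norm(v)
        shifts = selection_scale * (np.arange(1, n_taxa + 1) / n_taxa)
        means = means + shifts[:, None] * v[None, :]
    return pd.DataFrame(means, columns=w.labels,
                        index=[f"taxon{i+1}" for i in range(n_taxa)])
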