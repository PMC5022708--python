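"""Tests of neutral (drift) divergence among taxa.

Under pure drift, the between-taxon covariance of trait means is
proportional to the ancestral (pooled within-group) covariance matrix:
B ∝ (t/Nₑ)W.  Three tests with drift as the null hypothesis:

* regression test — projecting taxon means on the eigenvectors of W, the
  between-group variance of the i-th score B_i satisfies
  log B_i = log(t/Nₑ) + β log λᵢᵂ with slope β = 1 under drift;
* multivariate norm test — with one ancestral and one derived population,
  the observed divergence norm is compared with norms simulated from the
  drift null MVN(z₀, (t/Nₑ)W + diag(se²));
* PC-score correlation — under drift the mean scores of taxa on different
  PCs of W are uncorrelated; significant correlations suggest correlated
  directional selection.

Failure to reject drift is not evidence against selection — only that the
observed pattern is compatible with drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import TraitMatrix, ValidationError, as_generator, eigen

__all__ = [
    "DriftRegressionResult",
    "MultivDriftResult",
    "drift_test",
    "multiv_drift_test",
    "pc_score_correlation",
]

ADVISORY = ("drift tests are most reliable with at least 20 traits and "
            "at least 8 taxa")


@dataclass
class DriftRegressionResult:
    slope: float
    intercept: float
    ci_lower: float
    ci_upper: float
    log_eigenvalues: np.ndarray   # log λᵢᵂ for retained PCs
    log_between_var: np.ndarray   # log B_i
    retained: int
    drift_rejected: bool
    verdict: str = ""


@dataclass
class MultivDriftResult:
    observed_norm: float
    null_norms: np.ndarray
    p_value: float
    n_sim: int
    t_over_ne: float
    verdict: str = ""


def _means_array(means: pd.DataFrame, w: TraitMatrix) -> np.ndarray:
    if list(means.columns) != w.labels:
        if sorted(means.columns) == sorted(w.labels):
            means = means[w.labels]
        else:
            raise ValidationError("taxon means and W matrix trait labels differ")
    return means.to_numpy(dtype=float)


def drift_test(means: pd.DataFrame, w: TraitMatrix,
               min_eigenvalue_ratio: float = 1e-8) -> DriftRegressionResult:
    """Regression drift test: slope of log B_i on log λᵢᵂ, drift ⇒ slope 1.

    Taxon means (rows = taxa, columns = traits) are projected on the
    eigenvectors of W; B_i is the across-taxon variance of the i-th score.
    PCs with λᵢᵂ/λ₁ᵂ below ``min_eigenvalue_ratio`` are dropped to avoid
    logs of numerical zeros.  Drift is rejected when the 95% t-based CI of
    the slope excludes 1.
    """
    x = _means_array(means, w)
    n_taxa = x.shape[0]
    if n_taxa < 4:
        raise ValidationError("need at least 4 taxa for the regression test")
    if n_taxa < 8 or w.p < 20:
        warnings.warn(ADVISORY, stacklevel=2)
    lam, vec = eigen(w)
    keep = lam / lam[0] >= min_eigenvalue_ratio
    lam = lam[keep]
    if lam.size < 3:
        raise ValidationError("fewer than 3 PCs retained; cannot regress")
    scores = x @ vec[:, keep]
    b = scores.var(axis=0, ddof=1)
    positive = b > 0
    lam, b = lam[positive], b[positive]
    if lam.size < 3:
        raise ValidationError("fewer than 3 PCs with positive between-group variance")
    lx, ly = np.log(lam), np.log(b)
    res = stats.linregress(lx, ly)
    df = lam.size - 2
    if df > 0 and res.stderr > 0:
        tcrit = stats.t.ppf(0.975, df)
        lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    else:  # perfect fit: degenerate CI at the point estimate
        lo = hi = res.slope
    # epsilon guard so an exactly-proportional input is never "rejected"
    eps = 1e-9 * max(1.0, abs(res.slope))
    rejected = (1.0 < lo - eps) or (1.0 > hi + eps)
    verdict = (
        "drift rejected: the 95% CI of the regression slope excludes 1"
        if rejected else
        "drift not rejected: the observed divergence is compatible with "
        "drift (this is not evidence against selection)"
    )
    return DriftRegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        ci_lower=float(lo), ci_upper=float(hi),
        log_eigenvalues=lx, log_between_var=ly,
        retained=int(lam.size), drift_rejected=rejected, verdict=verdict,
    )


def multiv_drift_test(z0: np.ndarray, z1: np.ndarray, se1: np.ndarray,
                      w: TraitMatrix, t_over_ne: float, n_sim: int = 1000,
                      rng=0) -> MultivDriftResult:
    """Two-population drift test on the norm of the mean-difference vector.

    Derived means are simulated from MVN(z₀, (t/Nₑ)·W + diag(se₁²)); the
    drift-scale t/Nₑ must be supplied (it is not identified by the data).
    p = (1 + #{null norms ≥ observed})/(n_sim + 1).
    """
    z0 = np.asarray(z0, dtype=float).ravel()
    z1 = np.asarray(z1, dtype=float).ravel()
    se1 = np.asarray(se1, dtype=float).ravel()
    if not (len(z0) == len(z1) == len(se1) == w.p):
        raise ValidationError("z0, z1, se1 and W dimensions differ")
    if t_over_ne <= 0:
        raise ValidationError("t_over_ne must be positive")
    if n_sim < 100:
        raise ValidationError("need at least 100 simulations")
    g = as_generator(rng)
    sigma = t_over_ne * w.values + np.diag(se1**2)
    sims = g.multivariate_normal(z0, sigma, size=n_sim, method="cholesky")
    null_norms = np.linalg.norm(sims - z0, axis=1)
    observed = float(np.linalg.norm(z1 - z0))
    p = (1 + int(np.sum(null_norms >= observed))) / (n_sim + 1)
    verdict = (
        "divergence exceeds drift expectations, suggesting selection"
        if p < 0.05 else
        "observed divergence is compatible with drift (not evidence "
        "against selection)"
    )
    return MultivDriftResult(observed_norm=observed, null_norms=null_norms,
                             p_value=float(p), n_sim=n_sim,
                             t_over_ne=float(t_over_ne), verdict=verdict)


def pc_score_correlation(means: pd.DataFrame, w: TraitMatrix,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise correlations of taxon mean scores on the PCs of W.

    Returns a table of PC pairs with Pearson correlation, raw p, and a
    Bonferroni-adjusted significance flag over the p(p−1)/2 tests;
    flagged pairs are evidence of correlated directional selection.
    """
    x = _means_array(means, w)
    if x.shape[0] < 5:
        raise ValidationError("need at least 5 taxa")
    if x.shape[0] < 8 or w.p < 20:
        warnings.warn(ADVISORY, stacklevel=2)
    _, vec = eigen(w)
    scores = x @ vec
    p = w.p
    n_tests = p * (p - 1) // 2
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            si, sj = scores[:, i], scores[:, j]
            if np.std(si) == 0 or np.std(sj) == 0:
                rows.append({"pc_a": i + 1, "pc_b": j + 1, "correlation": np.nan,
                             "p_value": np.nan, "significant": False,
                             "note": "constant scores; skipped"})
                continue
            r, pv = stats.pearsonr(si, sj)
            rows.append({"pc_a": i + 1, "pc_b": j + 1, "correlation": float(r),
                         "p_value": float(pv),
                         "significant": bool(pv < alpha / n_tests),
                         "note": ""})
    return pd.DataFrame(rows)
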