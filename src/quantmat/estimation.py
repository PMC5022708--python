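"""Covariance-matrix estimation from individual-level data.

Covers the fixed-effects residual covariance (a simple MANCOVA residual
pooled matrix), a conjugate inverse-Wishart Bayesian estimator with a
diagonal shrinkage prior, and the one-way-ANOVA repeatability of repeated
measurements (the fraction of variance among rather than within
individuals — 1 means no measurement error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    IndividualTable,
    MatrixSample,
    TraitMatrix,
    ValidationError,
    as_generator,
)

__all__ = [
    "RepeatabilityVector",
    "BayesPosterior",
    "calculate_matrix",
    "bayesian_calculate_matrix",
    "calc_repeatability",
]


@dataclass
class RepeatabilityVector:
    """Per-trait repeatability r = s²_A / (s²_A + s²_W)."""

    trait_names: list[str]
    r: np.ndarray
    s2_among: np.ndarray
    s2_within: np.ndarray


@dataclass
class BayesPosterior:
    map_estimate: TraitMatrix
    prior_scale: TraitMatrix
    prior_df: float
    posterior_df: float
    samples: MatrixSample | None = None
    sample_median: TraitMatrix | None = None
    notes: list[str] | None = None


def _design_matrix(data: IndividualTable, fixed_factors: list[str]) -> np.ndarray:
    """Intercept + dummy coding of the requested factor columns."""
    n = data.n
    cols = [np.ones(n)]
    for f in fixed_factors:
        if f not in data.data.columns:
            raise ValidationError(f"unknown factor column {f!r}")
        levels = pd.Categorical(data.data[f])
        dummies = pd.get_dummies(levels, drop_first=True).to_numpy(dtype=float)
        cols.append(dummies)
    return np.column_stack(cols)


def calculate_matrix(data: IndividualTable,
                     fixed_factors: list[str] | None = None) -> TraitMatrix:
    """Residual covariance matrix after removing fixed effects.

    Each trait is regressed on the factor design by least squares; the
    covariance is the residual cross-product divided by n − rank(design).
    With no factors this is exactly the ordinary n−1 sample covariance.
    """
    fixed_factors = fixed_factors or []
    y = data.traits()
    x = _design_matrix(data, fixed_factors)
    rank = np.linalg.matrix_rank(x)
    if data.n <= rank:
        raise ValidationError(
            f"need more observations ({data.n}) than design rank ({rank})"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    cov = resid.T @ resid / (data.n - rank)
    return TraitMatrix(cov, data.trait_names, "covariance")


def bayesian_calculate_matrix(data: IndividualTable,
                              prior_df: float | str = "auto",
                              n_samples: int = 0,
                              rng=None) -> BayesPosterior:
    """Conjugate inverse-Wishart shrinkage estimate of the covariance matrix.

    The prior scale is ν₀ · diag(sample variances): shrinkage toward zero
    off-diagonals.  Posterior scale Λₙ = Λ₀ + S (centered cross-product),
    posterior df νₙ = ν₀ + n.  The MAP is the inverse-Wishart mode
    Λₙ / (νₙ + p + 1).  Optional posterior draws are inverse-Wishart(νₙ, Λₙ).
    """
    y = data.traits()
    n, p = y.shape
    if n < 2:
        raise ValidationError("need at least 2 individuals")
    notes: list[str] = []
    sample_var = y.var(axis=0, ddof=1)
    if prior_df == "auto":
        nu0 = float(p + 2)  # weakest proper prior with a finite mean
    else:
        nu0 = float(prior_df)
        if nu0 <= p - 1:
            notes.append(
                f"prior df {nu0} <= p-1 = {p - 1}: improper-prior regime; "
                "computation proceeds as requested"
            )
    lambda0 = nu0 * np.diag(sample_var)
    s = (y - y.mean(axis=0)).T @ (y - y.mean(axis=0))
    lambda_n = lambda0 + s
    nu_n = nu0 + n
    map_est = TraitMatrix(lambda_n / (nu_n + p + 1), data.trait_names, "covariance")

    samples = None
    median = None
    if n_samples > 0:
        g = as_generator(rng if rng is not None else 0)
        draws = stats.invwishart.rvs(df=nu_n, scale=lambda_n,
                                     size=n_samples, random_state=g)
        draws = draws.reshape(n_samples, p, p)
        samples = MatrixSample(
            [TraitMatrix(d, data.trait_names, "covariance") for d in draws],
            origin="posterior",
        )
        med = np.median(draws, axis=0)
        median = TraitMatrix((med + med.T) / 2, data.trait_names, "covariance")

    return BayesPosterior(
        map_estimate=map_est,
        prior_scale=TraitMatrix(lambda0, data.trait_names, "covariance"),
        prior_df=nu0,
        posterior_df=nu_n,
        samples=samples,
        sample_median=median,
        notes=notes or None,
    )


def calc_repeatability(data: IndividualTable) -> RepeatabilityVector:
    """One-way-ANOVA repeatability of replicated measurements, per trait.

    s²_W = MS_within; s²_A = (MS_among − MS_within)/n₀ with
    n₀ = (N − Σnᵢ²/N)/(a − 1) (the replicate count in the balanced case);
    negative among-individual components are clamped to zero.
    """
    if not data.has_replicates:
        raise ValidationError("repeatability needs a 'replicate' column")
    counts = data.data.groupby("individual").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValidationError(f"individuals with a single replicate: {bad}")
    a = len(counts)
    n_total = int(counts.sum())
    n0 = (n_total - (counts**2).sum() / n_total) / (a - 1)

    y = data.traits()
    groups = data.data["individual"].to_numpy()
    grand = y.mean(axis=0)
    ss_among = np.zeros(data.p)
    ss_within = np.zeros(data.p)
    for ind, cnt in counts.items():
        rows = y[groups == ind]
        gm = rows.mean(axis=0)
        ss_among += cnt * (gm - grand) ** 2
        ss_within += ((rows - gm) ** 2).sum(axis=0)
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n_total - a)
    s2_w = ms_within
    s2_a = np.maximum((ms_among - ms_within) / n0, 0.0)
    denom = s2_a + s2_w
    with np.errstate(invalid="ignore"):
        r = np.where(denom > 0, s2_a / np.where(denom > 0, denom, 1.0), 0.0)
    # replicates identical and individuals distinct => s2_w == 0, r == 1
    r = np.where((s2_w == 0) & (s2_a > 0), 1.0, r)
    return RepeatabilityVector(
        trait_names=list(data.trait_names),
        r=np.clip(r, 0.0, 1.0),
        s2_among=s2_a,
        s2_within=s2_w,
    )
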