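"""Hansen–Houle evolutionary statistics of a single covariance matrix.

Closed-form measures of integration (mean squared correlation r², the
coefficient of variation of eigenvalues ICV, and the fraction of variance
on the first principal component) plus the Monte-Carlo β-statistics taken
as expectations over random unit selection gradients:

    evolvability              ē = E[β·Gβ]
    respondability            r̄ = E[‖Gβ‖]
    flexibility               f̄ = E[cos(Gβ, β)]
    conditional evolvability  c̄ = E[(β·G⁻¹β)⁻¹]
    autonomy                  ā = E[((β·G⁻¹β)(β·Gβ))⁻¹]
    constraints                   E[|cos(Gβ, Λ₁)|]

Evolvability is the variance available along β; conditional evolvability
is the response along β when every other direction is under stabilizing
selection; autonomy is the fraction of variance along β independent of the
other directions (the per-draw ratio c/e); constraints measures how much
responses are deflected toward the leading principal component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    TraitMatrix,
    ValidationError,
    as_generator,
    eigen,
    random_unit_vectors,
    to_correlation,
)

__all__ = ["EvolStats", "closed_form_stats", "skewer_stats", "mean_matrix_statistics"]


@dataclass
class EvolStats:
    mean_squared_correlation: float | None = None
    icv: float | None = None
    pc1_percent: float | None = None
    evolvability: float | None = None
    respondability: float | None = None
    flexibility: float | None = None
    conditional_evolvability: float | None = None
    autonomy: float | None = None
    constraints: float | None = None
    standard_errors: dict = field(default_factory=dict)
    n_vectors: int | None = None
    seed: int | None = None
    draws: dict = field(default_factory=dict)  # per-β raw values, optional
    notes: list[str] = field(default_factory=list)


def closed_form_stats(m: TraitMatrix) -> EvolStats:
    """r², ICV and PC1% of a trait matrix.

    r² is the mean squared below-diagonal element of the correlation matrix
    (covariances are converted first, with a note); ICV = σ_λ/λ̄ using the
    sample (n−1) standard deviation of the eigenvalues; PC1% = λ₁/tr.
    """
    if m.p < 2:
        raise ValidationError("need at least 2 traits")
    notes = []
    if m.role == "covariance":
        corr = to_correlation(m)
        notes.append("r² computed on the correlation matrix derived from the input")
    else:
        corr = m
    low = corr.values[np.tril_indices(m.p, k=-1)]
    r2 = float(np.mean(low**2))

    out = EvolStats(mean_squared_correlation=r2, notes=notes)
    if m.role == "covariance":
        lam, _ = eigen(m)
        out.icv = float(np.std(lam, ddof=1) / np.mean(lam))
        out.pc1_percent = float(lam[0] / np.sum(lam))
    return out


def skewer_stats(m: TraitMatrix, n_vectors: int = 1000, rng=0,
                 betas: np.ndarray | None = None,
                 keep_draws: bool = False) -> EvolStats:
    """Monte-Carlo β-statistics over random unit selection gradients.

    Conditional evolvability and autonomy require an invertible matrix.
    Monte-Carlo standard errors (SD of the per-β draws / √n) are attached.
    """
    g = as_generator(rng)
    if betas is None:
        betas = random_unit_vectors(m.p, n_vectors, g)
    else:
        n_vectors = betas.shape[0]
    G = m.values
    resp = betas @ G  # rows: Gβ (G symmetric)
    e = np.einsum("ij,ij->i", betas, resp)  # β·Gβ
    norms = np.linalg.norm(resp, axis=1)
    f = e / norms  # cos(Gβ, β) = β·Gβ/‖Gβ‖ for unit β

    lam, vec = eigen(m)
    if lam[-1] > 0:
        ginv_b = np.linalg.solve(G, betas.T).T
        quad_inv = np.einsum("ij,ij->i", betas, ginv_b)  # β·G⁻¹β
        c = 1.0 / quad_inv
        a = c / e
    else:
        c = a = None

    constraints = np.abs(resp @ vec[:, 0]) / norms

    def mc(x):
        return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(len(x)))

    out = EvolStats(n_vectors=n_vectors)
    out.evolvability, se_e = mc(e)
    out.respondability, se_r = mc(norms)
    out.flexibility, se_f = mc(f)
    out.constraints, se_k = mc(constraints)
    out.standard_errors = {
        "evolvability": se_e, "respondability": se_r,
        "flexibility": se_f, "constraints": se_k,
    }
    if c is not None:
        out.conditional_evolvability, se_c = mc(c)
        out.autonomy, se_a = mc(a)
        out.standard_errors["conditional_evolvability"] = se_c
        out.standard_errors["autonomy"] = se_a
    else:
        out.notes.append(
            "matrix is singular: conditional evolvability and autonomy skipped"
        )
    if keep_draws:
        out.draws = {
            "evolvability": e, "respondability": norms, "flexibility": f,
            "constraints": constraints,
        }
        if c is not None:
            out.draws["conditional_evolvability"] = c
            out.draws["autonomy"] = a
    return out


def require_invertible(m: TraitMatrix, statistic: str) -> None:
    lam = np.linalg.eigvalsh(m.values)
    if lam.min() <= 0:
        raise ValidationError(f"{statistic} requires an invertible (SPD) matrix")


def mean_matrix_statistics(m: TraitMatrix, n_vectors: int = 1000, rng=0,
                           keep_draws: bool = False) -> EvolStats:
    """All closed-form and Monte-Carlo statistics in one record."""
    closed = closed_form_stats(m)
    seed_attr = rng if isinstance(rng, int) else None
    sk = skewer_stats(m, n_vectors=n_vectors, rng=rng, keep_draws=keep_draws)
    sk.mean_squared_correlation = closed.mean_squared_correlation
    sk.icv = closed.icv
    sk.pc1_percent = closed.pc1_percent
    sk.notes = closed.notes + sk.notes
    sk.seed = seed_attr
    return sk
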