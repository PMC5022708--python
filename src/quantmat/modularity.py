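"""Variational modularity: hypothesis tests, L-modularity, size removal.

Variational modularity is the pattern where traits in the same module are
more correlated than traits in different modules.  With an a-priori
hypothesis (from development or function) the observed correlation matrix
is compared to a binary module-membership matrix; without one, the trait
partition is inferred directly from the correlation matrix by maximizing
a Newman-style modularity score on the fully connected weighted graph
whose edge weights are the absolute correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import TraitMatrix, ValidationError, as_generator, eigen
from .comparison import mantel_cor

__all__ = [
    "ModularityHypothesis",
    "HypothesisTestResult",
    "LModularityResult",
    "test_modularity",
    "l_modularity",
    "remove_size",
]


@dataclass
class ModularityHypothesis:
    """Named binary module-membership matrices over a common trait set."""

    trait_names: list[str]
    matrices: dict[str, np.ndarray]  # name -> symmetric binary, zero diagonal

    def __post_init__(self):
        p = len(self.trait_names)
        for name, h in self.matrices.items():
            h = np.asarray(h)
            if h.shape != (p, p):
                raise ValidationError(f"hypothesis {name!r} has wrong shape")
            if not np.array_equal(h, h.T):
                raise ValidationError(f"hypothesis {name!r} is not symmetric")
            if not np.isin(h, (0, 1)).all():
                raise ValidationError(f"hypothesis {name!r} is not binary")
            h = h.copy()
            np.fill_diagonal(h, 0)
            self.matrices[name] = h.astype(float)

    @classmethod
    def from_membership(cls, trait_names, modules: dict[str, list[int]]):
        """Build from module -> trait-index lists (one hypothesis per module)."""
        p = len(trait_names)
        mats = {}
        for name, idx in modules.items():
            h = np.zeros((p, p))
            for i, j in itertools.combinations(sorted(idx), 2):
                h[i, j] = h[j, i] = 1.0
            mats[name] = h
        return cls(list(trait_names), mats)


@dataclass
class HypothesisTestResult:
    hypothesis: str
    mantel_correlation: float
    p_value: float
    avg_plus: float      # mean correlation within modules
    avg_minus: float     # mean correlation between modules
    avg_ratio: float
    mhi: float           # (AVG+ − AVG−)/ICV
    skipped: bool = False
    note: str | None = None


def _icv(corr: TraitMatrix) -> float:
    lam, _ = eigen(corr)
    return float(np.std(lam, ddof=1) / np.mean(lam))


def test_modularity(corr: TraitMatrix, hypotheses: ModularityHypothesis,
                    permutations: int = 1000, rng=0) -> list[HypothesisTestResult]:
    """Test a-priori modularity hypotheses against a correlation matrix.

    Per hypothesis: Mantel correlation (with permutation p) between the
    binary hypothesis matrix and the observed correlations; AVG+ (mean
    correlation over within-module pairs), AVG− (between-module pairs),
    their ratio, and MHI = (AVG+ − AVG−)/ICV.  A combined "full model"
    hypothesis (union of all) is appended.  The AVG ratio is meaningless
    when correlations differ in sign (use MHI, or remove_size first).
    """
    if corr.role != "correlation":
        raise ValidationError("modularity tests require a correlation matrix")
    if not hypotheses.matrices:
        raise ValidationError("need at least one hypothesis")
    g = as_generator(rng)
    icv = _icv(corr)
    low_idx = np.tril_indices(corr.p, k=-1)
    obs = corr.values[low_idx]

    todo = dict(hypotheses.matrices)
    if len(todo) > 1:
        union = (sum(todo.values()) > 0).astype(float)
        todo["full model"] = union

    results = []
    for name, h in todo.items():
        mask = h[low_idx] > 0
        if mask.all() or not mask.any():
            results.append(HypothesisTestResult(
                hypothesis=name, mantel_correlation=np.nan, p_value=np.nan,
                avg_plus=np.nan, avg_minus=np.nan, avg_ratio=np.nan, mhi=np.nan,
                skipped=True,
                note="hypothesis is constant below the diagonal; skipped"))
            continue
        hm = TraitMatrix(h + np.eye(corr.p), corr.labels, "correlation")
        try:
            mres = mantel_cor(corr, hm, permutations=permutations, rng=g)
            mantel_value, mantel_p = mres.value, mres.p_value
        except ValidationError:
            # constant observed correlations: AVG statistics still defined
            mantel_value = mantel_p = np.nan
        avg_plus = float(obs[mask].mean())
        avg_minus = float(obs[~mask].mean())
        results.append(HypothesisTestResult(
            hypothesis=name, mantel_correlation=mantel_value, p_value=mantel_p,
            avg_plus=avg_plus, avg_minus=avg_minus,
            avg_ratio=avg_plus / avg_minus if avg_minus != 0 else np.inf,
            mhi=(avg_plus - avg_minus) / icv,
        ))
    return results


# ---------------------------------------------------------------------------
# L-modularity
# ---------------------------------------------------------------------------

@dataclass
class LModularityResult:
    partition: np.ndarray        # trait -> module id
    l_value: float
    strengths: np.ndarray        # per-trait k_i = Σ|r_ij|
    total_weight: float          # Σ k_i
    trait_names: list[str] = field(default_factory=list)
    note: str | None = None


def _l_value(w: np.ndarray, partition: np.ndarray) -> float:
    """Newman-style modularity of a partition on weight matrix w (zero diag).

    L = Σ_{i≠j} w_ij δ(g_i, g_j) − Σ_{i,j} k_i k_j / (Σk) δ(g_i, g_j).
    The null sum includes the i = j terms, which makes the single-module
    partition score exactly zero.
    """
    k = w.sum(axis=1)
    total = k.sum()
    if total == 0:
        return 0.0
    same = partition[:, None] == partition[None, :]
    null = np.outer(k, k) / total
    return float((w * same).sum() - (null * same).sum())


def _greedy_once(w: np.ndarray, g: np.random.Generator) -> tuple[np.ndarray, float]:
    p = w.shape[0]
    part = np.arange(p)
    best = _l_value(w, part)
    improved = True
    while improved:
        improved = False
        # agglomerative merges
        mods = np.unique(part)
        best_merge = None
        for a, b in itertools.combinations(mods, 2):
            trial = np.where(part == b, a, part)
            lv = _l_value(w, trial)
            if lv > best + 1e-12:
                best_merge = (lv, trial)
                best = lv
        if best_merge is not None:
            part = best_merge[1]
            improved = True
            continue
        # single-trait relocation passes
        for i in g.permutation(p):
            for target in np.unique(part):
                if target == part[i]:
                    continue
                trial = part.copy()
                trial[i] = target
                lv = _l_value(w, trial)
                if lv > best + 1e-12:
                    part, best = trial, lv
                    improved = True
    return part, best


def _canonical(partition: np.ndarray) -> np.ndarray:
    """Relabel modules by order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(partition)
    for i, m in enumerate(partition):
        out[i] = mapping.setdefault(int(m), len(mapping))
    return out


def _all_partitions(n: int):
    """Enumerate all set partitions of range(n) as label arrays."""
    if n == 0:
        yield np.empty(0, dtype=int)
        return
    labels = np.zeros(n, dtype=int)

    def rec(i: int, k: int):
        if i == n:
            yield labels.copy()
            return
        for m in range(k + 1):
            labels[i] = m
            yield from rec(i + 1, max(k, m + 1))

    yield from rec(1, 1)


def l_modularity(corr: TraitMatrix, optimizer: str = "greedy", rng=0,
                 restarts: int = 20) -> LModularityResult:
    """Data-driven modular partition maximizing the L-modularity score.

    The correlation matrix is treated as a fully connected weighted graph
    with edge weights |r_ij|; trait strength k_i = Σ_j |r_ij|, and the
    partition maximizing L (see :func:`_l_value`) is found by seeded
    greedy agglomeration with relocation passes and random restarts, or by
    exhaustive enumeration for p ≤ 12.  Negative correlations enter by
    absolute value; consider removing a size factor first when signs are
    mixed.
    """
    if corr.role != "correlation":
        raise ValidationError("L-modularity requires a correlation matrix")
    w = np.abs(corr.values.copy())
    np.fill_diagonal(w, 0.0)
    k = w.sum(axis=1)
    total = float(k.sum())
    if total == 0:
        return LModularityResult(
            partition=np.zeros(corr.p, dtype=int), l_value=0.0,
            strengths=k, total_weight=0.0, trait_names=list(corr.labels),
            note="all off-diagonal correlations are zero; single module")
    if optimizer == "exhaustive":
        if corr.p > 12:
            raise ValidationError("exhaustive search is limited to p <= 12")
        best_part, best_l = None, -np.inf
        for part in _all_partitions(corr.p):
            lv = _l_value(w, part)
            if lv > best_l:
                best_part, best_l = part.copy(), lv
    elif optimizer == "greedy":
        g = as_generator(rng)
        best_part, best_l = None, -np.inf
        for _ in range(restarts):
            part, lv = _greedy_once(w, g)
            if lv > best_l:
                best_part, best_l = part, lv
    else:
        raise ValidationError(f"unknown optimizer {optimizer!r}")
    return LModularityResult(partition=_canonical(best_part), l_value=best_l,
                             strengths=k, total_weight=total,
                             trait_names=list(corr.labels))


# ---------------------------------------------------------------------------
# Size removal
# ---------------------------------------------------------------------------

def remove_size(m: TraitMatrix) -> tuple[TraitMatrix, np.ndarray]:
    """Remove the dominant (size) factor along the first principal component.

    With v = Λ₁, the residual is m − (mv)(mv)ᵀ/(vᵀmv), which has zero
    variance along Λ₁ and rank p − 1; the size vector mv/√(vᵀmv) restores
    the removed rank-1 component.  A warning note is attached when Λ₁ is
    not predominantly of one sign (no size interpretation).
    """
    lam, vec = eigen(m)
    v = vec[:, 0]
    signs = np.sign(v[np.abs(v) > 1e-12])
    if signs.size and not (np.all(signs > 0) or np.all(signs < 0)):
        import warnings
        warnings.warn("first principal component has mixed signs; "
                      "size interpretation is doubtful", stacklevel=2)
    mv = m.values @ v
    quad = float(v @ mv)
    residual = m.values - np.outer(mv, mv) / quad
    residual = (residual + residual.T) / 2
    # clip tiny negative eigenvalues from floating-point cancellation
    w, q = np.linalg.eigh(residual)
    residual = (q * np.maximum(w, 0.0)) @ q.T
    return m.with_values(residual), mv / np.sqrt(quad)
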