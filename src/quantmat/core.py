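"""Core domain types, SPD linear algebra and file I/O.

The central object is the :class:`TraitMatrix`, a labeled symmetric trait
covariance or correlation matrix (a G-matrix, P-matrix, within-group W or
between-group B matrix).  All other modules operate on these, on
individual-level measurement tables, on ordered samples of matrices
(bootstrap or posterior draws) and on labeled phylogenetic trees.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "SelectionGradient",
    "ResponseVector",
    "IndividualTable",
    "MatrixSample",
    "LabeledTree",
    "RNGStream",
    "as_generator",
    "read_matrix",
    "to_correlation",
    "eigen",
    "matrix_log",
    "matrix_exp",
    "matrix_sqrt",
    "random_unit_vectors",
    "read_tree",
    "read_matrix_sample",
    "read_individual_table",
    "write_result",
]

SYMMETRY_TOL = 1e-8


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files (non-square, bad header)."""


class ValidationError(ValueError):
    """Raised when a loaded object violates a domain invariant."""


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------

@dataclass
class RNGStream:
    """Seeded random-number stream with derivable independent substreams.

    Every stochastic operation takes an explicit stream (or a raw numpy
    Generator); there is no global RNG.  The same seed yields bit-identical
    outputs.
    """

    seed: int

    def generator(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def substream(self, key: str) -> np.random.Generator:
        # stable across runs and platforms: CRC32 of the key folds into the seed
        sub = zlib.crc32(key.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([self.seed, sub]))


def as_generator(rng) -> np.random.Generator:
    """Coerce an int seed, RNGStream, or Generator into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, RNGStream):
        return rng.generator()
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    raise TypeError(f"cannot interpret {rng!r} as a random generator")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TraitMatrix:
    """A labeled p×p symmetric covariance or correlation matrix."""

    values: np.ndarray
    labels: list[str]
    role: str  # "covariance" | "correlation"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        if self.role not in ("covariance", "correlation"):
            raise ValidationError(f"unknown role {self.role!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixFormatError(f"matrix must be square, got shape {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise MatrixFormatError("label count does not match matrix dimension")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        if asym > 1e-10:
            raise ValidationError(f"matrix asymmetric beyond tolerance ({asym:.3g})")
        self.values = (v + v.T) / 2.0
        if self.role == "correlation":
            if np.any(np.abs(self.values) > 1 + 1e-12):
                raise ValidationError("correlation entries outside [-1, 1]")
            np.fill_diagonal(self.values, 1.0)
            self.values = np.clip(self.values, -1.0, 1.0)
        else:
            w = np.linalg.eigvalsh(self.values)
            tr = max(np.trace(self.values), np.finfo(float).tiny)
            if w.min() < -1e-10 * tr:
                raise ValidationError(
                    f"covariance matrix not PSD (min eigenvalue {w.min():.3g})"
                )

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Sequence[str]) -> "TraitMatrix":
        """Return a copy with rows/columns permuted to the given label order."""
        idx = [self.labels.index(l) for l in labels]
        if sorted(labels) != sorted(self.labels):
            raise ValidationError("label sets differ; cannot reorder")
        return TraitMatrix(self.values[np.ix_(idx, idx)], list(labels), self.role)

    def with_values(self, values: np.ndarray, role: str | None = None) -> "TraitMatrix":
        return TraitMatrix(values, self.labels, role or self.role)

    def is_pd(self, tol: float = 0.0) -> bool:
        return bool(np.linalg.eigvalsh(self.values).min() > tol)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path)


def check_same_shape(a: TraitMatrix, b: TraitMatrix) -> None:
    if a.p != b.p:
        raise ValidationError(f"matrix dimensions differ ({a.p} vs {b.p})")
    if a.labels != b.labels:
        raise ValidationError("trait labels differ; use reorder() first")


@dataclass
class SelectionGradient:
    """A directional selection gradient β of the Lande equation Δz = Gβ."""

    beta: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.normalized and abs(np.linalg.norm(self.beta) - 1.0) > 1e-12:
            raise ValidationError("normalized gradient must have unit norm")


@dataclass
class ResponseVector:
    """A response-to-selection vector Δz."""

    dz: np.ndarray

    def __post_init__(self):
        self.dz = np.asarray(self.dz, dtype=float).ravel()
        if not np.all(np.isfinite(self.dz)):
            raise ValidationError("response vector has non-finite entries")


class IndividualTable:
    """n individuals × p traits, with optional replicate and factor columns.

    Column conventions (CSV and DataFrame alike): ``individual`` identifies
    the individual, optional ``replicate`` the repeated measurement, columns
    prefixed ``factor_`` are categorical fixed effects, and every remaining
    numeric column is a trait.
    """

    def __init__(self, data: pd.DataFrame):
        if "individual" not in data.columns:
            raise ValidationError("IndividualTable requires an 'individual' column")
        self.data = data.reset_index(drop=True)
        self.factors = [c for c in data.columns if c.startswith("factor_")]
        self.has_replicates = "replicate" in data.columns
        reserved = {"individual", "replicate", *self.factors}
        self.trait_names = [c for c in data.columns if c not in reserved]
        if not self.trait_names:
            raise ValidationError("no trait columns found")
        traits = data[self.trait_names]
        if traits.isna().any().any():
            raise ValidationError("missing trait values are not allowed")
        if data["individual"].nunique() < 2:
            raise ValidationError("need at least 2 individuals")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return len(self.trait_names)

    def traits(self) -> np.ndarray:
        return self.data[self.trait_names].to_numpy(dtype=float)

    def subset(self, rows: np.ndarray) -> "IndividualTable":
        return IndividualTable(self.data.iloc[rows].reset_index(drop=True))

    def write(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class MatrixSample:
    """An ordered set of same-shaped TraitMatrices (bootstrap/posterior draws)."""

    matrices: list[TraitMatrix]
    origin: str = "user"  # bootstrap | montecarlo | posterior | user

    def __post_init__(self):
        if not self.matrices:
            raise ValidationError("empty matrix sample")
        ref = self.matrices[0]
        for m in self.matrices[1:]:
            if m.p != ref.p or m.labels != ref.labels or m.role != ref.role:
                raise ValidationError("sample members differ in shape, labels or role")

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    def __getitem__(self, i) -> TraitMatrix:
        return self.matrices[i]

    @property
    def labels(self) -> list[str]:
        return self.matrices[0].labels

    @property
    def p(self) -> int:
        return self.matrices[0].p

    def as_array(self) -> np.ndarray:
        return np.stack([m.values for m in self.matrices])


class LabeledTree:
    """A rooted tree whose nodes may carry a (TraitMatrix, weight) payload."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate tip labels")
        for node in tree:
            if not hasattr(node, "payload"):
                node.payload = None  # (TraitMatrix, weight) once attached

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def has_branch_lengths(self) -> bool:
        return any(
            e.length is not None for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        )

    def attach_tip_payloads(self, matrices: dict[str, TraitMatrix],
                            weights: dict[str, float]) -> None:
        for leaf in self.tree.leaf_node_iter():
            label = leaf.taxon.label
            if label not in matrices:
                raise ValidationError(f"missing matrix for tip {label!r}")
            w = float(weights[label])
            if w <= 0:
                raise ValidationError(f"non-positive weight for tip {label!r}")
            leaf.payload = (matrices[label], w)


# ---------------------------------------------------------------------------
# SPD linear algebra
# ---------------------------------------------------------------------------

def eigen(m: TraitMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with descending eigenvalues and a fixed sign gauge.

    Returns ``(w, V)`` with ``w`` descending and ``V[:, i]`` the i-th
    orthonormal eigenvector, its largest-magnitude entry made positive.
    """
    a = m.values if isinstance(m, TraitMatrix) else np.asarray(m, dtype=float)
    w, v = np.linalg.eigh(a)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    return w, v * flip


def _apply_spectral(a: np.ndarray, f: Callable[[np.ndarray], np.ndarray],
                    require_pd: bool) -> np.ndarray:
    a = a.values if isinstance(a, TraitMatrix) else np.asarray(a, dtype=float)
    w, v = np.linalg.eigh(a)
    if require_pd and w.min() <= 0:
        raise ValidationError(
            f"matrix function requires positive eigenvalues (min {w.min():.3g})"
        )
    out = (v * f(w)) @ v.T
    return (out + out.T) / 2.0


def matrix_log(a) -> np.ndarray:
    """Matrix logarithm of an SPD matrix via eigendecomposition."""
    return _apply_spectral(a, np.log, require_pd=True)


def matrix_exp(a) -> np.ndarray:
    """Matrix exponential of a symmetric matrix."""
    return _apply_spectral(a, np.exp, require_pd=False)


def matrix_sqrt(a) -> np.ndarray:
    """Principal square root of an SPD matrix."""
    return _apply_spectral(a, np.sqrt, require_pd=True)


def random_unit_vectors(p: int, n: int, rng) -> np.ndarray:
    """n i.i.d. unit vectors uniform on the (p−1)-sphere, one per row.

    Standard normal draws normalized to unit Euclidean norm — the random
    selection gradients of the skewer methods.
    """
    if p < 1 or n < 1:
        raise ValueError("p and n must be >= 1")
    g = as_generator(rng)
    x = g.standard_normal((n, p))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def to_correlation(m: TraitMatrix) -> TraitMatrix:
    """Rescale a covariance matrix to a correlation matrix."""
    if m.role != "covariance":
        raise ValidationError("to_correlation expects a covariance matrix")
    d = np.diag(m.values)
    if np.any(d <= 0):
        raise ValidationError("zero or negative variance on the diagonal")
    s = 1.0 / np.sqrt(d)
    r = m.values * np.outer(s, s)
    np.fill_diagonal(r, 1.0)
    return TraitMatrix(np.clip(r, -1.0, 1.0), m.labels, "correlation")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path, role: str) -> TraitMatrix:
    """Read a labeled square matrix CSV (first row and column are labels)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(
            f"matrix body must be square, got {df.shape[0]}×{df.shape[1]}"
        )
    v = df.to_numpy(dtype=float)
    asym = np.max(np.abs(v - v.T)) if v.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValidationError(f"asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}")
    v = (v + v.T) / 2.0
    return TraitMatrix(v, list(df.index.astype(str)), role)


def read_individual_table(path) -> IndividualTable:
    return IndividualTable(pd.read_csv(path))


def read_tree(path_or_string) -> LabeledTree:
    """Read a rooted Newick tree; accepts a path or a Newick string."""
    s = str(path_or_string)
    try:
        if s.strip().startswith("(") or s.strip().endswith(";"):
            tree = dendropy.Tree.get(data=s, schema="newick")
        else:
            tree = dendropy.Tree.get(path=s, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip labels: {exc}") from exc
    return LabeledTree(tree)


def read_matrix_sample(path, role: str = "covariance",
                       origin: str = "user") -> MatrixSample:
    """Read a MatrixSample from a directory of CSVs or a stacked CSV.

    The stacked format has a ``sample`` column holding the draw index, a
    ``trait`` column holding the row label, and one column per trait.
    """
    path = Path(path)
    mats: list[TraitMatrix] = []
    if path.is_dir():
        for f in sorted(path.glob("*.csv")):
            mats.append(read_matrix(f, role))
    else:
        df = pd.read_csv(path)
        if "sample" not in df.columns or "trait" not in df.columns:
            raise MatrixFormatError("stacked sample CSV needs 'sample' and 'trait' columns")
        traits = [c for c in df.columns if c not in ("sample", "trait")]
        for _, grp in df.groupby("sample", sort=True):
            body = grp.set_index("trait").loc[traits, traits]
            mats.append(TraitMatrix(body.to_numpy(dtype=float), traits, role))
    return MatrixSample(mats, origin=origin)


def write_matrix_sample(sample: MatrixSample, path) -> None:
    rows = []
    for i, m in enumerate(sample):
        df = m.to_dataframe().reset_index(names="trait")
        df.insert(0, "sample", i)
        rows.append(df)
    pd.concat(rows).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, TraitMatrix):
        return {"labels": obj.labels, "role": obj.role, "values": obj.values.tolist()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def write_result(obj, path, *, method: str | None = None,
                 params: dict | None = None, seed: int | None = None) -> None:
    """Serialize a result as JSON with method, parameters and seed metadata."""
    payload = {
        "method": method,
        "params": _jsonable(params or {}),
        "seed": seed,
        "result": _jsonable(obj),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
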