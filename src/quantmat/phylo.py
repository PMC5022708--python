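"""Phylogenetically structured pooling and comparison of trait matrices.

Given per-tip covariance matrices and sample sizes, each internal node is
assigned the sample-size-weighted mean of its children's matrices; the
root then equals the pooled within-group matrix of a MANCOVA with the
terminal clades as fixed effects.  Branch lengths are ignored — a warning
is emitted when the tree carries them — so the pooling should be used
carefully when matrix divergence correlates with phylogenetic distance.
Sister groups at every internal node can then be compared by any pairwise
matrix-comparison method, localizing major covariance transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .comparison import ComparisonResult, compare_matrices
from .core import LabeledTree, TraitMatrix, ValidationError, as_generator

__all__ = ["phylo_w", "phylo_compare", "NodeComparison"]


def phylo_w(tree: LabeledTree, tip_matrices: dict[str, TraitMatrix],
            tip_weights: dict[str, float]) -> LabeledTree:
    """Attach weighted-mean matrices to every internal node (post-order).

    Each internal node's matrix is the weighted mean of its children's
    matrices (weights = sample sizes, summed up the tree); the root holds
    the global weighted mean over all tips.
    """
    tree.attach_tip_payloads(tip_matrices, tip_weights)
    if tree.has_branch_lengths():
        warnings.warn("tree has branch lengths; phylogenetic pooling ignores "
                      "them", stacklevel=2)
    ref = next(iter(tip_matrices.values()))
    for m in tip_matrices.values():
        if m.p != ref.p:
            raise ValidationError("tip matrices differ in dimension")
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            if node.payload is None:
                raise ValidationError(
                    f"missing payload for tip {node.taxon.label!r}")
            continue
        children = node.child_nodes()
        total_w = sum(c.payload[1] for c in children)
        pooled = sum(c.payload[1] * c.payload[0].values for c in children) / total_w
        node.payload = (TraitMatrix(pooled, ref.labels, ref.role), total_w)
    return tree


@dataclass
class NodeComparison:
    node_id: int                  # post-order index of the internal node
    tips: list[str]               # descendant tip labels
    results: list[ComparisonResult]
    note: str | None = None


def phylo_compare(tree: LabeledTree, comparison_method: str = "random_skewers",
                  rng=0, **kwargs) -> list[NodeComparison]:
    """Compare sister groups at every internal node of a payload-bearing tree.

    Binary nodes yield one comparison of the two children; multifurcations
    are compared all-pairs with a note.  Run :func:`phylo_w` first.
    """
    g = as_generator(rng)
    out = []
    for idx, node in enumerate(tree.tree.postorder_node_iter()):
        if node.is_leaf():
            continue
        if node.payload is None:
            raise ValidationError("internal node lacks a payload; run phylo_w first")
        children = node.child_nodes()
        for c in children:
            if c.payload is None:
                raise ValidationError("child node lacks a payload; run phylo_w first")
        results = []
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                results.append(compare_matrices(
                    children[i].payload[0], children[j].payload[0],
                    comparison_method, rng=g, **kwargs))
        tips = sorted(l.taxon.label for l in node.leaf_iter())
        note = (f"multifurcation of {len(children)}: all-pairs comparisons"
                if len(children) > 2 else None)
        out.append(NodeComparison(node_id=idx, tips=tips, results=results,
                                  note=note))
    return out
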