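"""Maximal-subtree minimal-depth statistics for variable interactions.

A *maximal v-subtree* is a subtree whose root splits on variable v and has
no ancestor splitting on v. The pairwise minimal depth of w within a
maximal v-subtree is the edge distance d from the subtree root to the
closest maximal w-subtree root inside it; normalized by the subtree depth m
(longest root-to-terminal path), d/m lies in [0, 1] and small values mark
variables that split close together — evidence of interaction. Values from
all maximal v-subtrees of all trees are averaged and symmetrized into a
pair-depth matrix; pairs that never co-occur receive the penalty value 1.

Under a balanced-tree model where every node splits on a uniformly chosen
variable out of p ("weak variable" assumption), the single-variable minimal
depth D_v has the closed form

    P(D_v = s) = (1 - 1/p)^(2^s - 1) * [1 - (1 - 1/p)^(2^s)],

since D_v > s - 1 exactly when none of the 2^s - 1 nodes above level s
splits on v. The convolution of two such laws gives the distribution of the
pairwise depth D_{v,w}, whose CDF is available as an alternative
normalization of the observed d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .forest_core import Forest, Tree

__all__ = [
    "MaxSubtreeRecord",
    "PairDepthMatrix",
    "find_maximal_subtrees",
    "minimal_depth",
    "subtree_stats",
    "pair_normalized_depths",
    "forest_pair_depth",
    "minimal_depth_pmf",
    "pair_depth_pmf",
    "pair_depth_cdf",
]


@dataclass
class MaxSubtreeRecord:
    tree_id: int
    var: int
    subtree_root_node_id: int
    root_depth_in_tree: int
    subtree_depth: int
    pair_depths: dict[int, int]


@dataclass
class PairDepthMatrix:
    """Forest-averaged, symmetrized normalized pair depths.

    ``values[i, j]`` is the interaction index for (variables[i],
    variables[j]); the diagonal is 1 by convention and cells with no
    observations in either direction carry the no-co-occurrence penalty 1.
    ``count_matrix`` holds the total number of (tree, maximal subtree)
    observations behind each symmetric cell.
    """

    variables: np.ndarray
    values: np.ndarray
    count_matrix: np.ndarray

    def to_frame(self, labels: Sequence[str] | None = None):
        import pandas as pd

        idx = labels if labels is not None else [str(v) for v in self.variables]
        return pd.DataFrame(self.values, index=idx, columns=idx)


def find_maximal_subtrees(tree: Tree, v: int) -> list[int]:
    """Roots of all maximal v-subtrees (nodes splitting on v with no
    v-splitting ancestor). Returns an empty list if v never splits."""
    roots: list[int] = []
    stack: list[tuple[int, bool]] = [(0, False)]
    while stack:
        node, seen_v = stack.pop()
        if tree.split_var[node] < 0:
            continue
        splits_v = tree.split_var[node] == v
        if splits_v and not seen_v:
            roots.append(node)
        nxt = seen_v or bool(splits_v)
        stack.append((int(tree.left[node]), nxt))
        stack.append((int(tree.right[node]), nxt))
    return sorted(roots)


def minimal_depth(tree: Tree, v: int) -> int | None:
    """Depth of the closest maximal v-subtree root; None if v never splits."""
    roots = find_maximal_subtrees(tree, v)
    if not roots:
        return None
    return int(min(tree.depth[r] for r in roots))


def subtree_stats(tree: Tree, root: int) -> tuple[int, dict[int, int]]:
    """(m, {w: d}) for the subtree at ``root``.

    m is the longest root-to-terminal edge count within the subtree; the map
    gives, for every variable w splitting inside the subtree below its root,
    the minimal relative depth of a w-split — which is exactly the depth of
    the closest maximal w-subtree root within the subtree, since the
    shallowest w-split can have no w-ancestor inside it.
    """
    m = 0
    dmap: dict[int, int] = {}
    stack: list[tuple[int, int]] = [(root, 0)]
    while stack:
        node, d = stack.pop()
        if tree.split_var[node] < 0:
            m = max(m, d)
            continue
        if d > 0:
            w = int(tree.split_var[node])
            if w not in dmap or d < dmap[w]:
                dmap[w] = d
        stack.append((int(tree.left[node]), d + 1))
        stack.append((int(tree.right[node]), d + 1))
    return m, dmap


def _maximal_roots(tree: Tree) -> list[int]:
    """All nodes that are maximal-subtree roots for their own split variable."""
    roots: list[int] = []
    stack: list[tuple[int, frozenset]] = [(0, frozenset())]
    while stack:
        node, seen = stack.pop()
        var = int(tree.split_var[node])
        if var < 0:
            continue
        if var not in seen:
            roots.append(node)
            seen = seen | {var}
        stack.append((int(tree.left[node]), seen))
        stack.append((int(tree.right[node]), seen))
    return roots


def pair_normalized_depths(tree: Tree, v: int, w: int) -> list[float]:
    """d/m values of w for every maximal v-subtree containing a w-split."""
    out: list[float] = []
    for root in find_maximal_subtrees(tree, v):
        m, dmap = subtree_stats(tree, root)
        if m > 0 and w in dmap:
            out.append(dmap[w] / m)
    return out


def forest_pair_depth(
    forest: Forest | Iterable[Tree],
    variables: Sequence[int],
    normalization: str = "dm",
) -> PairDepthMatrix:
    """Forest-averaged pairwise normalized minimal depths.

    Directional observations (v -> w) are averaged separately, then the two
    directions with observations are averaged into a symmetric index; cells
    without observations in either direction are set to the penalty 1, and
    the diagonal is 1 by convention. Smaller values indicate stronger
    interaction. ``normalization='cdf'`` replaces d/m by the analytic CDF
    P(D_{v,w} <= d) evaluated with l = m under the weak-variable model.
    """
    if normalization not in ("dm", "cdf"):
        raise ValueError(f"unknown normalization {normalization!r}")
    trees = forest.trees if isinstance(forest, Forest) else list(forest)
    if not trees:
        raise ValueError("empty forest")
    variables = np.asarray(variables, dtype=np.int64)
    k = len(variables)
    pos = {int(v): i for i, v in enumerate(variables)}
    n_vars = forest.n_vars if isinstance(forest, Forest) else int(
        max((int(t.split_var.max(initial=-1)) for t in trees), default=0) + 1
    )
    sums = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=np.int64)
    cdf_cache: dict[tuple[int, int], float] = {}
    for tree in trees:
        for root in _maximal_roots(tree):
            v = int(tree.split_var[root])
            vi = pos.get(v)
            if vi is None:
                continue
            m, dmap = subtree_stats(tree, root)
            if m == 0:
                continue
            for w, d in dmap.items():
                wj = pos.get(int(w))
                if wj is None or wj == vi:
                    continue
                if normalization == "dm":
                    val = d / m
                else:
                    key = (d, m)
                    if key not in cdf_cache:
                        cdf_cache[key] = pair_depth_cdf(n_vars, d, m)
                    val = cdf_cache[key]
                sums[vi, wj] += val
                counts[vi, wj] += 1
    with np.errstate(invalid="ignore"):
        directional = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    both = counts + counts.T
    values = np.ones((k, k))
    fwd = counts > 0
    bwd = counts.T > 0
    either = fwd | bwd
    avg = (
        np.where(fwd, directional, 0.0) + np.where(bwd, directional.T, 0.0)
    ) / np.maximum(fwd.astype(int) + bwd.astype(int), 1)
    values[either] = avg[either]
    np.fill_diagonal(values, 1.0)
    return PairDepthMatrix(variables=variables, values=values, count_matrix=both)


def minimal_depth_pmf(p: int, s: int) -> float:
    """P(D_v = s) under the balanced-tree weak-variable model."""
    if p < 1 or s < 0:
        raise ValueError("require p >= 1 and s >= 0")
    if p == 1:
        return 1.0 if s == 0 else 0.0
    if s == 0:
        return 1.0 / p  # (1-1/p)^0 * [1 - (1-1/p)] reduces exactly
    a = 1.0 - 1.0 / p
    return a ** (2.0**s - 1.0) * (1.0 - a ** (2.0**s))


def pair_depth_pmf(p: int, d: int, l: int) -> float:
    """P(D_{v,w} = d) in a tree of depth ``l`` for independent weak v, w:
    the convolution sum over the level l - m at which the v-subtree starts."""
    if not 0 <= d <= l:
        raise ValueError("require 0 <= d <= l")
    return float(
        sum(
            minimal_depth_pmf(p, l - m) * minimal_depth_pmf(p, l - m + d)
            for m in range(d, l + 1)
        )
    )


def pair_depth_cdf(p: int, d: int, l: int) -> float:
    """P(D_{v,w} <= d): partial sum of :func:`pair_depth_pmf` over 0..d."""
    if not 0 <= d <= l:
        raise ValueError("require 0 <= d <= l")
    return float(sum(pair_depth_pmf(p, dd, l) for dd in range(d + 1)))
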