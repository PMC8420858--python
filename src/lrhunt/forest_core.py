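"""Multivariate unsupervised regression forests.

Trees are grown by recursive partitioning with the *pseudo-response*
splitting rule: at every node a fresh random set of ``q`` variables is
treated as a multivariate regression target, and the best split of a
candidate variable minimizes the within-daughter sum of squared
deviations summed over the pseudo-responses,

    D_q(s, t) = sum_k [ sum_{j in t_L} (X_jk - mean_Lk)^2
                      + sum_{j in t_R} (X_jk - mean_Rk)^2 ].

This gives an unsupervised forest a supervised splitting criterion and is
the shared engine for (a) random-forest missing-data imputation of the
interaction-space matrix and (b) interaction detection via maximal-subtree
minimal depth.

Missing values (NaN) are supported: they are discarded when evaluating the
split statistic, and cases missing the chosen split variable are routed by
drawing a replacement from the in-bag non-missing values of that variable
within the node (re-drawn at every node).

Everything is deterministic given ``(data, params, seed)``: per-tree random
streams are spawned from a single :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import ceil, sqrt
from typing import Sequence

import numpy as np

__all__ = [
    "ForestParams",
    "Tree",
    "Forest",
    "draw_bootstrap",
    "select_pseudo_responses",
    "split_statistic",
    "best_split",
    "grow_tree",
    "grow_forest",
]


@dataclass(frozen=True)
class ForestParams:
    """Tuning parameters for forest growth.

    ``mtry`` and ``q_pseudo`` default to ceil(sqrt(p)) when left as None;
    ``nodesize`` is the minimum in-bag size a node must *exceed twice* to be
    split further (terminals may be smaller). ``n_trees`` defaults to the
    method's standard 1000 trees.
    """

    n_trees: int = 1000
    mtry: int | None = None
    q_pseudo: int | None = None
    nodesize: int = 5
    max_depth: int | None = None
    seed: int = 0
    unsupervised_mode: str = "pseudo_response"  # or "synthetic_contrast"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if self.unsupervised_mode not in ("pseudo_response", "synthetic_contrast"):
            raise ValueError(f"unknown unsupervised_mode {self.unsupervised_mode!r}")

    def resolve(self, p: int) -> tuple[int, int]:
        """Concrete (mtry, q_pseudo) for a dataset with ``p`` variables."""
        default = min(p, ceil(sqrt(p)))
        mtry = default if self.mtry is None else min(self.mtry, p)
        q = default if self.q_pseudo is None else min(self.q_pseudo, p)
        if mtry < 1 or q < 1:
            raise ValueError("mtry and q_pseudo must be >= 1")
        return mtry, q


@dataclass
class Tree:
    """A recursive-partitioning tree stored as flat node arrays.

    ``split_var[i] == -1`` marks node ``i`` terminal; children of terminals
    are -1 and their split values NaN. ``inbag_terminal`` / ``oob_terminal``
    map each case to the terminal holding it (or -1): every case lands in
    exactly one terminal, as an in-bag member (with multiplicity
    ``inbag_count``) or as an out-of-bag (OOB) member.
    """

    split_var: np.ndarray
    split_value: np.ndarray
    left: np.ndarray
    right: np.ndarray
    depth: np.ndarray
    inbag_terminal: np.ndarray
    oob_terminal: np.ndarray
    inbag_count: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.split_var)

    @property
    def n_cases(self) -> int:
        return len(self.inbag_terminal)

    def is_terminal(self, node: int) -> bool:
        return self.split_var[node] < 0

    def inbag_members(self, node: int) -> np.ndarray:
        return np.nonzero(self.inbag_terminal == node)[0]

    def oob_members(self, node: int) -> np.ndarray:
        return np.nonzero(self.oob_terminal == node)[0]

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "node_id": i,
                    "depth": int(self.depth[i]),
                    "split_var": None if self.split_var[i] < 0 else int(self.split_var[i]),
                    "split_value": None if self.split_var[i] < 0 else float(self.split_value[i]),
                    "left": None if self.left[i] < 0 else int(self.left[i]),
                    "right": None if self.right[i] < 0 else int(self.right[i]),
                }
                for i in range(self.n_nodes)
            ],
            "inbag_terminal": self.inbag_terminal.tolist(),
            "oob_terminal": self.oob_terminal.tolist(),
            "inbag_count": self.inbag_count.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        nodes = d["nodes"]
        n = len(nodes)
        sv = np.full(n, -1, dtype=np.int64)
        sx = np.full(n, np.nan)
        lt = np.full(n, -1, dtype=np.int64)
        rt = np.full(n, -1, dtype=np.int64)
        dp = np.zeros(n, dtype=np.int64)
        for rec in nodes:
            i = rec["node_id"]
            dp[i] = rec["depth"]
            if rec["split_var"] is not None:
                sv[i] = rec["split_var"]
                sx[i] = rec["split_value"]
                lt[i] = rec["left"]
                rt[i] = rec["right"]
        return cls(
            split_var=sv,
            split_value=sx,
            left=lt,
            right=rt,
            depth=dp,
            inbag_terminal=np.asarray(d["inbag_terminal"], dtype=np.int64),
            oob_terminal=np.asarray(d["oob_terminal"], dtype=np.int64),
            inbag_count=np.asarray(d["inbag_count"], dtype=np.int64),
        )

    @classmethod
    def from_json(cls, s: str) -> "Tree":
        return cls.from_dict(json.loads(s))


@dataclass
class Forest:
    trees: list[Tree]
    params: ForestParams
    bootstrap_indices: list[np.ndarray] = field(repr=False, default_factory=list)
    rng_seed: int = 0
    n_cases: int = 0
    n_vars: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def draw_bootstrap(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw a bootstrap multiset of size ``n`` and its OOB complement.

    The expected OOB fraction is (1 - 1/n)^n, about 37% for large n.
    """
    if n < 1:
        raise ValueError("need at least one case to bootstrap")
    inbag = rng.integers(0, n, size=n)
    present = np.zeros(n, dtype=bool)
    present[inbag] = True
    oob = np.nonzero(~present)[0]
    return inbag, oob


def select_pseudo_responses(p: int, q: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform without-replacement draw of ``q`` pseudo-response variables."""
    if not 1 <= q <= p:
        raise ValueError(f"q must be in [1, p]; got q={q}, p={p}")
    return np.sort(rng.choice(p, size=q, replace=False))


def split_statistic(node_values: np.ndarray, is_left: np.ndarray) -> float:
    """Within-daughter sum of squares D_q for a proposed split.

    ``node_values`` is the (cases x q) pseudo-response matrix at the node;
    ``is_left`` a boolean daughter assignment. NaN entries (missing values)
    are discarded. Zero iff every pseudo-response is constant within each
    daughter.
    """
    node_values = np.asarray(node_values, dtype=float)
    if node_values.ndim == 1:
        node_values = node_values[:, None]
    is_left = np.asarray(is_left, dtype=bool)
    if is_left.all() or not is_left.any():
        raise ValueError("both daughter nodes must be non-empty")
    total = 0.0
    for side in (is_left, ~is_left):
        vals = node_values[side]
        mask = ~np.isnan(vals)
        cnt = mask.sum(axis=0)
        v0 = np.where(mask, vals, 0.0)
        s = v0.sum(axis=0)
        ss = (v0 * v0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            within = ss - np.where(cnt > 0, s * s / np.maximum(cnt, 1), 0.0)
        total += float(np.where(cnt > 0, within, 0.0).sum())
    return max(total, 0.0)


def _scan_variable(
    x: np.ndarray, y0: np.ndarray, ysq: np.ndarray, ymask: np.ndarray
) -> tuple[float, float] | None:
    """Best split of one candidate variable at a node.

    ``x`` holds the in-bag node values of the variable (may contain NaN,
    which are discarded); ``y0``/``ysq``/``ymask`` are the node
    pseudo-responses with NaN zeroed, their squares, and the observedness
    mask. Considers midpoints between consecutive distinct observed values
    and returns (D_q, split_value) for the minimizing one, lowest split
    value on ties; None if fewer than two distinct observed values.
    """
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        return None
    xo = x[obs]
    order = np.argsort(xo, kind="stable")
    xs = xo[order]
    boundary = np.nonzero(xs[1:] != xs[:-1])[0]
    if boundary.size == 0:
        return None
    yo = y0[obs][order]
    ysqo = ysq[obs][order]
    mo = ymask[obs][order]
    cs = np.cumsum(yo, axis=0)
    css = np.cumsum(ysqo, axis=0)
    cm = np.cumsum(mo, axis=0)
    n_l = cm[boundary]
    s_l = cs[boundary]
    ss_l = css[boundary]
    n_r = cm[-1] - n_l
    s_r = cs[-1] - s_l
    ss_r = css[-1] - ss_l
    with np.errstate(invalid="ignore", divide="ignore"):
        within = (
            ss_l
            - np.where(n_l > 0, s_l * s_l / np.maximum(n_l, 1), 0.0)
            + ss_r
            - np.where(n_r > 0, s_r * s_r / np.maximum(n_r, 1), 0.0)
        )
    d = within.sum(axis=1)
    j = int(np.argmin(d))  # first minimum -> lowest split value
    split_value = 0.5 * (xs[boundary[j]] + xs[boundary[j] + 1])
    return max(float(d[j]), 0.0), float(split_value)


def best_split(
    data: np.ndarray,
    cases: np.ndarray,
    candidate_vars: Sequence[int],
    response_set: Sequence[int],
) -> tuple[int, float] | None:
    """Minimize D_q over candidate variables and their midpoint splits.

    ``cases`` indexes the node's in-bag members (multiset). Ties are broken
    toward the lowest variable index, then the lowest split value. Returns
    None when no candidate variable has two distinct observed values.
    """
    y = data[np.ix_(cases, np.asarray(response_set, dtype=np.intp))]
    ymask = ~np.isnan(y)
    y0 = np.where(ymask, y, 0.0)
    ysq = y0 * y0
    best: tuple[float, int, float] | None = None
    for var in sorted(int(v) for v in candidate_vars):
        res = _scan_variable(data[cases, var], y0, ysq, ymask)
        if res is None:
            continue
        d, s = res
        if best is None or d < best[0]:
            best = (d, var, s)
    if best is None:
        return None
    return best[1], best[2]


def _route_fill(
    x: np.ndarray, case_ids: np.ndarray, pool: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Fill NaNs of ``x`` with per-case random draws from ``pool``.

    All bootstrap copies of the same case receive the same draw, so a case
    lands in exactly one terminal.
    """
    miss = np.isnan(x)
    if not miss.any():
        return x
    filled = x.copy()
    uniq, inverse = np.unique(case_ids[miss], return_inverse=True)
    draws = rng.choice(pool, size=uniq.size, replace=True)
    filled[miss] = draws[inverse]
    return filled


def grow_tree(
    data: np.ndarray,
    params: ForestParams,
    inbag: np.ndarray,
    oob: np.ndarray,
    rng: np.random.Generator,
) -> Tree:
    """Grow one unsupervised multivariate tree.

    Per node: draw fresh pseudo-responses, draw ``mtry`` candidate split
    variables, pick the D_q-minimizing split, and route cases; cases missing
    the split variable are routed by a random draw from the node's in-bag
    non-missing values of that variable (OOB cases are routed by the same
    rule). Stops on nodesize, max_depth, or when no valid split exists.
    """
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    if n < 1 or p < 2:
        raise ValueError("data must have >= 1 case and >= 2 variables")
    mtry, q = params.resolve(p)
    has_nan = bool(np.isnan(data).any())

    split_var: list[int] = []
    split_value: list[float] = []
    left: list[int] = []
    right: list[int] = []
    depth: list[int] = []
    inbag_terminal = np.full(n, -1, dtype=np.int64)
    oob_terminal = np.full(n, -1, dtype=np.int64)
    inbag_count = np.bincount(inbag, minlength=n).astype(np.int64)

    def new_node(d: int) -> int:
        split_var.append(-1)
        split_value.append(np.nan)
        left.append(-1)
        right.append(-1)
        depth.append(d)
        return len(split_var) - 1

    # Recursion via explicit stack; children are processed left-first so node
    # ids come out in preorder and the rng call order is reproducible.
    root = new_node(0)
    stack: list[tuple[int, int, np.ndarray, np.ndarray]] = [(root, 0, inbag, oob)]
    while stack:
        nid, d, ib, ob = stack.pop()
        make_terminal = ib.size < 2 * params.nodesize or (
            params.max_depth is not None and d >= params.max_depth
        )
        chosen = None
        if not make_terminal:
            responses = select_pseudo_responses(p, q, rng)
            cand = np.sort(rng.choice(p, size=mtry, replace=False))
            chosen = best_split(data, ib, cand, responses)
        if chosen is None:
            inbag_terminal[np.unique(ib)] = nid
            if ob.size:
                oob_terminal[ob] = nid
            continue
        var, s = chosen
        x_ib = data[ib, var]
        if has_nan:
            pool = x_ib[~np.isnan(x_ib)]
            x_ib = _route_fill(x_ib, ib, pool, rng)
            x_ob = _route_fill(data[ob, var], ob, pool, rng) if ob.size else data[ob, var]
        else:
            x_ob = data[ob, var]
        go_left_ib = x_ib <= s
        go_left_ob = x_ob <= s
        split_var[nid] = var
        split_value[nid] = s
        lid = new_node(d + 1)
        rid = new_node(d + 1)
        left[nid] = lid
        right[nid] = rid
        # push right first so the left child is processed (and numbered) first
        stack.append((rid, d + 1, ib[~go_left_ib], ob[~go_left_ob]))
        stack.append((lid, d + 1, ib[go_left_ib], ob[go_left_ob]))
        # note: preorder numbering requires children created in order; ids for
        # both were just allocated, so processing order only affects rng use.

    return Tree(
        split_var=np.asarray(split_var, dtype=np.int64),
        split_value=np.asarray(split_value, dtype=float),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        depth=np.asarray(depth, dtype=np.int64),
        inbag_terminal=inbag_terminal,
        oob_terminal=oob_terminal,
        inbag_count=inbag_count,
    )


def _synthetic_contrast_data(
    data: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Augment rows with column-wise marginal redraws plus an indicator.

    The returned matrix stacks the real cases over an equal number of
    synthetic cases whose columns are drawn independently from the real
    columns' marginals; the last column is the real/synthetic indicator used
    as the regression target.
    """
    n, p = data.shape
    synth = np.column_stack([rng.choice(data[:, j], size=n, replace=True) for j in range(p)])
    aug = np.vstack([data, synth])
    indicator = np.concatenate([np.ones(n), np.zeros(n)])
    return np.column_stack([aug, indicator]), indicator


def _grow_contrast_tree(
    data: np.ndarray, params: ForestParams, rng: np.random.Generator
) -> Tree:
    n = data.shape[0]
    aug, _ = _synthetic_contrast_data(data, rng)
    p = data.shape[1]
    mtry, _ = params.resolve(p)
    inner = replace(
        params,
        mtry=mtry,
        q_pseudo=1,
        unsupervised_mode="pseudo_response",
    )
    inbag, oob = draw_bootstrap(2 * n, rng)
    tree = _grow_tree_fixed_response(aug, inner, inbag, oob, rng, response=p, n_split_vars=p)
    # keep terminal membership for real cases only
    tree.inbag_terminal = tree.inbag_terminal[:n]
    tree.oob_terminal = tree.oob_terminal[:n]
    tree.inbag_count = tree.inbag_count[:n]
    return tree


def _grow_tree_fixed_response(
    data: np.ndarray,
    params: ForestParams,
    inbag: np.ndarray,
    oob: np.ndarray,
    rng: np.random.Generator,
    response: int,
    n_split_vars: int,
) -> Tree:
    """Variant of grow_tree with a fixed single response column and a
    restricted candidate-variable range (used by the synthetic-contrast
    mode). Shares the split search and routing machinery."""
    n, _ = data.shape
    mtry = min(params.resolve(n_split_vars)[0], n_split_vars)

    split_var: list[int] = []
    split_value: list[float] = []
    left: list[int] = []
    right: list[int] = []
    depth: list[int] = []
    inbag_terminal = np.full(n, -1, dtype=np.int64)
    oob_terminal = np.full(n, -1, dtype=np.int64)
    inbag_count = np.bincount(inbag, minlength=n).astype(np.int64)

    def new_node(d: int) -> int:
        split_var.append(-1)
        split_value.append(np.nan)
        left.append(-1)
        right.append(-1)
        depth.append(d)
        return len(split_var) - 1

    root = new_node(0)
    stack = [(root, 0, inbag, oob)]
    while stack:
        nid, d, ib, ob = stack.pop()
        make_terminal = ib.size < 2 * params.nodesize or (
            params.max_depth is not None and d >= params.max_depth
        )
        chosen = None
        if not make_terminal:
            cand = np.sort(rng.choice(n_split_vars, size=mtry, replace=False))
            chosen = best_split(data, ib, cand, [response])
        if chosen is None:
            inbag_terminal[np.unique(ib)] = nid
            if ob.size:
                oob_terminal[ob] = nid
            continue
        var, s = chosen
        go_left_ib = data[ib, var] <= s
        go_left_ob = data[ob, var] <= s
        split_var[nid] = var
        split_value[nid] = s
        lid = new_node(d + 1)
        rid = new_node(d + 1)
        left[nid] = lid
        right[nid] = rid
        stack.append((rid, d + 1, ib[~go_left_ib], ob[~go_left_ob]))
        stack.append((lid, d + 1, ib[go_left_ib], ob[go_left_ob]))

    return Tree(
        split_var=np.asarray(split_var, dtype=np.int64),
        split_value=np.asarray(split_value, dtype=float),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        depth=np.asarray(depth, dtype=np.int64),
        inbag_terminal=inbag_terminal,
        oob_terminal=oob_terminal,
        inbag_count=inbag_count,
    )


def grow_forest(data: np.ndarray, params: ForestParams) -> Forest:
    """Grow ``params.n_trees`` trees from independent bootstraps.

    Per-tree random streams are spawned deterministically from
    ``params.seed``, so forests are bit-identical across reruns.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    trees: list[Tree] = []
    bootstraps: list[np.ndarray] = []
    children = np.random.SeedSequence(params.seed).spawn(params.n_trees)
    for ss in children:
        rng = np.random.Generator(np.random.PCG64(ss))
        if params.unsupervised_mode == "synthetic_contrast":
            if np.isnan(data).any():
                raise ValueError("synthetic_contrast mode requires complete data")
            tree = _grow_contrast_tree(data, params, rng)
            bootstraps.append(np.nonzero(tree.inbag_count)[0])
        else:
            inbag, oob = draw_bootstrap(n, rng)
            tree = grow_tree(data, params, inbag, oob, rng)
            bootstraps.append(inbag)
        trees.append(tree)
    return Forest(
        trees=trees,
        params=params,
        bootstrap_indices=bootstraps,
        rng_seed=params.seed,
        n_cases=n,
        n_vars=data.shape[1],
    )
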