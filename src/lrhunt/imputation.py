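"""Interaction-space assembly and random-forest missing-data imputation.

To study ligand-receptor interactions between sender cells (type A,
providing ligand gene columns) and receiver cells (type B, receptor
columns), the two expression matrices are stacked into a single
(n_A + n_B) x (p_A + p_B) *interaction space* whose two off-blocks —
A-cells x receptor-columns and B-cells x ligand-columns — are structurally
missing: no cell was measured on the other type's genes.

The missing blocks are completed with on-the-fly random-forest imputation:
an unsupervised multivariate forest is grown directly on the incomplete
matrix (missing values are discarded from split statistics and routed by
in-node random draws), and each missing entry is then imputed as the
tree-averaged mean of out-of-bag (OOB) non-missing values of that gene in
the case's terminal node, with per-tree fallbacks to in-bag terminal values
and finally the column's observed mean. Repeating the procedure M times
with different seeds yields multiple imputations whose downstream indices
are aggregated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .forest_core import ForestParams, grow_forest
from .lr_database import LRPairTable

__all__ = [
    "ExpressionMatrix",
    "InteractionSpaceMatrix",
    "ImputedDataset",
    "assemble_interaction_space",
    "rf_impute",
    "multiple_impute",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Cells x genes normalized expression for one cell type."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_type: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (cells x genes)")
        n, p = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != p:
            raise ValueError("cell_ids/gene_ids lengths must match the matrix")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from {self.cell_type or 'matrix'}: {missing}")
        return np.asarray([lookup[g] for g in genes], dtype=np.intp)


@dataclass
class InteractionSpaceMatrix:
    """Stacked cross-cell-type matrix with block missingness.

    Rows: A cells then B cells; columns: ligand genes (from A) then receptor
    genes (from B). ``values`` holds NaN where ``missing_mask`` is True —
    exactly the two off-blocks.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    row_block: np.ndarray  # 'A' / 'B' per row
    col_block: np.ndarray  # 'ligand' / 'receptor' per column
    gene_ids: list[str]
    cell_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_a(self) -> int:
        return int((self.row_block == "A").sum())

    @property
    def p_ligand(self) -> int:
        return int((self.col_block == "ligand").sum())

    def ligand_columns(self) -> np.ndarray:
        return np.nonzero(self.col_block == "ligand")[0]

    def receptor_columns(self) -> np.ndarray:
        return np.nonzero(self.col_block == "receptor")[0]


@dataclass
class ImputedDataset:
    """A completed interaction-space matrix (imputation m of M)."""

    values: np.ndarray
    imputation_index: int
    seed: int


def assemble_interaction_space(
    x_a: ExpressionMatrix, x_b: ExpressionMatrix, pairs: LRPairTable
) -> InteractionSpaceMatrix:
    """Stack sender ligand columns and receiver receptor columns.

    Ligand columns are the unique ligand genes of ``pairs`` taken from
    ``x_a``; receptor columns the unique receptor genes from ``x_b``. The
    off-blocks are masked missing. A gene appearing on both sides keeps two
    role-suffixed column ids rather than being merged.
    """
    ligands = pairs.ligands
    receptors = pairs.receptors
    la = x_a.values[:, x_a.gene_index(ligands)]
    rb = x_b.values[:, x_b.gene_index(receptors)]
    n_a, n_b = x_a.n_cells, x_b.n_cells
    p_l, p_r = len(ligands), len(receptors)
    values = np.full((n_a + n_b, p_l + p_r), np.nan)
    values[:n_a, :p_l] = la
    values[n_a:, p_l:] = rb
    mask = np.zeros_like(values, dtype=bool)
    mask[:n_a, p_l:] = True
    mask[n_a:, :p_l] = True
    overlap = set(ligands) & set(receptors)
    gene_ids = [f"{g}::ligand" if g in overlap else g for g in ligands] + [
        f"{g}::receptor" if g in overlap else g for g in receptors
    ]
    cell_ids = list(x_a.cell_ids) + list(x_b.cell_ids)
    if len(set(cell_ids)) != len(cell_ids):
        cell_ids = [f"A:{c}" for c in x_a.cell_ids] + [f"B:{c}" for c in x_b.cell_ids]
    row_block = np.array(["A"] * n_a + ["B"] * n_b)
    col_block = np.array(["ligand"] * p_l + ["receptor"] * p_r)
    return InteractionSpaceMatrix(
        values=values,
        missing_mask=mask,
        row_block=row_block,
        col_block=col_block,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
    )


def rf_impute(
    ism: InteractionSpaceMatrix, params: ForestParams, seed: int, imputation_index: int = 1
) -> ImputedDataset:
    """Complete the missing blocks with one forest imputation pass.

    Grows an unsupervised forest on the incomplete matrix, then imputes each
    missing entry (case i, gene g) as the average over trees of the mean of
    OOB non-missing g-values in i's terminal node; per tree the fallback
    chain is OOB -> in-bag terminal values -> overall observed column mean.
    Observed entries pass through unchanged.
    """
    x = np.where(ism.missing_mask, np.nan, ism.values)
    obs_per_col = (~np.isnan(x)).sum(axis=0)
    if (obs_per_col == 0).any():
        bad = [ism.gene_ids[j] for j in np.nonzero(obs_per_col == 0)[0]]
        raise ValueError(f"columns with no observed values cannot be imputed: {bad}")
    obs_per_row = (~np.isnan(x)).sum(axis=1)
    if (obs_per_row == 0).any():
        raise ValueError("rows with no observed values cannot be imputed")
    if not ism.missing_mask.any():
        return ImputedDataset(values=x.copy(), imputation_index=imputation_index, seed=seed)

    forest = grow_forest(x, replace(params, seed=seed))
    miss_r, miss_c = np.nonzero(ism.missing_mask)
    col_mean = np.nanmean(x, axis=0)
    obs_mask = ~np.isnan(x)
    x0 = np.where(obs_mask, x, 0.0)
    acc = np.zeros(miss_r.size)
    n_fallback_inbag = 0
    n_fallback_colmean = 0
    n_nodes_max = max(t.n_nodes for t in forest.trees)
    for tree in forest.trees:
        term_all = np.where(tree.inbag_terminal >= 0, tree.inbag_terminal, tree.oob_terminal)
        s_oob = np.zeros((n_nodes_max, x.shape[1]))
        c_oob = np.zeros((n_nodes_max, x.shape[1]))
        oob_cases = np.nonzero(tree.oob_terminal >= 0)[0]
        if oob_cases.size:
            nodes = tree.oob_terminal[oob_cases]
            np.add.at(s_oob, nodes, x0[oob_cases])
            np.add.at(c_oob, nodes, obs_mask[oob_cases].astype(float))
        s_in = np.zeros((n_nodes_max, x.shape[1]))
        c_in = np.zeros((n_nodes_max, x.shape[1]))
        ib_cases = np.nonzero(tree.inbag_terminal >= 0)[0]
        w = tree.inbag_count[ib_cases].astype(float)[:, None]
        np.add.at(s_in, tree.inbag_terminal[ib_cases], x0[ib_cases] * w)
        np.add.at(c_in, tree.inbag_terminal[ib_cases], obs_mask[ib_cases] * w)
        node_of = term_all[miss_r]
        co = c_oob[node_of, miss_c]
        ci = c_in[node_of, miss_c]
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(
                co > 0,
                s_oob[node_of, miss_c] / np.maximum(co, 1e-300),
                np.where(
                    ci > 0,
                    s_in[node_of, miss_c] / np.maximum(ci, 1e-300),
                    col_mean[miss_c],
                ),
            )
        n_fallback_inbag += int(((co == 0) & (ci > 0)).sum())
        n_fallback_colmean += int(((co == 0) & (ci == 0)).sum())
        acc += v
    logger.debug(
        "rf_impute seed=%d: fallbacks per tree-entry: inbag=%d colmean=%d",
        seed,
        n_fallback_inbag,
        n_fallback_colmean,
    )
    out = x.copy()
    out[miss_r, miss_c] = acc / forest.n_trees
    return ImputedDataset(values=out, imputation_index=imputation_index, seed=seed)


def multiple_impute(
    ism: InteractionSpaceMatrix,
    m: int,
    base_seed: int,
    params: ForestParams | None = None,
) -> list[ImputedDataset]:
    """M independent imputations with seeds derived from ``base_seed``."""
    if m < 1:
        raise ValueError("M must be >= 1")
    params = params or ForestParams()
    seeds = [
        int(ss.generate_state(1)[0] % (2**31))
        for ss in np.random.SeedSequence(base_seed).spawn(m)
    ]
    return [
        rf_impute(ism, params, seed=s, imputation_index=i + 1)
        for i, s in enumerate(seeds)
    ]
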