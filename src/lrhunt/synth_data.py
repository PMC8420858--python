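"""Synthetic two-cell-type expression data with planted LR interactions.

The generator emulates *post-normalization* expression structure: each
planted ligand-receptor pair k is driven by a latent activity factor z_k
with an independent standard-normal realization per cell in both
populations; the ligand gene (sender type A) and the receptor gene
(receiver type B) load on their factor with strength beta on top of
Gaussian noise. A few *context* genes per block also load on the factors —
these are the cross-block informative columns the imputation stage needs —
and the remaining genes are independent noise. An optional
lognormal-count layer draws Poisson counts with rate exp(x) and
log-normalizes them, roughly mimicking library-size-normalized counts.

Also provides deterministic tree fixtures for the depth statistics and a
block-masking helper so imputation accuracy can be scored against withheld
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forest_core import Tree
from .imputation import ExpressionMatrix, InteractionSpaceMatrix
from .lr_database import LRPairTable

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_dataset",
    "make_worked_example_tree",
    "generate_block_missing",
    "recovery_auc",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: two populations of 200 cells, 20 genes each, 5 planted pairs
    with loading beta=2 over unit noise, 5 context genes per block.
    """

    n_a: int = 200
    n_b: int = 200
    p_a: int = 20
    p_b: int = 20
    n_planted: int = 5
    n_context: int = 5
    effect: float = 2.0
    noise_sd: float = 1.0
    count_model: str = "gaussian"  # or "lognormal-counts"
    seed: int = 0
    n_null_pairs: int | None = None  # None -> all p_a x p_b candidates

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.p_a, self.p_b, self.n_planted) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_planted > min(self.p_a, self.p_b):
            raise ValueError("n_planted must be <= min(p_a, p_b)")
        if self.n_planted + self.n_context > min(self.p_a, self.p_b):
            raise ValueError("planted + context genes exceed gene count")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.count_model not in ("gaussian", "lognormal-counts"):
            raise ValueError(f"unknown count_model {self.count_model!r}")


@dataclass
class SynthTruth:
    planted_pairs: list[tuple[str, str]]
    factors_a: np.ndarray
    factors_b: np.ndarray
    config: SynthConfig
    complete_interaction_space: np.ndarray | None = field(default=None, repr=False)


def _block(
    rng: np.random.Generator,
    n: int,
    p: int,
    k: int,
    n_context: int,
    beta: float,
    sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One population: k driven genes, n_context context genes, noise rest."""
    z = rng.normal(size=(n, k))
    x = rng.normal(scale=sigma, size=(n, p))
    x[:, :k] += beta * z
    for j in range(n_context):
        x[:, k + j] += beta * z[:, j % k]
    return x, z


def generate_dataset(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, LRPairTable, SynthTruth]:
    """Generate (X_A, X_B, candidate pair table, truth) per the config.

    Candidate pairs are the full p_a x p_b cross product by default
    (``n_null_pairs`` restricts the null part to a random subset drawn from
    the noise genes). Planted pairs are always included.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_planted
    xa, za = _block(
        rng, config.n_a, config.p_a, k, config.n_context, config.effect, config.noise_sd
    )
    xb, zb = _block(
        rng, config.n_b, config.p_b, k, config.n_context, config.effect, config.noise_sd
    )
    if config.count_model == "lognormal-counts":
        from .cli_io import log_normalize

        xa = log_normalize(rng.poisson(np.exp(xa)).astype(float) + 1e-9, scale=1e4)
        xb = log_normalize(rng.poisson(np.exp(xb)).astype(float) + 1e-9, scale=1e4)

    genes_a = (
        [f"LG{i + 1}" for i in range(k)]
        + [f"CTXA{i + 1}" for i in range(config.n_context)]
        + [f"NSA{i + 1}" for i in range(config.p_a - k - config.n_context)]
    )
    genes_b = (
        [f"RC{i + 1}" for i in range(k)]
        + [f"CTXB{i + 1}" for i in range(config.n_context)]
        + [f"NSB{i + 1}" for i in range(config.p_b - k - config.n_context)]
    )
    x_a = ExpressionMatrix(
        values=xa,
        cell_ids=[f"A{i + 1}" for i in range(config.n_a)],
        gene_ids=genes_a,
        cell_type="A",
    )
    x_b = ExpressionMatrix(
        values=xb,
        cell_ids=[f"B{i + 1}" for i in range(config.n_b)],
        gene_ids=genes_b,
        cell_type="B",
    )
    planted = [(f"LG{i + 1}", f"RC{i + 1}") for i in range(k)]
    if config.n_null_pairs is None:
        candidates = [(ga, gb) for ga in genes_a for gb in genes_b]
    else:
        noise_a = genes_a[k + config.n_context :]
        noise_b = genes_b[k + config.n_context :]
        combos = [(ga, gb) for ga in noise_a for gb in noise_b]
        take = min(config.n_null_pairs, len(combos))
        idx = rng.choice(len(combos), size=take, replace=False)
        candidates = planted + [combos[i] for i in sorted(idx)]
    pair_table = LRPairTable(pairs=candidates, source_tag="synthetic")
    truth = SynthTruth(
        planted_pairs=planted, factors_a=za, factors_b=zb, config=config
    )
    return x_a, x_b, pair_table, truth


def make_worked_example_tree() -> Tree:
    """Deterministic fixture tree for the maximal-subtree worked example.

    Variables: h=0, v=1, w=2, u=3. The root splits on h; its left child is a
    maximal v-subtree of depth 1 (terminals 1, 2, no w inside) and its right
    child a maximal v-subtree of depth m=3 (terminals 3-6) containing a
    maximal w-subtree whose root sits at depth d=2 inside it, so the
    normalized pairwise depth of w in that subtree is d/m = 2/3. The maximal
    h-subtree is the entire tree.
    """
    #            0:h
    #        /         \
    #      1:v          2:v
    #     /   \        /   \
    #   t(3) t(4)   t(5)   6:u
    #                      /  \
    #                   t(7)  8:w
    #                         /  \
    #                      t(9) t(10)
    split_var = np.array([0, 1, 1, -1, -1, -1, 3, -1, 2, -1, -1], dtype=np.int64)
    split_value = np.where(split_var >= 0, 0.0, np.nan)
    left = np.array([1, 3, 5, -1, -1, -1, 7, -1, 9, -1, -1], dtype=np.int64)
    right = np.array([2, 4, 6, -1, -1, -1, 8, -1, 10, -1, -1], dtype=np.int64)
    depth = np.array([0, 1, 1, 2, 2, 2, 2, 3, 3, 4, 4], dtype=np.int64)
    return Tree(
        split_var=split_var,
        split_value=split_value,
        left=left,
        right=right,
        depth=depth,
        inbag_terminal=np.zeros(0, dtype=np.int64),
        oob_terminal=np.zeros(0, dtype=np.int64),
        inbag_count=np.zeros(0, dtype=np.int64),
    )


def generate_block_missing(
    complete_matrix: np.ndarray, n_a: int, p_a: int
) -> InteractionSpaceMatrix:
    """Mask a complete (n_a+n_b) x (p_a+p_b) matrix to the two-block pattern.

    Test helper: the caller keeps ``complete_matrix`` as withheld truth so
    imputation accuracy on the masked entries is measurable.
    """
    complete_matrix = np.asarray(complete_matrix, dtype=float)
    n, p = complete_matrix.shape
    if not (0 < n_a < n and 0 < p_a < p):
        raise ValueError("n_a and p_a must split the matrix into four blocks")
    mask = np.zeros((n, p), dtype=bool)
    mask[:n_a, p_a:] = True
    mask[n_a:, :p_a] = True
    values = np.where(mask, np.nan, complete_matrix)
    return InteractionSpaceMatrix(
        values=values,
        missing_mask=mask,
        row_block=np.array(["A"] * n_a + ["B"] * (n - n_a)),
        col_block=np.array(["ligand"] * p_a + ["receptor"] * (p - p_a)),
        gene_ids=[f"g{j}" for j in range(p)],
        cell_ids=[f"c{i}" for i in range(n)],
    )


def recovery_auc(result, planted_pairs: list[tuple[str, str]]) -> float:
    """AUC for recovering planted pairs from an LR result table.

    Probability that a planted pair scores a *smaller* interaction index
    than a null pair (Mann-Whitney U on the aggregated index, ties counted
    half).
    """
    import pandas as pd
    from scipy.stats import rankdata

    df: pd.DataFrame = result if isinstance(result, pd.DataFrame) else result.frame
    planted = set(planted_pairs)
    labels = np.array(
        [(l, r) in planted for l, r in zip(df["ligand"], df["receptor"])]
    )
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both planted and null pairs to compute AUC")
    # smaller index = stronger, so rank the negated index
    r = rankdata(-df["imdi"].to_numpy())
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
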