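"""End-to-end LR hunting: impute, grow forests, score, aggregate, rank.

For each of M imputed interaction-space datasets, an unsupervised
multivariate forest is grown on the completed matrix and the normalized
pairwise minimal-depth index I_(m)(S) is computed for every candidate
ligand-receptor pair S. The aggregated index is the mean over imputations,

    I(S) = (1/M) * sum_m I_(m)(S),

and significance is assessed against the empirical distribution of I(S)
over the candidate-pair ensemble (left tail: smaller index = stronger
interaction). Direction matters: ligands of A against receptors of B is one
run; the reverse direction is a separate run with the roles swapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import sqrt

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .depth_stats import forest_pair_depth
from .forest_core import ForestParams, grow_forest
from .imputation import (
    ExpressionMatrix,
    assemble_interaction_space,
    multiple_impute,
)
from .lr_database import LRPairTable, filter_to_expressed

__all__ = [
    "RunConfig",
    "LRResultTable",
    "lr_hunting",
    "per_imputation_imdi",
    "aggregate_imdi",
    "empirical_pvalues",
    "rank_table",
    "sum_ranks_across_samples",
    "lr_score",
    "compare_rankings",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full LR hunting run.

    ``m_imputations`` defaults to 20, past which the aggregated index is
    stable; both forest stages default to 1000 trees.
    """

    m_imputations: int = 20
    imputation_params: ForestParams = field(default_factory=ForestParams)
    detection_params: ForestParams = field(default_factory=ForestParams)
    normalization: str = "dm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_imputations < 1:
            raise ValueError("M must be >= 1")
        if self.normalization not in ("dm", "cdf"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class LRResultTable:
    """Ranked LR pairs: aggregated index, empirical p, rank (1 = strongest)."""

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def rank_of(self) -> dict[tuple[str, str], int]:
        return {
            (l, r): int(k)
            for l, r, k in zip(
                self.frame["ligand"], self.frame["receptor"], self.frame["rank"]
            )
        }


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def per_imputation_imdi(
    imputed_values: np.ndarray,
    ism,
    pairs: LRPairTable,
    params: ForestParams,
    normalization: str = "dm",
) -> dict[tuple[str, str], float]:
    """Grow one detection forest on a completed matrix and extract the
    normalized pair-depth index for every candidate pair."""
    forest = grow_forest(imputed_values, params)
    pdm = forest_pair_depth(
        forest, np.arange(imputed_values.shape[1]), normalization=normalization
    )
    lig_cols = {g: j for j, g in enumerate(ism.gene_ids) if ism.col_block[j] == "ligand"}
    rec_cols = {g: j for j, g in enumerate(ism.gene_ids) if ism.col_block[j] == "receptor"}

    def col(g: str, table: dict[str, int], role: str) -> int:
        if g in table:
            return table[g]
        return table[f"{g}::{role}"]

    return {
        (l, r): float(pdm.values[col(l, lig_cols, "ligand"), col(r, rec_cols, "receptor")])
        for l, r in pairs.pairs
    }


def aggregate_imdi(
    per_imputation_values: list[dict[tuple[str, str], float]],
) -> dict[tuple[str, str], float]:
    """Arithmetic mean of the per-imputation indices, pair by pair."""
    if not per_imputation_values:
        raise ValueError("need at least one imputation")
    keys = set(per_imputation_values[0])
    for d in per_imputation_values[1:]:
        if set(d) != keys:
            raise ValueError("imputation index maps must share the same pair set")
    m = len(per_imputation_values)
    return {
        k: sum(d[k] for d in per_imputation_values) / m
        for k in per_imputation_values[0]
    }


def empirical_pvalues(
    imdi: dict[tuple[str, str], float],
) -> dict[tuple[str, str], float]:
    """Left-tail empirical proportion over the candidate-pair ensemble:
    p(S) = #{S': I(S') <= I(S)} / n, so p is in (0, 1] and rank-equivalent
    to the index itself."""
    if len(imdi) < 2:
        raise ValueError("need >= 2 pairs for an empirical distribution")
    vals = np.asarray(list(imdi.values()))
    order = np.sort(vals)
    n = len(vals)
    return {
        k: float(np.searchsorted(order, v, side="right")) / n for k, v in imdi.items()
    }


def rank_table(
    imdi: dict[tuple[str, str], float],
    pvalues: dict[tuple[str, str], float],
) -> LRResultTable:
    """Sort ascending by index (stable on input order for ties), rank 1..n."""
    rows = [
        {"ligand": l, "receptor": r, "imdi": v, "pvalue": pvalues[(l, r)]}
        for (l, r), v in imdi.items()
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values("imdi", kind="mergesort", ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return LRResultTable(frame=df)


def lr_hunting(
    x_a: ExpressionMatrix,
    x_b: ExpressionMatrix,
    pairs: LRPairTable,
    config: RunConfig,
) -> LRResultTable:
    """Run the full pipeline for ligands of ``x_a`` against receptors of
    ``x_b``: assemble -> multiply impute -> per-imputation detection forest
    and pair-depth index -> aggregate -> empirical p-values -> ranked table.
    Fully deterministic given ``config.seed``."""
    pairs = filter_to_expressed(pairs, set(x_a.gene_ids), set(x_b.gene_ids))
    ism = assemble_interaction_space(x_a, x_b, pairs)
    ss_impute, ss_detect = np.random.SeedSequence(config.seed).spawn(2)
    logger.info(
        "lr_hunting: %d x %d interaction space, %d candidate pairs, M=%d",
        *ism.shape,
        len(pairs),
        config.m_imputations,
    )
    imputed = multiple_impute(
        ism, config.m_imputations, _derive_seed(ss_impute), config.imputation_params
    )
    detect_seeds = [_derive_seed(s) for s in ss_detect.spawn(config.m_imputations)]
    per_m = [
        per_imputation_imdi(
            ds.values,
            ism,
            pairs,
            replace(config.detection_params, seed=seed),
            config.normalization,
        )
        for ds, seed in zip(imputed, detect_seeds)
    ]
    imdi = aggregate_imdi(per_m)
    pvals = empirical_pvalues(imdi)
    return rank_table(imdi, pvals)


def sum_ranks_across_samples(
    tables: list[LRResultTable],
) -> dict[tuple[str, str], tuple[int, int]]:
    """Sum each pair's rank across per-sample result tables.

    A pair absent from a sample contributes that sample's max rank + 1;
    frequency counts the samples actually containing the pair. Small rank
    sums with high frequency mark consistently strong interactions.
    """
    if not tables:
        raise ValueError("need at least one result table")
    ranks = [t.rank_of() for t in tables]
    all_pairs: dict[tuple[str, str], None] = {}
    for r in ranks:
        for k in r:
            all_pairs.setdefault(k)
    out: dict[tuple[str, str], tuple[int, int]] = {}
    for pair in all_pairs:
        total = 0
        freq = 0
        for r in ranks:
            if pair in r:
                total += r[pair]
                freq += 1
            else:
                total += max(r.values()) + 1
        out[pair] = (total, freq)
    return out


def lr_score(ligand_mean: float, receptor_mean: float, mu: float) -> float:
    """Penalized LR expression product used by product-score methods:
    sqrt(l*r) / (mu + sqrt(l*r)). Monotone in l*r; for ranking comparison."""
    if ligand_mean < 0 or receptor_mean < 0:
        raise ValueError("expression means must be non-negative")
    if mu <= 0:
        raise ValueError("mu must be positive")
    g = sqrt(ligand_mean * receptor_mean)
    return g / (mu + g)


def compare_rankings(
    a: LRResultTable, b: dict[tuple[str, str], float], k: int
) -> tuple[float, float]:
    """Spearman correlation and top-k overlap between an LR hunting table and
    a strength-score table (higher score = stronger)."""
    rank_a = a.rank_of()
    shared = [p for p in rank_a if p in b]
    if not shared:
        raise ValueError("no shared pairs between the two rankings")
    ra = np.array([rank_a[p] for p in shared], dtype=float)
    # convert scores to ranks with 1 = strongest, to match the index ranks
    scores = np.array([b[p] for p in shared], dtype=float)
    rb = (-scores).argsort().argsort() + 1.0
    rho = float(spearmanr(ra, rb).statistic)
    order_a = [p for _, p in sorted(zip(ra, shared))]
    order_b = [p for _, p in sorted(zip(rb, shared))]
    overlap = len(set(order_a[:k]) & set(order_b[:k])) / k
    return rho, overlap
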