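# lrhunt

Ligand–receptor (LR) interaction discovery between two cell types from
single-cell expression data, using unsupervised random forests and
maximal-subtree minimal-depth statistics.

Most cell–cell communication tools score each LR pair in isolation (a
correlation or an expression product). `lrhunt` instead ranks all candidate
pairs *jointly* in a multivariate model, so that correlations and
higher-order interaction patterns among ligands and receptors — many
ligands competing for one receptor, shared downstream programs — inform the
ranking. It is intended for computational biologists with two annotated
cell populations (sender and receiver), normalized expression matrices, and
a curated LR pair table (e.g. a CellPhoneDB export restricted to
single-gene pairs).

## Method

Given sender expression `X^(A)` (n_A × p_A, ligand genes) and receiver
expression `X^(B)` (n_B × p_B, receptor genes):

1. **Interaction space.** Stack the matrices into an
   (n_A + n_B) × (p_A + p_B) matrix whose off-blocks (sender rows ×
   receptor columns, receiver rows × ligand columns) are structurally
   missing.
2. **Forest imputation.** Grow an unsupervised multivariate forest directly
   on the incomplete matrix. Splits minimize

       D_q(s, t) = Σ_k [ Σ_{j∈t_L}(X_jk − mean_Lk)² + Σ_{j∈t_R}(X_jk − mean_Rk)² ]

   over a fresh random set of q pseudo-response variables per node; missing
   values are discarded from the statistic and routed by in-node random
   draws. Each missing entry is imputed from out-of-bag (OOB) non-missing
   terminal-node data, averaged over trees. This is repeated M times
   (default 20) to reflect imputation uncertainty.
3. **Pairwise minimal depth.** On each completed matrix a detection forest
   is grown, and every candidate pair (v, w) is scored by the normalized
   pairwise minimal depth: within each maximal v-subtree of depth m, the
   distance d to the closest maximal w-subtree root, normalized as d/m,
   averaged over subtrees and trees and symmetrized. Variables that split
   close together interact; pairs that never co-occur score the penalty 1.
4. **Aggregation and significance.** The aggregated index is
   I(S) = (1/M) Σ_m I_(m)(S); p-values are left-tail empirical proportions
   over the p_A × p_B candidate ensemble. Smaller I(S) = stronger
   interaction.

An analytic reference distribution for minimal depths under a
balanced-tree, weak-variable model — P(D_v = s) = (1−1/p)^(2^s−1)
[1−(1−1/p)^(2^s)] and the derived pairwise-depth CDF — is available as an
alternative normalization (`normalization="cdf"`).

## Worked example

```python
from lrhunt import (ForestParams, RunConfig, SynthConfig,
                    generate_dataset, lr_hunting, recovery_auc)

cfg = SynthConfig(n_a=100, n_b=100, p_a=10, p_b=10,
                  n_planted=3, n_context=2, seed=1)
x_a, x_b, pairs, truth = generate_dataset(cfg)
fp = ForestParams(n_trees=150)
result = lr_hunting(x_a, x_b, pairs,
                    RunConfig(m_imputations=3, imputation_params=fp,
                              detection_params=fp, seed=0))
print(result.frame.head(8).to_string(index=False))
print("recovery AUC: %.3f" % recovery_auc(result, truth.planted_pairs))
```

prints

```
ligand receptor     imdi  pvalue  rank
 CTXA2      RC2 0.358961    0.01     1
   LG1      RC2 0.364247    0.02     2
   LG1    CTXB1 0.373758    0.03     3
  NSA4      RC2 0.373804    0.04     4
 CTXA2    CTXB1 0.375963    0.05     5
 CTXA1      RC1 0.378375    0.06     6
 CTXA1    CTXB1 0.378474    0.07     7
   LG2    CTXB1 0.380071    0.08     8
recovery AUC: 0.756
```

The generator plants three LR pairs (LG1–RC1, …) driven by shared latent
factors; `imdi` is the aggregated index (smaller = stronger), `pvalue` its
empirical left-tail proportion among the 100 candidates, and the AUC is the
probability that a planted pair outranks a null pair. Factor-driven genes
(LG*, RC*, CTX*) dominate the top of the table, noise pairs the bottom.

The same pipeline is scriptable from the shell:

```sh
lrhunt simulate --out-dir sim --seed 1
lrhunt run --expr expr.tsv --cells cells.tsv --pairs pairs.csv \
           --sender Myeloid --receiver Th --seed 7 --out ranked.tsv
lrhunt ranksum sample1.tsv sample2.tsv --out edges.tsv
```

`lrhunt run` ranks ligands of `--sender` against receptors of
`--receiver`; run it again with the roles swapped for the reverse
direction. `ranksum` sums per-sample ranks into a circos-ready edge list.

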