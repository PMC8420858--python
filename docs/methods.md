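# Methods

## Model and procedure

`lrhunt` treats the expression of two interacting cell types as draws from
a joint multivariate distribution over ligand and receptor genes, observed
only block-wise: sender cells reveal the ligand coordinates, receiver cells
the receptor coordinates. The pipeline has four stages.

**Interaction space.** The two matrices are stacked into one
(n_A + n_B) × (p_A + p_B) matrix with the two off-blocks missing. A gene
serving as both a ligand and a receptor column keeps two role-suffixed
columns (`G::ligand`, `G::receptor`); the blocks are never merged.

**Unsupervised forest engine.** Trees are grown from bootstrap samples
(in expectation (1 − 1/n)^n ≈ 37% of cases are out of bag). At every node a
fresh set of q pseudo-response variables is drawn and the split of a
candidate variable is chosen to minimize the within-daughter sum of squares
D_q over those pseudo-responses, evaluated at midpoints between consecutive
distinct observed values. Ties break to the lowest variable index, then the
lowest split value, making forests bit-identical given (data, params,
seed); per-tree streams are spawned from one `SeedSequence`. Missing
values are discarded from split statistics; a case missing the chosen split
variable is routed by a random draw from the node's in-bag non-missing
values of that variable, re-drawn at every node, with all bootstrap copies
of a case routed together so each case occupies exactly one terminal.
An alternative unsupervised construction (`unsupervised_mode=
"synthetic_contrast"`) augments the data with column-wise marginal redraws
and grows trees that regress the real-versus-synthetic indicator; it is a
non-default mode kept for comparison.

**Imputation.** After growing, each missing entry (case i, gene g) is the
average over trees of the mean of OOB non-missing g-values in i's terminal,
falling back per tree to in-bag terminal values and finally to the observed
column mean. The final value is a mean, not a draw: stochasticity across
the M imputations enters through bootstraps and routing seeds, which keeps
single imputations deterministic and testable. A single pass is used — one
forest per imputed dataset — with multiple imputation (M = 20 by default;
the aggregated index is stable beyond that, see the stability numbers the
acceptance script computes) supplying robustness rather than iterative
refinement.

**Pair scoring.** On each completed matrix a detection forest is grown and
scored by maximal-subtree pairwise minimal depth. Depth conventions: within
a maximal v-subtree the root has depth 0, d counts edges to the closest
maximal w-subtree root, and m counts edges on the longest root-to-terminal
path *of the v-subtree* — this reproduces d = 2, m = 3, d/m = 2/3 on the
reference geometry of `make_worked_example_tree()`. Directional observations
(v→w) are averaged per direction over their own observation counts, then
the directions with observations are averaged into a symmetric index;
pairs with no co-occurrence anywhere score the penalty 1 (absent evidence
= weakest), and the diagonal is 1 by convention. The default normalization
is d/m; `normalization="cdf"` instead evaluates the analytic CDF
P(D_{v,w} ≤ d) with tree depth l set to the subtree depth m, under the
balanced-tree weak-variable model. In that model
P(D_v = s) = (1−1/p)^(2^s−1) [1−(1−1/p)^(2^s)], because D_v > s−1 exactly
when none of the 2^s − 1 shallower nodes splits on v; the s = 0 case
reduces exactly to 1/p and is returned in that form.

Aggregation is the arithmetic mean over imputations; the empirical p-value
of pair S is the left-tail proportion #{S′ : I(S′) ≤ I(S)} / n over the
candidate ensemble (computed per direction, including S itself, so
p ∈ [1/n, 1] and the p-ordering equals the index ordering). Cross-sample
summaries sum each pair's rank across samples, charging an absent pair a
sample's max rank + 1 (configurable by construction of the input tables);
the penalized product score √(l·r)/(μ + √(l·r)) is provided purely as a
comparison baseline for ranking agreement.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 1000 | trees per forest (both stages) |
| `mtry` | ⌈√p⌉ | candidate split variables per node |
| `q_pseudo` | ⌈√p⌉ | pseudo-responses per node |
| `nodesize` | 5 | a node splits only if its in-bag size ≥ 2·nodesize |
| `max_depth` | none | optional depth cap |
| `m_imputations` | 20 | imputation replicates aggregated into I(S) |
| `normalization` | `dm` | `dm` (d/m) or `cdf` (analytic CDF) |

`mtry`, `q_pseudo` and `nodesize` follow conventional regression-forest
defaults; only the tree count and M are fixed by the method itself. All
are surfaced in `ForestParams` / `RunConfig` and on the CLI.

## Synthetic data: what it emulates and what it does not

`generate_dataset` emulates *post-normalization* expression: each planted
pair k has a latent factor z_k with an independent N(0,1) realization per
cell in both populations; ligand gene k in A and receptor gene k in B are
β·z_k + ε with ε ~ N(0, σ²); `n_context` genes per block load on the
factors (gene j on factor j mod k, strength β); the rest are N(0, σ²)
noise. Defaults: 200 + 200 cells, 20 + 20 genes, 5 planted pairs,
5 context genes per block, β = 2, σ = 1; candidates are the full
p_A × p_B cross product. An optional lognormal-count layer
(Poisson(exp(x)) then log-normalization) roughens the margins. Not
simulated: dropout, ambient RNA, doublets, batch effects, mean–variance
coupling of real counts.

**Identifiability limit (important).** With exact two-block missingness the
observed data are two independent samples and the likelihood factorizes
over blocks, so *no* imputation procedure can recover the cross-block
dependence itself: under the in-node random-draw routing, sender and
receiver rows co-locate in terminals at random, and imputed entries
concentrate near observed column means (measurably: the cross-block
correlation between imputed receptor values and the matching ligand truth
is ≈ 0, and imputation error is on the column-mean-imputation scale).
What the pipeline *does* detect is that factor-driven genes carry excess
marginal variance: their columns split near the roots of detection trees
on both sides of the block boundary, so planted ligand–receptor pairs
co-occur shallowly and receive small indices, while noise pairs rarely
co-occur. Passing recovery tests therefore demonstrate sensitivity to
planted activity (strongly expressed, high-variance communicating genes),
not reconstruction of cell-level cross-type coupling — on real data the
ranking is likewise driven by the joint prominence and co-splitting
structure of the two genes. Context genes are retained because they make
the imputation benchmark honest (they are the only columns that could, in
principle, inform the other block) and act as realistic high-variance
decoys in the candidate set.

Pair-level outputs are exchangeable over cells in distribution; a specific
cell permutation changes bootstrap draws and hence perturbs individual
indices slightly, so exact permutation invariance is not asserted.

## Numerical choices and problem sizes

- Split statistics clamp tiny negative within-node sums of squares to 0;
  oracle comparisons in tests use an absolute tolerance of 1e-9 and only
  demand argument equality when the minimizer is unique beyond that gap.
- Degenerate inputs: all-constant candidate variables yield terminal
  nodes; an all-missing variable is never splittable; an all-missing
  matrix yields single-node trees; imputation refuses columns or rows with
  zero observed values.
- Test and acceptance runs scale the study conditions down to keep a
  single-CPU run short: recovery uses M = 5 and 200 trees on the default
  generator conditions; the stability comparison uses 60 + 60 cells,
  8 + 8 genes and 50-tree forests, aggregating disjoint subsets of 50
  independent single-imputation indices into two M = 20 and two M = 5
  aggregates (algebraically identical to independent runs, since the
  aggregate is a mean over imputations).
- `rf_impute` takes an integer seed rather than a generator so the
  imputation record is exact and reproducible in isolation.

## Known limitations

- Single-gene pairs only; multi-subunit complexes are dropped at load.
- One direction per run (sender ligands → receiver receptors); run twice
  for both directions.
- The empirical p-value is a ranking device over the candidate ensemble,
  not a calibrated frequentist error rate.
- The cross-block identifiability limit above: imputed entries inform
  variance structure, not cell-level coupling.
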