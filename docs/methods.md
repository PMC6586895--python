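# Methods

## Problem setting

A combination screen measures, for a drug pair $(a, b)$ and a cancer cell
line $c$, a Loewe-excess synergy score: the integrated excess of observed
cell kill over the additive expectation of the Loewe model. Scores are
unbounded reals; the operational threshold for calling an experiment
synergistic is 20. The learning problem is regression of the synergy score
from features of the drugs and of the cell line, with one row per screened
(combination, cell line) pair. Only a minority of the combination ×
cell-line grid is screened (about 20% in the screens this package
emulates), and drug order within a pair is arbitrary — all pair features
must be symmetric under drug swap. We canonicalize pairs lexicographically
by drug id and carry the monotherapy blocks through the swap.

## Feature classes

Each feature column carries exactly one group label; the groups partition
the matrix and drive both the ablation hook and the importance summaries.

* **Chemical structure** — 166-bit MACCS structural keys per drug,
  pair-sum encoded: the elementwise sum of two binary vectors, so 2 = both
  drugs have the substructure, 1 = exactly one, 0 = neither. A drug with no
  SMILES contributes zeros and increments a `MACCS_MISSING` count (0/1/2).
* **Drug targets / protein domains / pathways** — indicator-then-pair-sum
  encodings of the drugs' putative target sets, of the structural domains of
  those targets (four sources — Pfam, Prosite, SMART, SUPERFAMILY —
  concatenated with source-namespaced ids to prevent collisions), and of the
  pathways containing the targets. Targets missing from every vocabulary
  contribute nothing: annotation lists are incomplete and this should not be
  fatal.
* **Drug synergy network** — an undirected graph linking two drugs when a
  strict majority of their combination's scores strictly exceeds 20 (a tie
  is not a majority). Three link-prediction indices per query pair
  $(x, y)$ with neighbourhoods $\Gamma(\cdot)$:
  common neighbours $|\Gamma(x)\cap\Gamma(y)|$, Jaccard
  $|\Gamma(x)\cap\Gamma(y)|/|\Gamma(x)\cup\Gamma(y)|$ (0 on an empty
  union), and Adamic–Adar $\sum_{z\in\Gamma(x)\cap\Gamma(y)} 1/\ln|\Gamma(z)|$
  (natural log, the index's original definition). By default a *leakage
  guard* is active: during cross-validation the network is rebuilt from each
  training fold, and a query pair's own edge is removed before its features
  are read, so no test label reaches a feature. A frozen whole-dataset
  network is available by passing `leakage_guard=False` / omitting
  `experiments`, since published pipelines do not always document their
  handling.
* **Monotherapy** — per canonical drug: max tested concentration, IC50,
  an IC50-censoring flag, Hill slope, maximal kill, and the assay QA flag
  (12 columns). An IC50 that was not reached within the tested range is
  imputed at the drug's max concentration with the flag set, preserving the
  ordering information "at or above max".
* **Gene expression modules** — genes are clustered by average-linkage
  hierarchical clustering of the dissimilarity $1-|r|$ over the gene–gene
  Pearson correlation matrix, with a fixed-count tree cut (default 5 on the
  synthetic cohort; a real 17k-gene screen would use a larger count, e.g.
  53) and clusters below `min_module_size` sent to "unassigned". Each
  module is summarized per cell line by the mean expression of its members;
  a first-principal-component eigengene summary is available as a switch.
  Full WGCNA machinery (soft-thresholding, topological overlap, dynamic
  tree cut) is deliberately out of scope.
* **Mutations** — one binary column per variant whose gene is in the
  cancer-gene list and which occurs in at least one cell line (a per-gene
  aggregation switch exists).
* **Copy number** — per-gene copy numbers are kept as features only for
  cancer genes whose copy number tracks their own expression: Spearman rank
  correlation (average ranks; any constant vector has correlation 0 by
  convention) strictly above both the median over *all* genes and 0.17,
  with a two-sided Fisher r-to-z p-value $2(1-\Phi(\operatorname{atanh}(r)\sqrt{n-3}))$
  below 0.01.
* **Trivial information** — combination id, cell line id, tissue, disease,
  sex as stable integer codes in sorted category order (tree models split
  on codes; one-hot would bloat a deliberately small group).

Assembly sorts columns by (group, name), forbids duplicate names and
missing values, and is invariant to input row order.

## Models and evaluation

Five regression backends share one interface: ordinary least squares,
Lasso (regularization by internal 5-fold CV; the literature this follows
is silent on the strength), an RBF-kernel ε-SVR, random forest, and
gradient-boosted trees. Boosting presets: `paper-tuned`
(n_estimators=500, max_depth=8, subsample=0.75, colsample_bytree=1.0) and
`paper-default` (250, 8, 1.0, 1.0), learning rate fixed at 0.1. The
`tune_xgboost` coordinate sweep reproduces the search protocol that
produced the tuned preset: sweep each axis holding the others, fix the
best, re-sweep; the returned point is the argmin over everything
evaluated.

The primary metric is the weighted average Pearson correlation

$$\mathrm{WAPCC} = \frac{\sum_i \sqrt{n_i-1}\,\rho_i}{\sum_i \sqrt{n_i-1}}$$

over combinations $i$ screened on $n_i$ cell lines, where $\rho_i$ is the
Pearson correlation between observed and predicted scores of that
combination's experiments (constant vectors give $\rho=0$ so degenerate
combinations stay defined; $n_i=1$ combinations carry zero weight).
Evaluation is ten repetitions of 10-fold CV; a combination's out-of-fold
predictions are pooled *within a repetition* before computing $\rho_i$
(most combinations span folds), and the reported WAPCC is the mean over
repetitions. Bootstrap confidence intervals resample combinations — the
weight-bearing unit — with replacement; model comparisons use a two-sample
z-test on repetition-level summaries. Classification performance uses
scores binarized strictly above 20 and ROC-AUC (Mann–Whitney
normalization, ties at one half).

A caution on permutation nulls: with label-permuted targets, out-of-fold
predictions of a model that can memorize per-combination means (e.g. trees
splitting on the combination-id code) are *anti*-correlated with the held
out labels — the standard k-fold artifact — so the null WAPCC sits below
zero rather than at it. "No positive skill" is the correct null reading.

## The synthetic cohort

The generator provides study conditions for every stage without access to
a gated screen. Defaults: 60 drugs, 40 cell lines, 150 distinct
combinations, 20% of the grid screened uniformly at random without
replacement (floor rounding → 1200 experiments), 250 genes in 5 equal
modules, 60 proteins, 15 pathways, 40 domains across four sources.

* Expression: $x_{gc} = \sqrt{v}F_{m(g)c} + \sqrt{1-v}\,\varepsilon_{gc}$
  with standard-normal factor and noise, so the expected within-module
  pairwise correlation equals $v$ (default 0.8).
* Copy numbers: integers in $[0, 8]$; for a coupled gene (20% of genes) a
  latent Gaussian mixes the gene's standardized expression at the loading
  $2\sin(\pi\rho_s/6)$ that targets Spearman $\rho_s = 0.6$ under
  bivariate normality; rounding ties leave the realised correlation
  slightly below target.
* Monotherapy: per-drug max concentration from {3.16, 10, 31.6} µM, IC50
  log-uniform in [0.01, 10] µM (censored when above max), Hill slope
  uniform [0.5, 3], maximal kill uniform [20, 100]%.
* Synergy: intercept 5, +6 if the drugs share a pathway, +8 × (mean
  expression of a designated module), +20 if the pair targets a designated
  protein *and* the cell line carries a designated mutation, +0.3 ×
  |ΔEinf|, plus Gaussian noise. With `noise_sd=None` (default) the noise SD
  is set to the SD of the deterministic part, so the signal explains about
  half the score variance.

The effect sizes follow a variance-budget argument: the
$\sqrt{n_i-1}$-weighted metric only rewards signal that varies *within* a
combination, while the 50%-signal calibration scales noise to the *total*
signal SD. A large between-combination term (e.g. the pathway indicator)
therefore inflates the noise without adding recoverable within-combination
correlation. The defaults put most signal variance in the cell-varying
terms (module ≈ 40%, monotherapy ≈ 25%, mutation interaction ≈ 25%) and
keep a modest pathway share (≈ 8%) so every planted effect remains
detectable.

Randomness uses independent named substreams (vocabulary, drugs, screen
sampling, expression, CNV, monotherapy, mutations, noise, metadata)
spawned from one seed, so changing e.g. the gene count does not perturb
which grid cells are screened. The `truth` record (module assignment,
coupled genes, coefficients, designated module/protein/gene, carrier cell
lines) suffices to rebuild the planted design matrix, and an OLS refit on
that matrix recovers each coefficient within two standard errors.

What the generator does **not** emulate: real chemistry (fingerprints are
random bits at density 0.3 — pair-sum bookkeeping is exercised, chemical
similarity structure is not), dose-response surfaces, correlated
mutation/tissue structure, batch effects, or heavy-tailed synergy noise.
Passing tests therefore certify the pipeline's mechanics and its ability
to recover planted signal of realistic strength — not clinical
performance on a real screen.

## Numerical and degenerate-input conventions

* Pearson or Spearman of a constant vector: 0 (never NaN).
* Jaccard with an empty neighbourhood union: 0. Unknown drugs are
  isolated nodes.
* Majority rule and binarization are strict (`>`), ties fail.
* Hypergeometric enrichment uses the exact upper tail
  $P(X \ge k)$; Bonferroni multiplies by the number of non-empty terms,
  capped at 1.
* Bootstrap replicates with zero total weight are redrawn.
* z-test with both variances zero: z=0, p=1 if means agree, else ±∞, p=0.
* Module detection sorts genes before clustering and renames clusters by
  their first member in sorted gene order, making the output invariant to
  gene and cell-line order.
* Boosted models run single-threaded with the histogram tree method, so
  refits with the same seed are bitwise identical.

## Known limitations

* The fixed-count tree cut needs the module count as a parameter; no
  selection rule is provided (none is established for this design).
* The SVR backend uses an RBF kernel by default; only the ε-insensitive
  objective, not the kernel, is pinned down by the modelling tradition this
  follows.
* Network features on a sparse screen are frequently zero; their value
  shows up on denser, better-connected screens.
* With tree models, the permutation-null WAPCC is negatively biased (see
  above); comparisons against it should test for positive skill only.
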