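# Methods

## Problem and model

The package ranks genes as candidate immuno-oncology drug targets. Genes
are nodes of an undirected gene–gene interaction network (the
message-passing substrate); each node carries a vector of d numeric
features summarizing heterogeneous evidence — patient cohort genomics
stratified by checkpoint-inhibitor response, per-cell-type interactome
influence scores, HLA-peptidomics presentation correlations, GWAS
phenotype-association counts and CRISPR co-culture screen scores. Known
targets (genes addressed in at least phase I trials) are positives; under
the closed-world assumption every other gene is a negative.

The classifier is a graph isomorphism network (GIN) with linear update
layers. A stack of m pre-processing layers, each
`DROPOUT(ReLU(BN(LINEAR(x))))`, maps the d input features to a base width
w. Each of the message-passing layers then computes

    x_i ← DROPOUT(ReLU(BN(LINEAR((1 + ε)·x_i + Σ_{j∈N_s(i)} x_j))))

with **sum** aggregation over a sampled neighbourhood N_s(i) (sum rather
than mean/max for expressivity), followed by n post-processing layers of
the same per-node block and a single linear unit with a sigmoid. Widths
expand by a factor of 2 from the pre-processing stack into the GIN layers
and contract by the same factor into the post-processing stack
(w → 2w → w → 1). Neighbourhoods are resampled uniformly without
replacement, per layer per epoch, capped at k ∈ {50, 100, 200} or "all".
The model is inductive: a forward pass scores any node from its features
and edges.

The network is implemented directly in numpy with explicit backward passes
(linear, batch-normalization with running statistics, ReLU, inverted
dropout) and an Adam optimizer. This keeps CPU training bit-reproducible
under a fixed seed, which the protocol's determinism contracts rely on.

## Training protocol (positive–unlabelled)

1. **Outer split.** 75/25 train/held-out, stratified jointly over the
   positive label and per-feature missingness indicators by greedy
   iterative multilabel stratification. Constant indicator columns are
   dropped with a warning. The held-out partition never touches training
   or tuning.
2. **Imputation** uses training-partition statistics only, per feature
   class: pseudo-missing → 0 (absence of evidence is a genuine zero);
   true-missing with median policy → training-set median, with one class
   ("median-split", used for regulatory-network degrees) imputing held-out
   genes from the held-out median instead; topological-specificity
   features → 0; "exclude"-class features drop genes missing them.
3. **Repeated CV.** 10×-repeated stratified 10-fold CV over the training
   partition (each repeat an independent stratified partition). Every
   fold model trains on a 1:1 undersampled balance: all positives kept,
   negatives drawn without replacement.
4. **Fold training.** Full-batch binary cross-entropy on the undersampled
   fold-train nodes, Adam, default learning rate 1e-2, 100 epochs, no
   early stopping. The forward pass spans the whole graph (message
   passing needs every node's features); labels of non-training nodes are
   never used. Batch-normalization uses batch statistics while training
   and frozen running statistics (momentum 0.1) at evaluation.
5. **Bagging.** A gene's score is the mean over only those fold models
   whose training fold excluded it: exactly `repeats` models for
   training-partition genes (10 in the canonical 10×10 plan) and all
   `repeats × folds` models (100) for held-out genes. Ranking ties break
   lexicographically on the gene identifier.
6. **Hyperparameter search** maximizes the mean CV test-fold ROC-AUC with
   a sequential uniform sampler over the design space (embedding width,
   pre/post depths, learning rate, dropout, k ∈ {50,100,200}); the
   incumbent is monotone in the number of trials. Default budget 50.
7. **Shortlisting** takes the top 300 bagged predictions and removes the
   positively labelled genes, preserving order.

Defaults that the source protocol leaves open and that we fixed once:
loss (BCE), optimizer (Adam), epochs (100), undersampling ratio (1:1),
ε = 0 and non-learnable, dropout placed after the activation, 2 GIN
layers, scalar sigmoid head, batch-norm momentum 0.1.

## Evaluation and statistics

* **ROC-AUC** via the Mann–Whitney identity (ties ½).
* **Curve comparison** by DeLong's paired placement-value test or a
  percentile bootstrap of ΔAUC.
* **Empirical P** values follow the resampling definition exactly as
  printed: `p = #(null draws ≥ |observed|) / #draws`; the draws enter raw.
  An optional (r+1)/(n+1) correction exists behind a flag, off by default.
  The sign convention matters only for signed statistics; every built-in
  use resamples non-negative quantities.
* **Exact Wilcoxon signed-rank** (two-sided, paired): full enumeration of
  the 2^n sign assignments through a subset-sum convolution on doubled
  ranks (exact for half-integer average ranks under ties); two-sided p is
  twice the smaller tail, capped at 1. For n = 8 this reproduces
  0.00781 (W = 0), 0.0156 (W = 1) and 0.0391 (W = 3).

Three validation tasks probe a fitted ranking:

* **Time-sliced test** — mean score of targets that entered trials after
  the label freeze vs 1,000 means of size-matched gene sets sampled from
  *all* scored genes (the time-sliced genes are deliberately not excluded
  from the null, which would deflate it). Reported: empirical p and a
  Mann–Whitney p of the time-sliced scores against the null means (an
  "other genes" comparand is available).
* **Phase ranking** — Kruskal–Wallis across {approved, phases I–III,
  non-target} plus Mann–Whitney approved vs in-development; time-sliced
  genes excluded by default or optionally recategorized as in-development.
* **DEG recovery** — overlap of the top 200 predictions with
  differentially expressed genes (BH-adjusted p < 0.05) against 1,000
  size-matched sets sampled to match the top set's distribution across
  mean-expression deciles (strata too small to sample are merged into a
  neighbour); plus per-bin Spearman correlations between predictions and
  the Wald statistic over the top 1,000 genes in bins of 200.

## Permutation interpretability

All procedures evaluate frozen models and return copies; nothing is
retrained.

* **Feature importance**: shuffle a column across genes, recompute each
  fold model's ROC-AUC on its evaluation genes; importance is the signed
  drop (original − mean permuted) on the CV training set and the absolute
  difference on CV-test/held-out sets; default 500 permutations. A
  biological category aggregates its members' per-feature importances
  (each shuffled independently, so a c-feature category accumulates
  c × n_perm shuffles); a joint-shuffle mode preserving within-category
  covariance is available. A recall-based variant fixes the decision
  threshold at a specificity level (0.7/0.8/0.9) chosen on the original
  scores and reports the absolute recall change.
* **Network importance**: degree-preserving edge permutation by local
  swapping — propose replacing random edges (a,b),(c,d) with (a,d),(c,b),
  rejecting self-loops and duplicates, with a default proposal budget of
  10·|E| per permuted network (enough to fully randomize). Each fold
  model is evaluated on its own set of permuted networks (100 fold models
  × 500 networks = 50,000 evaluations at canonical scale). The "500" of
  the source protocol is read as the number of permuted networks per fold
  model, not the proposal count, which the published evaluation total
  fixes unambiguously.
* **Pathway importance** for a single predicted target: only the edges
  with both endpoints inside one pathway are rewired (degree-preserving,
  rejections also checked against the fixed edges), 100 draws; raw
  importance is the median absolute change of the target's score;
  reported importance divides by √(pathway edge count) to correct the
  size dependence. Pathways not containing the target or with fewer than
  2 internal edges are flagged not-permuted. Scores are computed in eval
  mode, so the procedure is deterministic given the seed.

## Synthetic data

The generator emulates the corpus shape with planted, tunable signal: a
preferential-attachment graph (attachment 4, mean degree ≈ 8), a latent
standardized target propensity per gene, positives and time-sliced
targets drawn from the high-propensity pool, extra homophilous edges
among high-propensity genes (strength 0.3 by default), features = noise
plus `effect × propensity` on 3 designated signal columns (effect 1.5 SD
by default) with per-class missingness injected at 5%, a DEG table with
Wald = 2·propensity + N(0,1), and patient-level cohort omics consistent
with the featurization formulas. Defaults are the benchmark conditions
(2,000 genes, 100 positives) used by the recovery suite; a ground-truth
manifest (signal columns, propensities, planted sets) supports parameter
recovery. Everything is deterministic per seed.

What the generator does *not* emulate: the real interactome's clustering
and community structure, correlated missingness across modalities,
feature-scale heterogeneity, and label noise beyond the closed-world
mislabelling implicit in the construction. Passing the recovery suite
shows the pipeline can find signal of the planted kinds at these sizes,
not that the real corpus carries such signal.

## Numerical and fixture choices

* Problem sizes in the test-suite: the recovery benchmark runs the full
  protocol at 2,000 genes with a 2×5 CV plan and 100-epoch folds;
  smaller property tests use 300–500 genes. These sizes make the planted
  effects detectable while keeping the suite quick on one CPU.
* The null-calibration suite checks that the time-sliced and
  DEG-recovery empirical p-values are uniform under no signal
  (Kolmogorov–Smirnov over 200 simulated runs). The DEG fixture uses a
  DEG fraction of ~40%: the overlap statistic is an integer, and with a
  sparse DEG set the as-printed empirical p is heavily discretized —
  conservative (ties count against rejection) rather than miscalibrated —
  which a two-sided KS test would flag for reasons unrelated to
  calibration.
* Copy number 0 is floored to 1e-3 before logs; `log[R]` is implemented
  literally as log2(CN)/2 with a conventional log2(CN/2) dialect
  available. "Unexpressed" means TPM exactly 0 (configurable threshold).
* Quantile normalization maps each patient profile to the mean sorted
  profile through its own ranks; residualization on study/tissue dummies
  adds the grand mean back so feature scales stay interpretable.
* Specificity thresholds for the recall importance pick the smallest
  observed score threshold whose specificity reaches the target
  (maximizing recall at that specificity); an unreachable target errors.
* Feature categories are treated as a partition of the feature columns;
  the category-level importance reported by default is the mean of member
  importances.

## Known limitations

* Full-batch training computes batch-normalization statistics over all
  graph nodes, including unlabelled ones — standard for full-batch GNN
  training, but a mild transductive element; running statistics used at
  evaluation are frozen after training.
* The tuner is a uniform sequential sampler, not a density-model
  optimizer; it satisfies the same interface and monotone-incumbent
  contract and can be swapped out.
* DeLong's test uses the normal approximation; for very small gene sets
  prefer the bootstrap route.
* Exact signed-rank enumeration is limited to n ≤ 25 non-zero
  differences (2^n enumeration).
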