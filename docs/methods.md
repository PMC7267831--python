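# Methods

## Problem and model

Given an undirected, weighted molecular network `G = ⟨V, E, W⟩` over string
gene IDs and a collection of genesets (functions, diseases, traits), each
geneset defines a binary classification task: rank held-out genes by their
likelihood of membership. Two method families are implemented over three
network representations.

**Representations.** The adjacency matrix `A` (`A[i,j] = w(i,j)`, symmetric,
zero diagonal, lexicographic node order); the random-walk-with-restart
influence matrix

```
F = α (I − (1−α) W_D)^{-1},   W_D = A D^{-1},   D = diag(weighted degrees)
```

and node2vec embeddings `E ∈ R^{|V|×d}`. `W_D` is column-normalised as
printed above, which makes it column-stochastic and `F` column-stochastic
for α ∈ (0,1] whenever no node has zero degree; column `j` of `F` is the
stationary visiting distribution of a walk restarting at `j` with
probability α per step. We solve the linear system `(I − (1−α)W_D) F = αI`
densely; at the package's benchmark scales (hundreds to a few thousand
nodes) this is exact and fast, and it is verified in the tests against both
an independent dense inversion and a 200-term Neumann-series oracle.

**Label propagation.** `S = M x` with `x[i] = 1` for training positives and
0 otherwise, `M ∈ {A, F}`. Under `M = A` a gene's score is exactly the
summed weight of its edges to positively labeled neighbours (checked
brute-force in the tests). By default negatives do not enter `x` — this
mirrors how propagation is used in practice — but a signed mode
(`use_negatives=True`) sets `x[i] = −1` on training negatives.

**Supervised learning.** Logistic regression with L2 penalty, `C = 1.0`,
intercept included, on the gene's feature row (adjacency row, influence row
or embedding). Rows are deliberately *not* standardised: the scale of a
network row is meaningful (degree, connectivity strength). Fitting uses
scikit-learn's deterministic lbfgs solver, tolerance 1e-4, max 1000
iterations; all three knobs are exposed in `MethodConfig`.

## node2vec

Second-order biased random walks with unnormalised transition weight
`w(cur, next) · bias`, where bias is `1/p` when `next` is the previous node,
`1` when `next` neighbours the previous node, and `1/q` otherwise — the
standard in-out/return scheme with multiplicative edge weights. Defaults:
`p = q = 0.1`, `d = 128`, 10 walks of length 80 per node, window 10, one
epoch, 5 negative samples, initial learning rate 0.025 with linear decay.
The skip-gram objective is optimised by single-threaded mini-batch SGD with
a unigram^0.75 negative-sampling table, so a fixed seed reproduces the
embedding bit-for-bit. Isolated nodes emit length-1 walks (with a warning)
and keep their random-initialisation vector.

`p` and `q` are the protocol's fixed values; the remaining parameters are
the conventional node2vec defaults and are all overridable from
`Node2VecParams` / the CLI. The tests exercise a reduced setting (d = 16,
walks 10×40, 3 epochs) where embeddings of a planted two-block network
separate the blocks in at least 4 of 5 seeds.

## Geneset preprocessing

Fixed order: **propagate → size filter → redundancy filter →
multi-attribute removal.**

* *Propagation* annotates each gene to every ontology ancestor of its sets;
  cycles are rejected naming a member. Annotation dates propagate with the
  earliest contributing descendant date — some rule is required because the
  temporal split demands a date for every (gene, set) pair after
  propagation, and "earliest evidence" is the conservative choice for a
  scheme that must not leak post-cutoff information into training.
* *Size filter*: keep sets with `min_size ≤ |S| ≤ max_size`
  (defaults 10 / 200).
* *Redundancy filter*: greedy scan in descending-size, then lexicographic
  order; drop a set whose Jaccard index with any kept set exceeds the
  threshold (default 0.5). Greedy keep-largest-first is deterministic and
  keeps the more general set of a redundant pair.
* *Multi-attribute removal*: genes in **more than** 10 of the surviving sets
  are removed from all sets (strict inequality; emptied sets are dropped).

**Negative selection.** For target set T: universe U = union of all
annotated genes; exclude T and every member of any other set S with
one-sided Fisher `P(X ≥ |S∩T|) < 0.05`, where `X ~ Hypergeom(|U|, |T|, |S|)`.
The test's background is the annotated-gene universe, consistent with the
selection operating inside U. Shrinking the threshold excludes fewer sets,
so the negative pool grows monotonically (property-tested).

## Validation schemes

* **Temporal holdout** (cutoff default 2017-01-01): a gene is a *test* gene
  iff *all* of its annotations postdate the cutoff; one pre-cutoff
  annotation keeps it in training. Missing dates are an error, not a guess.
* **Study-bias holdout**: genes sorted by publication count descending, ties
  broken lexicographically for determinism; the top `⌈2n/3⌉` train (ceiling
  on the training side — "top two-thirds" favours training).
* **Stratified 5-fold CV** via seeded `StratifiedKFold`; per-fold class
  counts deviate from proportionality by at most 1.

Tasks keep only genes present in the network (logged) and must have at least
10 positives on both sides of a holdout split. For CV the per-geneset metric
is the mean over folds; the prior is the task-level positive fraction.

## Metrics and comparison protocol

* **auPRC** is average precision: the mean over positives of precision at
  each positive's rank. Step-wise rather than trapezoidal — conservative
  and directly checkable against enumeration. Score ties are broken by gene
  id so rankings (and therefore results) are reproducible; auROC instead
  uses midranks (ties earn half credit).
* **P@TopK** with K = number of test positives by default.
* auPRC and P@TopK are reported as `log2(metric / prior)`; a raw value of 0
  maps to a −∞ sentinel rather than an exception. Note `E[auPRC]` under a
  random ranking exceeds the prior by `O(1/n)`; the package's Monte-Carlo
  check runs at 1000 test genes, where the bias is within ±0.01.
* **Competition ranking** ("1224"): rank = 1 + number of strictly better
  methods; averaged over the collection.
* **Wilcoxon signed-rank**, two-sided, paired per geneset: zero differences
  are excluded (classical procedure) but win counts are reported on the raw
  pairs; the null distribution is computed exactly for ≤ 25 nonzero
  differences by dynamic programming over doubled midranks (equivalent to
  enumerating all 2^n sign assignments, and cross-checked against both a
  literal enumeration and scipy), with a continuity- and tie-corrected
  normal approximation above. An all-tied comparison reports p = 1 with a
  flag. The paired signed-rank variant is used because per-geneset values
  are paired across methods; the unpaired rank-sum can be obtained from
  scipy directly if desired.
* **Class verdict**: the four SL×LP comparisons are BH-adjusted; a method
  beats the other class when it wins more genesets than both opponents and
  both adjusted p-values are < 0.05; if both methods of a class qualify the
  class itself is the winner. The reported `win_fraction` is the share of
  all 4·n comparisons won by SL.

**Geneset network properties.** Edge density = within-set edge weight /
`n(n−1)/2`; segregation = within-set edge weight / total weight incident to
the set (within edges counted once), in [0, 1]. Their association with
performance is measured by Spearman correlation with a seeded 1000-resample
bootstrap CI; constant inputs yield NaN with a flag rather than a value.

## Synthetic benchmark

The generator is a planted-partition (stochastic block) model: modules of
configurable size are wired i.i.d. with `p_within`, all other pairs with
`p_between`, weights unit or uniform; each module doubles as a ground-truth
geneset. This is the minimal generator whose edge density and segregation —
the two properties the evaluation studies — are directly controlled.
Annotation artifacts add near-duplicate sets (Jaccard ≥ 0.9), genes injected
into 11 sets (multi-attribute), per-gene dates entirely pre- or post-cutoff
with configurable probability, and publication counts from a discrete Pareto
tail (exponent 1.5, emulating the heavy tail of PubMed mention counts).
Everything is a pure function of `SimConfig`: identical seeds give
byte-identical fixture files.

The standard study conditions are 500 genes, ten 30-gene modules,
`p_within = 0.3` against `p_between = 0.01`, evaluated with 5-fold CV over
three seeds; the density sweep uses 200-gene networks with five modules at
`p_within ∈ {0.05, 0.1, 0.2, 0.4}`. At these settings the whole benchmark
plus the sweep completes in seconds on one CPU.

**What passing tests do and do not show.** The generator produces
unambiguous, equally sized, non-overlapping modules on a homogeneous
background. Real molecular networks have heavy-tailed degree distributions,
hub genes, correlated annotation noise and modules of wildly varying size
and cohesion; real collections overlap hierarchically rather than by
construction. Recovery of planted modules therefore validates the machinery
(features, training, splitting, scoring, statistics), not the biological
performance ordering of the methods on real data — on this easy geometry
all four methods can saturate, which is visible in the benchmark's
near-perfect medians.

## Numerical and degenerate-input choices

* Duplicate edges collapse by maximum weight; self-loops and zero-weight
  edges are dropped at load (with logged counts); negative weights are
  errors. Node order is lexicographic everywhere.
* Edge-list weights are written with `repr`, so a write/load round trip is
  lossless.
* Zero-degree nodes get influence column `α·e_i` (warned, kept).
* One-to-many ID mappings add edges between all target pairs; unmapped nodes
  are dropped with a log line.
* Genes in a task but absent from the network are excluded from training and
  reported as `missing` in prediction results rather than silently scored.
* `α = 1` short-circuits to the identity kernel; LP-I then scores training
  positives 1 and everything else 0 (tested limit).

## Known limitations

* Dense linear algebra bounds practical network size to a few thousand
  nodes; the genome-scale sparse path (iterative per-column solves) is not
  implemented.
* The node2vec trainer is a plain numpy SGD loop — deterministic and exact
  for benchmark-sized graphs, but not competitive in throughput with
  multi-threaded word2vec implementations.
* Only the unpaired-vs-paired Wilcoxon choice is exposed indirectly; the
  rank-sum variant is not wrapped.
* No OBO parsing, evidence codes, or retrieval of real networks/annotation
  databases: inputs are plain edge-list TSV, GMT, and two-column TSVs.
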