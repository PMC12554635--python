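# Methods

This note documents the models and procedures implemented in `exprnet`,
the defaults and the reasoning behind choices the design left open. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute themselves.

## Synthetic data model

The generators produce the ground-truth worlds every test runs against.
Expression is log-normal: Gaussian on the log2 scale with a per-gene
baseline drawn uniformly from [3, 9] (the range typical of normalized
bulk RNA-seq), within-class standard deviation `dispersion`
(default 0.3), exponentiated back to a raw non-negative scale so that
the pipeline's own `log2(x+1)` recovers the Gaussian world. The first
`n_markers` genes carry a class-2 log2-mean shift of `effect_size` and
are recorded in `truth_markers`. Paired cohorts add a subject-level
intercept (sd `subject_sd`, default 0.5) shared by both samples of a
pair, mimicking matched designs where within-subject contrasts are more
powerful than between-subject ones. A log-normal rather than
negative-binomial model was chosen because every downstream computation
operates after `log2(x+1)`; a count model would add dispersion
machinery without changing anything the pipeline sees.

What the generator deliberately omits: library-size artifacts, batch
effects, single-cell dropout — and, importantly, **correlation between
genes**. Genes are independent given their class means. Consequences of
that last point are discussed under "Limitations".

## Normalization

Two order-locked chains feed the one-dimensional clustering
(`scale_tag` enforces composition; misordered transforms raise):

* unpaired: `log2(x+1)` → per-gene, per-class z-scores (sample sd,
  n−1; zero-variance rows map to 0);
* paired: `log2(x+1)` → per-gene, per-class min–max rescale to [1, 2]
  (constant rows map to the midpoint 1.5, keeping ratios defined) →
  class2/class1 ratio per subject, bounded in [0.5, 2] by construction.

The rescale/z-score scope is per gene within each class. An open
question was whether scoping should be per gene or across the whole
matrix; per-gene scope is required for the subsequent per-gene
clustering to be scale-free, and is what the operation contracts
specify. A consequence worth stating plainly: any per-class, per-gene
standardization removes a constant class shift *exactly*, so the
normalized clustering matrix is blind to pure mean-shift markers. In
real cohorts the graph still carries signal because co-regulated genes
partition samples the same way; see "Limitations" for what this means
on independent-gene synthetic data.

The differential-expression prefilter replaces a count-based DE step
with nonparametric rank tests — Wilcoxon signed-rank for paired
designs, Mann–Whitney U otherwise — with Benjamini–Hochberg adjustment
at `alpha` (default 0.05), truncated to `max_genes` by p-value. Users
who ran their own DE tool can pass an explicit gene list instead. If
nothing passes BH, the top `max_genes` by absolute mean log2 difference
are returned with a warning rather than an empty panel.

## One-dimensional median-linkage clustering

Median (WPGMC) linkage is implemented directly rather than through a
generic routine because downstream results depend on an exactly
specified merge order: ties resolve to the lowest-index pair, making
runs reproducible without hidden randomness. In one dimension the
cluster representative is the midpoint of its children and distances
are absolute differences; heights may invert (median linkage is not
monotone), which the dendrogram type permits. The implementation is
cross-checked in the tests against both an exhaustive brute-force
oracle (n ≤ 8, tolerance 1e-12) and an independent library
implementation of WPGMC on tie-free data.

Every internal node except the root is a candidate cluster (the tree
stores per-node levels, so multi-scale clusters are available without
naming a cut height); `min_size` defaults to 2 because singleton
clusters carry no shared-sample information. Extremeness is the
median's z-score against the gene's own normalized value vector — the
reference distribution was an open choice (gene-wise vs.
cluster-population-wise); gene-wise is implemented as the more direct
reading. The top `ceil(fraction × n_candidates)` by |z| are kept per
gene (fraction default 0.1), with deterministic tie-breaking (larger
size, then lexicographic member ids).

## Graph construction and per-sample subgraphs

Edges connect clusters of different genes intersecting in at least
`min_shared` samples (default 1), annotated with the exact shared count
and the tree levels of both endpoints. Intersections are computed by a
boolean membership-matrix product; same-gene pairs are excluded. Graphs
are held in process; GraphML and nodes/edges CSV exports preserve the
graph-database workflow without a database dependency.

A sample's subgraph is the induced graph on clusters containing it.
Node features: cluster median, size, tree level, plus the sample's own
normalized expression of the cluster's gene ("all" mode), or the
expression value alone ("gene" mode). Features and edge weights are
min–max scaled with statistics fit on training subgraphs only;
out-of-range held-out values are clipped to [0, 1].

Held-out samples need membership in clusters built on training data.
Per gene, the sample is routed to the selected cluster whose median is
nearest to its normalized value, provided the distance is at most one
training standard deviation of that gene; otherwise the gene
contributes no node. A sample landing in no cluster yields an empty
subgraph, which the classifier handles with a prior-based default
probability and a flag.

The prediction network (built from the selected markers) clusters
per-gene z-scores computed against **pooled** training statistics, not
the per-class route used for the feature-selection graph. Per-class
statistics would require the held-out label (leakage) and would put
training and held-out samples on different scales; with pooled
statistics, training membership, held-out assignment and the expression
feature share one label-free scale.

## Marker selection

Sampling one cluster per gene uniformly at random removes within-gene
redundancy; scores accumulate over `n_iterations` (default 10 000;
calibration and recovery tests use 500 for speed, stated where used).
Community frequency is operationalized as community size minus one
(co-membership count): with one node per gene, within-community
multiplicity of a single gene is impossible, so co-membership is the
meaningful quantity. Louvain modularity maximization is used with a
fixed seed and node order for reproducibility. Pathway scores count the
BH-enriched gene sets (hypergeometric, universe = graph genes,
adjusted p < 0.05 per community) containing the gene; without a GMT
collection the criterion is disabled, giving the "no-pathway" catalog
variant.

Significance per criterion comes from a gene-level bootstrap. The
observed statistic is the gene's mean score minus the mean of all other
genes' pooled scores. Scores are strongly correlated across iterations
within a gene — expected degree is a function of the gene's fixed
cluster structure — so an i.i.d. draw from the pooled score values
would wildly understate the null variance (measured during development:
42% of null genes rejected after BH). Each bootstrap replicate
therefore redraws the iteration indices with replacement and
substitutes the score row of a uniformly chosen *other* gene,
preserving gene-level structure under exchangeability. A
+1/(n_boot + 1) continuity correction keeps p-values strictly positive.
Genes are ranked per criterion by BH-adjusted p (average ranks on
ties); the final markers are the `top_k` smallest rank sums, ties
broken by the best single-criterion p-value, then gene id.

## Graph classifiers

GCN, GAT and GATv2 layers follow their standard propagation rules (see
README for the formulas) on dense per-subgraph matrices, with
self-connections added inside each layer — never stored in the
adjacency — so isolated nodes are well-defined in both the spectral
normalization and the attention softmax. Multi-head attention
concatenates head outputs in hidden layers and averages them in the
last. Edge weights (normalized shared counts) enter the GCN through the
weighted adjacency and the attention models as an optional additive
logit bias (off by default). Readout is global mean pooling by default
(sum and max available), followed by a linear two-class softmax head.

Because no deep-learning framework is assumed at run time, the layers
are built on a ~300-line reverse-mode autodiff engine over numpy arrays
(broadcast arithmetic, matmul, reductions, reshaping, concatenation),
verified against central finite differences in the tests. Training uses
Adam (lr default 0.01), full-batch cross-entropy, Glorot-uniform seeded
initialization and a fixed epoch budget (default 50); there is no early
stopping by default, which keeps runs bit-reproducible, with optional
patience-based stopping. Defaults — 2 layers, hidden dim 64, 4 heads —
are sized for desk-scale problems.

Hyperparameter search optimizes mean five-fold cross-validated AUC
(folds stratified, pairs never split) by random search, or by a
Gaussian-process surrogate with expected improvement over a sampled
candidate pool ("bayesian" strategy) for larger spaces.

## Pipeline and evaluation

One evaluation iteration: stratified 80/20 split (pairs unsplit) →
prefilter on the training 80% → design-specific normalization →
per-gene clustering → feature-selection graph → marker selection →
prediction network from the markers → subgraphs → classifier training →
held-out evaluation. The default 10 iterations redraw the split each
time — the reading consistent with reporting a standard deviation —
and metrics are averaged. Accuracy thresholds the class-2 probability
at 0.5; AUC is the Mann–Whitney form with ties counted one half. All
per-iteration seeds spawn deterministically from one master seed via
`numpy.random.SeedSequence`, so a rerun reproduces every number exactly
in single-threaded execution. ANOVA (F-test) and greedy mRMR (mutual
information, difference form) are included as light comparator feature
selectors.

## Limitations

* **Independent-gene synthetic data carries no graph signal.** Because
  per-class standardization removes class shifts exactly and the
  generator draws genes independently, degree and community scores
  cannot distinguish planted markers from background in the synthetic
  world; marker recovery there is driven by the prefilter, with the
  graph ranking approximately neutral among surviving genes. A green
  recovery test therefore establishes that the end-to-end chain keeps
  true markers, not that graph topology alone finds them. Graph scores
  add discrimination when genes co-vary in modules, which real cohorts
  exhibit and the deliberately simple generator does not.
* Dense per-subgraph linear algebra limits subgraphs to a few thousand
  nodes; the design targets marker panels (tens of genes), not
  transcriptome-wide graphs.
* The held-out assignment rule (nearest median within one training sd)
  fills a gap the original procedure leaves open; other conventions
  (e.g. joint clustering of all samples) would leak label information
  through paired ratios and were rejected.
* Bootstrap p-values are resolution-limited to 1/(n_boot + 1); with BH
  adjustment across many genes, small `n_boot` cannot produce very
  small adjusted p-values.
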