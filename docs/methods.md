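# Methods

## The ensemble model

`mcam` treats a clustering solution not as an estimate of a "true" partition
but as one of many defensible dimensionality reductions of a quantitative
peptide-by-condition matrix. The unit of analysis is the *clusterset*: the
complete partition produced by one configuration (transform, distance,
algorithm, K). The ensemble (MCA) is the set of all clustersets from the
combinatorial grid, and every downstream statement is a statement about the
ensemble — which labels are repeatedly enriched, which peptide pairs
repeatedly co-cluster, which parameters repeatedly help or hurt.

### Grid expansion

The Cartesian product transform × distance × algorithm × K is constrained
per algorithm: affinity propagation derives its own cluster count, so it
contributes |transforms| × |distances| configurations with no K; the
self-organizing map is trained on the Euclidean metric only, contributing
|K| × |transforms|; k-means uses squared Euclidean and rejects chebychev
(the L∞ metric admits no sensible centroid update); normalized-cut and
hierarchical take the full product. K runs over even values from 2 to the
largest even K leaving at least `per_cluster` (default 5) peptides per
cluster under an equal split — 14 for 77 peptides. Configurations whose
transform is mathematically undefined on the given data (e.g. zscore_log10
on any data whose z-scores include non-positive values, which is all data)
are counted in the grid but skipped at run time and recorded in the
manifest; this keeps the combinatorial count data-independent.

### Transforms and distances

All transforms are row-wise (each row is the dynamic trajectory of one
peptide). zscore uses the sample (n−1) standard deviation; pareto divides
the centered row by the square root of that standard deviation; composites
(normMax_log10, zscore_log10) chain left-to-right as named. The FFT
transform is the magnitude spectrum of the full-length DFT — phase is
discarded and the DC component kept, so clustering on it groups rows by
frequency content at unchanged dimensionality. diff takes first differences
and shortens the vector by one. Degenerate outputs (zero variance, log of a
non-positive value) raise rather than propagate non-finite values.

Distances: euclidean (optionally squared, for k-means), cityblock (L1),
chebychev (L∞), correlation (1 − Pearson r), cosine (1 − cosine
similarity). Correlation of a constant vector and cosine of a zero vector
are errors, surfaced as degenerate configurations.

### Algorithm back-ends

* **Hierarchical**: scipy average linkage on the chosen metric, tree cut to
  K groups (`fcluster`, maxclust).
* **Kmeans**: in-package Lloyd iterations so that arbitrary metrics are
  supported, with metric-matched centroid updates — mean for squared
  Euclidean, per-dimension median for cityblock, member mean for
  correlation/cosine. Seeding is k-means++ under the configured metric,
  driven entirely by the stored per-config seed. Empty clusters are
  repaired by reassigning the point currently farthest from its centroid,
  preserving the requested K deterministically.
* **SOM**: in-package batch-trained 1×K line map (Gaussian neighborhood on
  the line, width decaying geometrically from K/2 to 0.5 over 40 epochs),
  Euclidean metric; best-matching-unit memberships are the clusters, and
  empty units simply reduce k_eff. A line topology makes unit count equal K.
* **Ncut**: scikit-learn spectral clustering on the precomputed affinity
  s(i,j) = exp(−d(i,j)²/σ²) with σ the median off-diagonal pairwise
  distance — a scale-free, self-tuning bandwidth. Fixed random_state and
  discretization make it deterministic across runs.
* **AP**: scikit-learn affinity propagation on negated distances, damping
  0.9, up to 1,000 iterations, preference set to the median similarity so K
  is emergent; non-convergence falls back to a single cluster (logged via
  the partition itself, k_eff = 1).

Seeds for the non-deterministic algorithms (Kmeans, SOM) are drawn once at
grid expansion and recorded in the run manifest, so any ensemble can be
rebuilt bit-for-bit; they deliberately vary across configs so the ensemble
is not locked into one local minimum.

## Enrichment

With N peptides in the dataset, K_label of them carrying a label, and k of a
cluster's n members carrying it, the enrichment p-value is the
hypergeometric upper tail P(X ≥ k). The background is always the full
dataset, including unannotated peptides. Only labels observed in a cluster
(k ≥ 1) generate records, but the BH family size m counts all tests
accumulated within one (clusterset, category) family across all clusters of
that set; correction is Benjamini–Hochberg at α = 0.05 (Bonferroni available
behind a flag). Annotation stringency filters (e.g. Scansite level ≤ 3,
domain p ≤ 1e-5) are applied to the input table before enrichment, with the
comparison direction configurable since predictor score conventions differ.

Four dynamic metrics — MinValue, MaxValue, MaxPosChange (largest consecutive
increase), MaxNegChange (largest-magnitude consecutive decrease) — are
computed on the untransformed data, discretized into dataset-wide quartile
bins, and enriched as ordinary categories. Quartiles are the parameter-free
choice for an unspecified binning; the binning is isolated behind
`dynamic_labels` so other schemes can be substituted. Constant statistics
collapse to a single bin with a warning.

## Parameter refinement

For each individual parameter value, all clustersets carrying it are removed
and the ensemble re-scored. "Total enrichment" is normalized per set — the
mean number of significant labels per clusterset — because removing sets
necessarily shrinks raw totals; the relative change of this mean is the
improvement measure. A parameter is pruned when removal improves the overall
mean by at least 2% and no single category's mean drops by more than 10%.
The default is a single pass (every parameter evaluated against the full
ensemble, qualifying parameters removed jointly); an iterative mode repeats
the pass on the survivors until fixed point. A removal that would empty the
ensemble aborts with a report instead of pruning. A category with zero
enrichment before and after removal contributes a delta of 0.

## Ensemble mining

* **Mutual information** between two partitions is computed from the joint
  co-membership distribution, I(X;Y) = Σ p(x,y) ln[p(x,y)/(p(x)p(y))], in
  nats (the base only matters comparatively). The diagonal of the MI matrix
  is the partition entropy; subset means (off-diagonal average within the
  sets sharing one parameter) quantify how strongly that parameter
  determines solution architecture.
* **Quartile analysis**: sets are ranked per metric by significant-label
  count (ties broken by set id), the top/bottom ceil(M/4) extracted, and
  each parameter tested for quartile overrepresentation with the same
  hypergeometric machinery (population = all sets), BH-corrected per metric.
* **Metric-overlap bootstrap**: the observed overlap of two metrics'
  quartiles is compared to a null built from 1,000 random same-size subset
  pairs, classified two-sided against the normal approximation of that null
  (the null mean converges to q²/M, the hypergeometric expectation).
* **Co-occurrence**: for each peptide pair, the number of clustersets in
  which they share a cluster; frequencies are counts/M, and heat-map export
  takes log10 after replacing zero frequencies by 0.5/M. The summary
  reports total pairs, never-co-clustering pairs and majority (freq > 0.5)
  pairs, percentages to one decimal.
* **Robust clusters**: seeded by an enriched label; the denominator is the
  number of sets in which that label is significant anywhere, and a peptide
  joins the group if it sits inside a label-enriched cluster in at least
  50% of those sets. The group is then re-tested for enrichment against the
  dataset as a single pseudo-cluster. Peptide-centric clusters collect
  everything co-clustering with a seed peptide at ≥ 50% frequency.
* **Cross-dataset comparison**: Pearson correlation of the upper-triangle
  co-occurrence frequencies over shared peptides; extreme differences are
  pairs moving from freq ≥ 0.75 in one ensemble to freq < 0.25 in the
  other, flagged in both directions.

## Synthetic data and controls

The generator emulates relative phosphorylation time courses: each planted
group has a positive temporal template (defaults: transient, sustained and
late-rising archetypes over a 0/5/10/30-minute course), and rows are the
template times i.i.d. log-normal noise exp(N(0, sd²)) — multiplicative noise
because the measurements are positive and ratio-scaled. Defaults are 77
peptides, 4 conditions, 3 balanced groups, sd = 0.1. Annotations plant one
label per (group, category) assigned within-group with probability 0.8
(0.9 in the strong-signal regression fixtures) over a background of 5
uniform labels per category at probability 0.05. What the generator does
*not* emulate: missing values, acquisition-dependent noise structure,
correlated annotations, or realistic label-set sizes — so passing tests
demonstrate the machinery's statistical behaviour, not performance on real
spectra.

Two randomization controls destroy structure while preserving marginals:
`shuffle_matrix` permutes all n×T values globally (the stronger null;
within-column mode available), and `shuffle_labels` applies a uniform random
bijection to the peptide column of the annotation table. Dynamic-metric
bins are computed on the original data *before* shuffling, so the control
measures false positives against fixed labels rather than re-deriving
labels from the randomized matrix. The empirical false-positive rate is the
pooled fraction of significant tests per category across repetitions; on
no-signal data with ten repetitions of a 132-configuration grid it stays
well below the BH α of 0.05 (typically ≤ 0.01).

## Problem sizes and determinism

The packaged experiments use a reduced but algorithm-complete grid (4
transforms × 3 distances × 5 algorithms × K ∈ {2,4,6} → 132 configurations)
and ten control repetitions on 77×4 data; the full 1,320-configuration grid
is expanded and counted exactly but clustered only on demand. Every random
choice — synthetic data, annotation draws, shuffles, k-means++/SOM
initialization, bootstrap draws — flows from explicit integer seeds, and
rebuilding an ensemble from its manifest seeds is bit-for-bit identical.

## Known limitations

* Affinity propagation occasionally fails to converge on pathological
  (e.g. heavily shuffled) data; the fallback single-cluster partition is
  conservative for enrichment (nothing can be enriched in one cluster).
* The SOM and k-means implementations are compact reference routines, not
  performance-tuned; for the dataset sizes this method targets (tens to a
  few hundred peptides) they are more than adequate.
* The 2%/10% pruning thresholds are configurable but the rule is greedy in
  parameter space; interactions between jointly-removed parameters are not
  re-evaluated in the default single pass (use `iterative=True` for a
  fixed-point variant).
* Enrichment treats labels within a category as exchangeable; hierarchical
  label structure (e.g. GO ancestry) is not modelled.
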