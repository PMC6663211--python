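# Methods

## Model and pipeline

`neuromapper` implements the Mapper construction for gene co-expression:
a dataset of brain tissue samples, each a z-scored gene-expression vector
with an ROI annotation, is summarized as the nerve of an overlapping cover.
The assumptions are minimal but worth stating:

- **Similarity is correlation.** Both the lens (sample × sample Pearson
  correlation PCA) and the per-bin clustering distance (1 − Pearson r on
  the full gene vectors) assume that co-expression — not expression
  magnitude — carries the anatomical signal. Z-scoring per gene makes this
  explicit.
- **Two filter dimensions suffice.** The cover is built on the top-2
  eigencomponents only. Structure orthogonal to that plane (e.g. a tissue
  class whose samples project onto another class's lens region) can be
  recovered by the in-bin clustering but not by the cover itself.
- **Equal-density windows.** Window positions are computed in rank
  (percentile) units, so every window holds a comparable number of samples
  regardless of how skewed the lens marginals are. A window of size *w*
  percent steps by *s = w(1 − o/100)*; the number of windows per dimension
  is *1 + ⌈(100 − w)/s⌉* and the union always covers [0, 100].

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_pct` (*w*) | 20 | window size, percentile units of each lens dimension |
| `overlap_pct` (*o*) | 40 | overlap between consecutive windows, % of the window |
| `min_cluster_size` | 3 | smallest sample set that can become a node |
| `clustering` | `linkage-gap` | per-bin clusterer (see below) |
| `gap_bins` | 10 | histogram resolution of the linkage-gap cut |
| selection `max_noise_fraction` | 0.2 | drop σ whose graphs leave > 20% of samples in no node |
| selection `top_k` | 4 | cap on the selected σ set, ranked by modularity |
| `dense_threshold` | 2 | agreement value above which a link counts as dense |

*w* and *o* are the method's true degrees of freedom; everything else is
plumbing. At zero overlap bins are disjoint and the graph has no edges; as
*o* → 100 the graph approaches a dense lattice. Published analyses of
atlas-scale data (~3,700 samples per hemisphere) use windows near 5%; the
defaults here are sized for the hundreds-of-samples datasets the synthetic
generators produce, so that a bin still holds enough samples to cluster.
Both are just grid choices — `sweep` + `select_optimal` exist precisely so
the scale is chosen by measured network quality (noise fraction, Pareto
front on noise vs modularity) rather than by hand.

## Per-bin clustering

The default clusterer cuts the **average-linkage dendrogram at the first
empty bin of its merge-height histogram** (`gap_bins` bins spanning
[0, max height]); if no interior bin is empty the whole bin is one cluster.
This is the classic Mapper clustering heuristic: a unimodal bin (one tissue
class, or a segment of a continuous gradient) shows no gap and stays whole,
while a bin straddling genuinely separated groups shows a gap in merge
heights and is split there. Clusters smaller than `min_cluster_size` become
bin noise.

Two alternatives are selectable: `density` (HDBSCAN on the precomputed
distance matrix) and `single-linkage` (fixed cut at `linkage_cut`). HDBSCAN
is not the default because density-mode extraction behaves poorly on the
bins this cover produces at moderate sample sizes: on unimodal or gradient
bins of 25–125 samples it either fragments them into many spurious leaf
clusters or discards most points as outliers (a 125-point Gaussian bin
yields ~20 "clusters"), disconnecting structures that are genuinely
contiguous. On large, strongly multimodal bins it behaves well, so it
remains available for atlas-scale data.

Constant sample vectors have undefined correlation; they are assigned
distance 1 (uncorrelated) to every other sample. Identical samples
(distance ~0 throughout the bin) short-circuit to a single cluster. All
tie-breaks — member ordering, cluster ordering, main-component choice, the
KS gap location — are fixed (sorted ids, smallest value) so every run is
deterministic; the modularity optimizer (networkx Louvain) is seeded.

## Data preparation

Z-scoring standardizes each gene with the sample standard deviation
(ddof = 1), by default **within each donor** before pooling, so that
donor-level offsets cannot masquerade as anatomy in the lens; the pooled
scope is available. Constant genes become all-zero columns and are flagged
rather than dropped, keeping gene indices stable. Probe-level atlas data
are collapsed to genes by the probe mean (or the maximum-variance probe);
unmapped probes are dropped and counted. Donor pooling intersects gene
sets and by default keeps left-hemisphere samples only, matching the
hemisphere with full atlas coverage. Missing values in generic input are
dropped (rows, then columns), never imputed.

## Aggregation, comparison, path analysis

The co-occurrence diagonal stores within-ROI *unordered* pair counts
m(m−1)/2, so every cell of the matrix is a pair count; a sample pair
sharing several nodes contributes once per node. The agreement matrix is
the elementwise mean over selected σ, masked to entries nonzero in every
contributing network — links must be reproduced at all selected scales.

The KS statistic is used descriptively (no p-value): D is the maximum gap
between the empirical CDFs of linked vs unlinked external values, and the
trade-off threshold τ is the location of that maximum (smallest value on
ties). With a log transform configured, τ lives on the log scale and e^τ
is the natural-scale threshold. Regimes use strict inequality for *dense*
(agreement > 2) and τ-inclusive *low* (value ≤ τ); a three-regime view
collapses {dense_low, sparse_low} → low.

Path distances are unweighted hops: seeds are the main-component nodes
containing seed-ROI samples, node distance is the BFS minimum over seeds,
and a sample's distance is the arithmetic mean over the main-component
nodes containing it (samples only in noise or minor components are
excluded and counted). ROIs are ranked by mean sample distance, ascending.

## Synthetic study conditions

The generators produce the three geometries the pipeline must resolve, all
pure functions of (spec, seed):

- `blocks` — 4 ROIs × 40 samples, 400 genes, 50 marker genes per block
  boosted by β = 2 over Gaussian noise σ = 1, z-scored. Emulates discrete
  tissue classes; ground truth supports ARI-based recovery checks.
- `chain` — 8 ROIs × 30 samples at latent positions r/8; each gene follows
  a sigmoid profile (random center, width 0.15, half rising half falling)
  scaled by β = 2 plus noise σ = 0.5. Sigmoids rather than linear ramps
  curve the lens genuinely into 2-D, exercising the cover; adjacent ROIs
  are most correlated, emulating an anatomical expression gradient.
- `lens_cloud` — raw 2-D point clouds (two Gaussian blobs at 10σ
  separation, or a unit circle with radial noise 0.05) fed directly to the
  cover/graph stage; clustering falls back to Euclidean distance in lens
  space since no expression exists.

What these do **not** emulate: donor batch effects, probe-level noise,
spatial autocorrelation of neighboring samples, heavy-tailed expression,
or the ~10× larger sample counts of real atlases. Passing tests therefore
demonstrate the machinery's correctness and its ability to recover planted
topology at realistic effect sizes — not performance on real microarray
data, whose scale and noise structure differ.

## Numerical and design notes

- Eigencomponents below 1e-12 × trace are treated as null; a similarity
  matrix of rank < 2 (all samples identical) is a fatal error. Component
  signs follow a fixed convention (largest-magnitude loading positive).
- The correlation lens normalizes each sample vector — a projective warp
  that slightly bends latent planes (canonical correlation ~0.9 on a clean
  2-D factor model, vs ~1.0 for the covariance lens). Correlation remains
  the default because it is robust to per-sample scale; the covariance
  lens is one flag away.
- A 2-D cover cannot produce literal path graphs from 1-D gradients: a
  sample in two windows per dimension lies in up to four bins, whose
  clusters form small cliques, so chain-like data yield long *thick* paths
  (interior node degrees 4–6). Elongation (graph diameter) and
  hop-distance gradients are the meaningful 1-D signatures.
- Sweep grids are configurable everywhere; the recorded selection policy
  (noise filter → Pareto(noise, modularity) → top-k by modularity,
  lexicographic tie-break) is deliberately simple, monotone, and
  order-invariant.

## Known limitations

- No persistent homology, weighted shortest paths, nonlinear lenses, or
  covers beyond 2-D.
- ROI labels are used verbatim; there is no ontology roll-up.
- The differential-expression and functional-connectivity matrices are
  consumed as inputs, not computed.
- Block recovery degrades gracefully but not uniformly across random
  seeds: occasional draws place two blocks so close in lens space that a
  shared bin shows no linkage gap and the components merge.
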