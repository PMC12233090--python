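# Methods

## Problem setting

scGT performs diagonal integration of two single-cell modalities measured on
different cells: a labeled scRNA-seq *reference* (gene expression counts)
and an unlabeled scATAC-seq *query* summarized as a gene activity matrix.
Both are genes x cells over a shared gene axis. The method produces a joint
low-dimensional embedding of all nR + nQ cells, a predicted cell type for
every query cell with a confidence score, and an optional "Unknown" call
for query cells whose confidence falls below a threshold.

## Preprocessing

Each dataset is restricted to the common genes (exact string match, sorted
lexicographically), LogNormalized (`x -> ln(1 + s * x / colsum)`, s = 10,000
— the conventional scale factor), and standardized per gene to zero mean and
unit population standard deviation **within its own dataset**. Per-dataset
standardization means a constant per-gene modality offset is largely removed
before any cross-dataset comparison; genes with zero variance become
all-zero rows. The same pipeline is applied to counts and to gene activity
scores.

## Hybrid graph

Three mutual-K-nearest-neighbor (MNN) edge sets are built in PCA coordinates
(Euclidean distance, exact neighbor search):

* **Inter-dataset edges A^RQ** via reciprocal PCA: a PCA is fitted on each
  dataset (cells as samples) and both datasets are projected into each
  fitted space; mutual-KNN pairs are collected in both coordinate systems
  and unioned. Union (rather than intersection) is used because the
  downstream filter exists precisely to remove unreliable pairs, so recall
  is preferred at this stage; intersection empirically retains too few
  pairs to align the datasets (tens instead of thousands at desk scale).
* **Intra-dataset edges A^RR, A^QQ** via each dataset's own PCA and
  mutual-KNN, self-neighbors excluded.

Defaults: 30 principal components, K = 5 for inter-dataset and K = 10 for
intra-dataset neighbors. Larger inter-K was not used because the MNN
mutuality requirement is the only guard against spurious cross-modality
pairs before filtering.

### Filtering inter-dataset connections

Intra-dataset neighborhoods are far more label-consistent than
cross-modality ones, so they are used to audit A^RQ:

1. every reference cell r gets a purity score `u_r` = fraction of its A^RR
   neighbors sharing its label (0 if isolated);
2. every query cell q gets an estimated type: per-type sums of `u_j` over
   its A^RQ neighbors, argmax wins; a zero maximum (in particular, no
   neighbors) yields "Unknown";
3. the estimate is smoothed by a plurality vote over each query cell's
   <=4-hop neighborhood in A^QQ. "Unknown" estimates vote as their own
   candidate: a query region whose initial estimates are mostly Unknown is
   the signature of a cell type absent from the reference, and propagating
   that status protects novel clusters from being absorbed into a reference
   type through spurious cross-dataset pairs. Ties are broken in favor of
   real types, then by the sorted type ordering, for determinism;
4. an edge (i, j) survives only if the reference label of i equals the
   refined estimate of j; edges to "Unknown" cells are dropped.

The hybrid graph A^H is the union of the filtered inter edges and both
intra edge sets over nR + nQ nodes (reference block first), each edge tagged
with its provenance.

## Network

* **Encoder**: one fully connected layer (common genes -> d_enc = 256) with
  an ELU nonlinearity (flaggable to identity), applied to the
  column-concatenation [X^R, X^Q].
* **Two kernelized Gumbel-Softmax attention layers** (256 -> 64 -> 64).
  Each layer computes queries/keys/values q, k, v by linear maps and
  outputs, per cell i, a *global* term — softmax-kernel attention over all
  cells approximated with m_rf = 35 positive random features
  `phi(x) = exp(-||x||^2/2) / sqrt(m_rf) * exp(W_rf x)` (W_rf rows i.i.d.
  N(0, I), drawn once per model and fixed) — plus a *local* term
  `sigmoid(beta) * sum of v_j over hybrid-graph neighbors` (unnormalized
  sum as printed; a degree-normalization flag exists). The factorization
  through the two cached sums `sum_j w_j phi(k_j) v_j^T` and
  `sum_j w_j phi(k_j)` keeps the cost linear in cell count; no n x n matrix
  is formed. During training the per-source weights `w_j = e^{g_j / tau}`
  use one fresh standard-Gumbel draw per source cell per layer per forward
  pass (one shared draw vector, as forced by the factorization); at
  inference g = 0, making the forward pass deterministic. Temperature
  tau = 0.25. Exponent shifts that provably cancel in the numerator/
  denominator ratio (a per-query-cell shift and one global key-side shift)
  keep all exponentials finite; a 1e-8 floor guards the denominator.
* **Classifier**: a single affine layer from the 64-dimensional embedding
  to the |T_R| type logits, followed by a column-stabilized softmax.
  The classifier weights are **zero-initialized** so the initial
  probabilities are exactly uniform. This matters because the
  confidence-gated promotion mechanism (below) must not latch onto the
  arbitrarily confident predictions a randomly initialized linear head
  produces on a large-magnitude embedding.

Confidence of a query cell is the maximum of its probability column; the
predicted type is the argmax (ties to the smallest type index). With an
unknown-threshold set (0.9 in the rejection analyses), cells below it are
reported as "Unknown".

## Losses and training

The total loss is the unweighted sum of:

* **Hard regularization**: mean over filtered inter pairs of the squared
  embedding distance divided by the embedding dimension, minus a relaxation
  epsilon = 0.1, clamped at zero. Identically zero when no pairs survive
  filtering.
* **Cross-entropy** over the supervised set, which starts as the reference
  cells with their true labels.
* **Query graph regularization**: penalizes predicted-type disagreement
  across A^QQ edges, relaxed by epsilon = 0.1. The printed form uses a 0/1
  agreement indicator whose gradient vanishes almost everywhere; training
  therefore backpropagates the agreement-probability surrogate
  `sum_t P_{t,i} P_{t,j}` (equal to the indicator for one-hot columns),
  while the indicator form is computed and logged each epoch.

**Promotion** (optional, on by default): once per epoch, query cells whose
inference-mode confidence exceeds 0.95 are added to the supervised set with
their predicted label; labels of previously promoted cells are refreshed to
the current prediction, reference labels are never touched, and the set
never shrinks.

Optimization is full-graph Adam (learning rate 1e-3, beta = (0.9, 0.999)),
with L2 weight decay 5e-4 added to the gradient, for 300 epochs by default.
All randomness (initialization, Gumbel draws) derives from a single seed;
two runs with the same seed produce identical outputs. A non-finite loss
aborts with a message naming the offending term.

## Metrics

All metrics use Euclidean distance on the joint embedding (cells as rows),
not a UMAP reduction, to avoid extra stochasticity.

* **Silhouette F1**: harmonic mean of the modality-mixing term
  `1 - (1 + Sil_omic)/2` and the biological-separation term
  `(1 + Sil_celltype)/2`, each silhouette being the standard mean
  silhouette under the respective labeling. Undefined (NaN, with a warning)
  when a labeling has a single class.
* **MAP**: for each cell, the precision accumulated at every type-matched
  rank among its W = 30 ordered nearest neighbors, averaged over matched
  ranks (0 if none match), then averaged over cells.
* **Cell-type ASW**: (mean cell-type silhouette + 1) / 2.
* **Label transfer accuracy**: exact-match fraction over query cells; in
  corrected mode, ground-truth labels absent from the reference type set
  are first mapped to "Unknown" so that rejecting a reference-absent type
  counts as correct.
* **Confusion matrix**: rows are true types, columns predicted, each
  nonempty row normalized to sum to 1.

## Synthetic data generator

The generator emulates the structure the method is designed for: two
modalities sharing latent cluster structure with a modality-specific
distribution shift, configurable type overlap, and realistic count noise.

Per-type mean programs live on the log scale: a shared per-gene baseline
(N(0.7, 0.4)) plus a *marker program* — a sparse direction supported on a
random `de_fraction` = 20% subset of genes with random signs and magnitudes,
normalized to unit Euclidean norm and scaled by `cluster_separation` = 16.
Concentrating the signal on marker-gene subsets mirrors how real cell types
differ (a moderate number of strong markers rather than a diffuse shift
across all genes); with the defaults a marker gene carries a log-fold-change
of roughly 1.5-3.5. The query modality adds a per-gene offset drawn
N(0, 0.3) to all its cells. Per-cell log-means receive N(0, 0.3) jitter,
counts are negative binomial with dispersion 0.5 (var = mu + 0.5 mu^2), and
entries are randomly zeroed to an exact target sparsity (60% reference, 65%
query), emulating dropout in gene-level summaries over an informative
panel. Defaults: 800 cells per modality, 200 genes, four equally frequent
types. `ref_only_types` / `query_only_types` remove types from one modality
to create mismatched-type scenarios.

What the generator does **not** emulate: peak-level ATAC structure,
doublets, batch effects beyond the single modality shift, gene-gene
correlation beyond the cluster programs, and transcriptome-scale gene
counts. Passing tests on these data demonstrate the machinery recovers
planted structure under count noise and modality shift; they do not certify
performance on real tissues.

## Problem sizes and numerical choices

Desk-scale defaults were chosen so a full integration (graph construction
plus 300 training epochs at 1,600 cells x 200 genes) completes in well
under a minute on one CPU core, and the full recovery study (five seeds)
in a few minutes. Exact brute-force neighbor search is used throughout
(no approximate indices); randomized solvers are avoided in PCA (full SVD)
so results are bit-reproducible given the seed. Ties in argmax operations
resolve to the smallest index everywhere. The attention denominator is
floored at 1e-8; cross-entropy probabilities at 1e-12.

## Known limitations

* The filter cannot re-label a novel-type query region as a reference type
  correctly by construction (it has no notion of types outside T_R); its
  job is only to drop inconsistent cross-modality edges. When spurious
  cross-modality pairs concentrate on one reference type, the 4-hop vote
  can still assign a novel cluster that type and retain those edges;
  the Unknown-vote rule mitigates but does not eliminate this at desk
  scale.
* Confidence-based unknown rejection is sensitive to training duration:
  shared-type confidence sharpens with epochs while reference-absent
  clusters can also gain confidence if they retain cross-modality edges.
* Full-graph training holds the dense standardized matrix and all
  intermediates in memory; the implementation targets datasets up to
  roughly 10^5 cells and does not provide minibatch neighbor sampling.
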