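# Methods

This note records the model, the numerical choices and the known
limitations of graphfuse, in the order the pipeline runs.

## Data model and alignment

The unit of input is one omics layer: a real-valued samples × features
matrix with unique sample and feature ids and a positive loss weight. A
dataset is a list of layers over one shared sample axis plus an optional
label map. Alignment restricts all layers (and the label table) to their
common samples and re-orders them lexicographically by sample id, so
every downstream matrix is reproducible regardless of input file order.
Layer weights default to equal shares and are normalized to sum to one.

Missing values are rejected at load time; an explicit per-feature median
imputation flag exists because silently imputed values would distort the
distance kernels downstream. An optional per-feature z-score flag is
provided but off by default — the pipeline is scale-sensitive by design
(the sensitivity score is proportional to feature standard deviation),
and rescaling is a modeling decision the user should make knowingly.

## Multi-modal autoencoder

Architecture, per layer `v` of width `d_v`: input → one hidden ReLU layer
of width `clip(d_v/4, L, 512)` → linear map into the shared latent space
of dimension `L`; the per-layer contributions are summed to form the
latent code, and each decoder mirrors its encoder from that same code.
This is the smallest architecture with one shared latent layer and one
nonlinear stage per branch; summation of linearly mapped branch outputs
is equivalent to concatenation followed by one linear mixing layer.

The loss is the weighted sum of per-layer mean squared reconstruction
errors with weights summing to one. Optimization is Adam (lr 1e-3,
default 100 epochs, mini-batches of 64, shuffled by a seeded generator);
all gradients are hand-derived NumPy, which keeps the package free of
deep-learning framework dependencies and makes training bit-reproducible
from the seed on a fixed platform. Training raises immediately, naming
the epoch, if the loss goes non-finite. A `loss_weights` override allows
zero weights (e.g. to ablate one layer's objective) even though dataset
layer weights must be strictly positive.

Defaults: latent dimension 100, checkpoint every 10 epochs, top 100
features per checkpoint. A latent dimension at or above the narrowest
layer's width triggers a warning rather than an error — the code is then
not compressive for that layer but the model is still well-defined.

### Sensitivity analysis

The importance of input feature `i` of one layer is
`S_i = σ_i · Σ_j |W_ij|`, where `σ_i` is the standard deviation of the
raw input column and `W` is that layer's first (input → hidden) encoder
weight matrix — the only weights directly connected to input nodes.
Scores are snapshotted on the checkpoint schedule (plus the final epoch
when it is not a multiple of the interval). Per checkpoint the top-N
feature ids are taken with ties broken by (score descending, feature id
ascending); the union over checkpoints is the stable set, ordered by
(number of checkpoints selected, best score, feature id). `S_i` is
deliberately scale-covariant: multiplying a feature's column by `c > 0`
multiplies its score by `c` (weights fixed).

Whether importance should be read from encoder or decoder weights is an
open modeling choice; the first encoder layer is used here because it is
the only layer whose rows are indexed by input features.

## Similarity network fusion

Per view, the affinity is `W(i,j) = exp(−ρ² / (µ ε_ij))` with Euclidean
distance ρ and local scale
`ε_ij = (mean ρ(x_i, N_i) + mean ρ(x_j, N_j) + ρ(x_i, x_j)) / 3`, where
`N_i` are the K nearest neighbors of `i` (self excluded; distance ties
broken by sample order). The diagonal is exactly 1; `ε` is floored at
1e-12 with a warning when duplicate samples would make it 0.
Defaults: µ = 0.5, K = max(n/10, 10) capped at n−1.

Two kernels follow: the full status kernel
`P(i,j) = W(i,j) / (2 Σ_{k≠i} W(i,k))` off the diagonal with `P(i,i) = ½`
(rows sum to exactly 1), and the sparse kernel `S` supported on the K
nearest neighbors with rows summing to 1. The off-diagonal mass is summed
directly over the off-diagonal entries; subtracting the unit diagonal
from the row sum loses all precision when the similarities are below
machine epsilon relative to 1, which happens routinely for
high-dimensional layers.

Fusion uses the synchronous m-view update — each view's status matrix is
diffused against the average of the other views' current matrices through
its own sparse kernel — which reduces exactly to the alternating two-view
scheme at m = 2. After each update, matrices are averaged with their
transpose and renormalized back to the P form (off-diagonal mass ½,
diagonal ½). Iteration stops at `t_max` (default 20) or when the largest
entrywise change drops below `tol` (1e-6); the change norms are recorded.
A single view is returned unchanged.

Exact symmetry and exact row-stochasticity cannot hold simultaneously for
a generic matrix, so the final fused output — the average of the status
matrices — is symmetrized exactly, at the cost of row sums holding only
approximately (typically within a few percent near convergence). Symmetry
was prioritized because the GCN's adjacency normalization requires a
symmetric input; tests assert exact symmetry and approximate row sums.

### Evaluating cluster separation

`between_within_ratio` reports mean between-cluster over mean
within-cluster similarity (lower = better separation). With `top_k` set
it is measured on the realized network — each node's `top_k` strongest
edges, symmetrized by maximum — rather than the dense matrix. This
distinction matters: fusing an informative view with a pure-noise view
concentrates the signal in the strong edges while the dense bulk of the
diffused matrix stays diffuse, so fusion beats naive kernel averaging on
the realized network (the claim the tests check, at `top_k = K`) but not
on the dense-bulk mean. The dense-bulk behavior is a known limitation of
the diffusion when one view is entirely uninformative.

## Graph convolutional classifier

`H^(l+1) = σ(L H^(l) W^(l))` with ReLU between layers and softmax on the
output; `L` is `D̃^{−1/2}ÃD̃^{−1/2}` (default) or `D̃^{−1}Ã` with
`Ã = A + I`. The fused PSN is used as a dense weighted adjacency (its
diagonal is zeroed first; self-connections enter only through the `+I`);
optional top-k-per-row sparsification (symmetrized by maximum) is
available but off by default. Depth is 2 convolutions (hidden width 64).
Node features are z-scored by default so the learning rate is meaningful
regardless of embedding scale.

Training: Adam, lr 1e-2, L2 weight decay 5e-4 on weights (not biases),
up to 200 epochs with early stopping after 30 epochs without training
loss improvement. Dropout is available (inverted, seeded) but defaults to
0 — at the cohort sizes targeted here, weight decay suffices and a
0-default keeps evaluation variance down. Plain cross-entropy is the
default; inverse-frequency class weighting is available for imbalanced
cohorts. The loss is computed strictly on the training mask, so held-out
labels cannot influence the fit — perturbing test-fold labels provably
leaves predictions unchanged, and a test asserts exactly that.

## Cross-validation protocol

Labeled samples are split randomly (optionally stratified) into folds of
sizes differing by at most one. The protocol is transductive: the
autoencoder and fusion are unsupervised, see all samples in every fold,
and are therefore computed once and shared across folds — mathematically
identical to refitting them per fold and about tenfold cheaper. Only the
GCN is refit per fold with the fold masked out of its loss. This mirrors
the semi-supervised graph setting but differs from strictly inductive
cross-validation: the unsupervised stages do see the test samples'
features (never their labels). Accuracy and F1 (weighted by default,
macro always reported alongside) are aggregated as mean ± standard
deviation over folds, not over pooled predictions.

The ablation runner repeats cross-validation with identical fold plans
and seeds for the full model, latent features with an edgeless graph
(`ae_only`), and one-hot node features with the fused graph (`snf_only`).

## Synthetic cohorts

Classes are centroids in a latent space of true dimension 8; each
sample's latent vector is `signal_strength ×` its class centroid plus
unit Gaussian latent noise; a layer's informative features are a random
linear map (columns scaled by 1/√latent_dim) of the latent vector plus
Gaussian observation noise, and its remaining features are independent
standard normal. The standard benchmark is n = 300 with class mix
22/10/49/19 % and layers of 500/400/60 features with 20/20/10 informative
(signal 2.0, noise 1.0, seed 7) — the class imbalance and extreme layer
width disparity of a typical multi-omics subtype cohort at a size that
keeps the full pipeline in seconds.

What passing on this generator does and does not show: the data are
Gaussian, low-rank and linearly generated, so they exercise the
machinery (shared-latent compression, cluster geometry, graph + feature
complementarity, imbalance) but not the discreteness of copy-number
calls, heavy-tailed expression, batch effects, or missingness of real
cohorts. Results on it are a correctness check, not a performance claim
for real data.

## Determinism

Every stochastic component (init, batch shuffling, fold assignment,
dropout) draws from `numpy` generators seeded from explicit config
fields; stage seeds are derived through `SeedSequence`. The full pipeline
writes byte-identical numeric artifacts across repeated runs with the
same configuration and data on the same platform; only the timing log
differs. Problem sizes used in the test suite: the benchmark cohort
(n = 300) for end-to-end checks and a smaller planted cohort (n = 120,
signal 4.0) for fast unit-level pipeline tests.

## Known limitations

- The dense fused matrix's bulk retains noise-view diffuseness (above);
  interpret the PSN through its strong edges.
- Fused row sums are approximate (symmetry is exact instead).
- No inductive inference: classifying a new patient requires re-running
  fusion and training with that patient in the graph.
- No GPU path; the NumPy implementation targets cohort sizes in the
  hundreds to low thousands.
- The synthetic generator makes no attempt to mimic CNV discreteness or
  protein-array dynamic ranges.
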