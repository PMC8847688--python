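# graphfuse

Multi-omics integration for cancer-subtype classification. graphfuse
combines two complementary reductions of a sample-aligned multi-omics
cohort — a **multi-modal autoencoder** that compresses all omics layers
into one shared latent embedding, and **similarity network fusion (SNF)**
that merges per-layer patient similarity networks into one fused patient
network — and feeds both into a **graph convolutional network (GCN)** for
semi-supervised, multi-class subtype classification. Sensitivity analysis
on the trained autoencoder surfaces the features driving each layer's
representation, and the fused patient similarity network (PSN) can be
exported for visualization in Cytoscape.

It is written for computational biologists who have two or more omics
matrices (e.g. CNV, mRNA, protein array) over a common patient cohort with
subtype labels for some or all patients, and who want a classifier whose
decisions can be inspected through both a patient network and ranked
feature lists.

## Model

**Autoencoder.** One encoder/decoder per omics layer `X_v`, all sharing a
single latent space of dimension `L`; encoder outputs are linearly mapped
into the common space and summed. Training minimizes the weighted joint
reconstruction loss

```
E = Σ_v w_v · MSE(X_v, g_v(f(X_1 … X_m))),     Σ_v w_v = 1,
```

with Adam on hand-written NumPy gradients. Feature importance uses
sensitivity analysis: `S_i = σ_i · Σ_j |W_ij|`, the feature's standard
deviation times the summed absolute first-layer weights leaving it,
snapshotted every `checkpoint_interval` epochs; the per-checkpoint top-N
sets are merged into a stable feature set.

**SNF.** Per layer, a scaled exponential affinity
`W(i,j) = exp(−ρ²(x_i,x_j) / (µ ε_ij))` with Euclidean ρ and a local scale
`ε_ij` built from K-nearest-neighbor distances; from it a full
row-stochastic status kernel `P` (diagonal ½) and a sparse K-nearest
kernel `S`. Fusion cross-diffuses each view's status matrix through the
others,

```
P(v) ← S(v) · ( mean_{k≠v} P(k) ) · S(v)ᵀ,
```

until convergence, and averages the final status matrices into one fused
network.

**GCN.** Each layer propagates node features through the normalized
adjacency operator with self-loops, `H^(l+1) = σ(L H^(l) W^(l))` with
`L = D̃^{−1/2} Ã D̃^{−1/2}` or `D̃^{−1} Ã`, `Ã = A + I`. The fused PSN is
the graph, the latent embedding the node features. Training is
transductive: all nodes propagate, only training-mask nodes enter the
cross-entropy loss.

Evaluation is 10-fold cross-validation reporting accuracy
(trace of the confusion matrix over its total) and F1 (harmonic mean of
precision and recall per class, weighted and macro), as fold-level
mean ± standard deviation.

## Worked example

`examples/04_full_pipeline_cv.py` builds the standard synthetic benchmark
(300 samples, four imbalanced subtypes in a 22/10/49/19 % mix, three
layers of 500/400/60 features with 20/20/10 planted informative features)
and cross-validates the pipeline and its ablation arms:

```
full pipeline 10-fold CV: accuracy 0.9933 +- 0.0141, F1(weighted) 0.9929
full     : accuracy 0.9933 +- 0.0141
ae_only  : accuracy 0.9900 +- 0.0161
snf_only : accuracy 0.9533 +- 0.0281
```

The combined model matches or beats both single-input arms (`ae_only` =
latent features with an edgeless graph, `snf_only` = one-hot features
with the fused graph), showing the embedding and the network carry
complementary signal. `examples/02_autoencoder_features.py` prints the
planted-feature recovery of the sensitivity analysis:

```
omics_wide: stable set 31 features, recovered 20/20 planted
omics_mid: stable set 29 features, recovered 19/20 planted
omics_narrow: stable set 28 features, recovered 10/10 planted
```

The other examples cover cohort simulation (`01`) and network fusion with
Cytoscape export (`03`).

## Command line

Every stage is also a subcommand of the `graphfuse` CLI:

```sh
graphfuse simulate --seed 7 --out data/
graphfuse run-all --data data/omics_wide.tsv --data data/omics_mid.tsv \
    --data data/omics_narrow.tsv --labels data/labels.tsv \
    --folds 10 --seed 0 --out run/
```

`run-all` writes the embedding, fused network (matrix, edge list,
GraphML), predictions, feature report, CV table and the exact
configuration into the output directory. Individual stages (`ae`, `snf`,
`gcn`, `cv`, `ablate`, `export-graph`) run the same library calls on
precomputed inputs.

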