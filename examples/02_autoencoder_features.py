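"""Train the multi-modal autoencoder and recover planted features.

One encoder/decoder per omics layer, all sharing one latent space; the
training objective is the weighted sum of per-layer reconstruction
errors.  Every 10 epochs the sensitivity score S_i = sigma_i * sum|W_ij|
of each input feature is snapshotted; the per-checkpoint top-25 sets are
merged into a stable feature set per layer.
"""

import warnings

from graphfuse import AEConfig, generate_dataset, standard_benchmark_config, train_autoencoder

warnings.filterwarnings("ignore", message="latent_dim")

dataset, truth = generate_dataset(standard_benchmark_config(seed=7))
config = AEConfig(latent_dim=100, epochs=100, checkpoint_interval=10, top_n=25,
                  seed=0)
embedding, report, loss_trace = train_autoencoder(dataset, config)

print(f"latent embedding: {embedding.values.shape[0]} samples x "
      f"{embedding.latent_dim} dims")
print(f"reconstruction loss: {loss_trace[0]:.3f} -> {loss_trace[-1]:.3f} "
      f"over {len(loss_trace)} epochs")
for layer in dataset.layers:
    stable = set(report.stable_ids(layer.name))
    planted = set(truth.informative_features[layer.name])
    hit = len(stable & planted)
    print(f"{layer.name}: stable set {len(stable)} features, "
          f"recovered {hit}/{len(planted)} planted")

# A recovery near 100% means the sensitivity analysis ranked the features
# that actually carry subtype signal above the pure-noise background.
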