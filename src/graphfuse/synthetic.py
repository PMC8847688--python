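"""Synthetic multi-omics datasets with planted subtype structure.

The generator emulates the statistical shape of a multi-omics cancer
cohort: a few imbalanced subtypes, several layers of very different
widths, and in each layer a small planted set of informative features.
Classes live as centroids in a low-dimensional latent space; each
sample's latent vector is its class centroid scaled by the signal
strength plus unit latent noise; a layer's informative features are a
random linear map of that latent vector plus Gaussian observation noise,
and its remaining features are pure standard-normal noise.  This minimal
Gaussian linear-map model exercises the autoencoder (low-rank
structure), the network fusion (cluster geometry) and the graph
classifier (graph + features) at once.

The default class mix (22/10/49/19 %) mirrors a typical four-subtype
breast-cancer cohort so imbalance handling is always exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import MultiOmicsDataset, OmicsLayer

__all__ = [
    "LayerSpec",
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_noise_view",
    "standard_benchmark_config",
]

DEFAULT_PROPORTIONS = (0.22, 0.10, 0.49, 0.19)


@dataclass
class LayerSpec:
    """Shape of one synthetic omics layer."""

    n_features: int
    n_informative: int
    signal_strength: float = 2.0
    noise_sd: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("need 0 <= n_informative <= n_features")
        if self.noise_sd < 0 or self.signal_strength < 0:
            raise ValueError("signal_strength and noise_sd must be nonnegative")


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort."""

    n_samples: int = 300
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    layer_specs: list[LayerSpec] = field(
        default_factory=lambda: [
            LayerSpec(500, 20, name="omics_wide"),
            LayerSpec(400, 20, name="omics_mid"),
            LayerSpec(60, 10, name="omics_narrow"),
        ]
    )
    latent_dim_true: int = 8
    seed: int = 7

    def __post_init__(self) -> None:
        if len(self.class_proportions) < 1:
            raise ValueError("need at least one class")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not self.layer_specs:
            raise ValueError("need at least one layer spec")
        if self.n_samples < 1 or self.latent_dim_true < 1:
            raise ValueError("n_samples and latent_dim_true must be positive")


@dataclass
class GroundTruth:
    """What was planted: informative feature ids per layer and true classes."""

    informative_features: dict[str, list[str]]
    class_of: dict[str, int]
    class_names: list[str]
    latent: np.ndarray


def standard_benchmark_config(seed: int = 7) -> SynthConfig:
    """The standard benchmark: n=300, four imbalanced classes, three
    layers of 500/400/60 features with 20/20/10 informative, signal 2.0,
    noise 1.0."""
    return SynthConfig(
        n_samples=300,
        class_proportions=DEFAULT_PROPORTIONS,
        layer_specs=[
            LayerSpec(500, 20, 2.0, 1.0, name="omics_wide"),
            LayerSpec(400, 20, 2.0, 1.0, name="omics_mid"),
            LayerSpec(60, 10, 2.0, 1.0, name="omics_narrow"),
        ],
        latent_dim_true=8,
        seed=seed,
    )


def generate_dataset(config: SynthConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw one synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    C = len(config.class_proportions)
    y = rng.choice(C, size=n, p=np.asarray(config.class_proportions))
    centroids = rng.normal(size=(C, config.latent_dim_true))
    sample_ids = [f"S{i:04d}" for i in range(n)]
    class_names = [f"subtype_{chr(ord('A') + c)}" for c in range(C)]

    m = len(config.layer_specs)
    layers: list[OmicsLayer] = []
    informative: dict[str, list[str]] = {}
    latent_by_layer = {}
    for li, spec in enumerate(config.layer_specs):
        name = spec.name or f"omics_{li + 1}"
        # per-layer latent realization: shared centroids, fresh latent noise
        Z = spec.signal_strength * centroids[y] + rng.normal(
            size=(n, config.latent_dim_true)
        )
        latent_by_layer[name] = Z
        A = rng.normal(size=(config.latent_dim_true, spec.n_informative))
        A /= np.sqrt(config.latent_dim_true)
        X = rng.normal(size=(n, spec.n_features))  # pure-noise background
        cols = rng.choice(spec.n_features, size=spec.n_informative, replace=False)
        cols = np.sort(cols)
        signal = Z @ A
        if spec.noise_sd > 0:
            signal = signal + rng.normal(scale=spec.noise_sd, size=signal.shape)
        X[:, cols] = signal
        feature_ids = [f"{name}_f{j:05d}" for j in range(spec.n_features)]
        layers.append(
            OmicsLayer(
                name=name,
                matrix=X,
                sample_ids=sample_ids,
                feature_ids=feature_ids,
                weight=1.0 / m,
            )
        )
        informative[name] = [feature_ids[j] for j in cols]

    labels = {sid: int(c) for sid, c in zip(sample_ids, y)}
    dataset = MultiOmicsDataset(layers=layers, labels=labels, class_names=class_names)
    truth = GroundTruth(
        informative_features=informative,
        class_of=labels,
        class_names=class_names,
        latent=centroids,
    )
    return dataset, truth


def generate_noise_view(n: int, d: int, seed: int = 0, name: str = "noise") -> OmicsLayer:
    """An i.i.d. standard-normal layer carrying no class signal."""
    rng = np.random.default_rng(seed)
    return OmicsLayer(
        name=name,
        matrix=rng.normal(size=(n, d)),
        sample_ids=[f"S{i:04d}" for i in range(n)],
        feature_ids=[f"{name}_f{j:05d}" for j in range(d)],
        weight=1.0,
    )
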