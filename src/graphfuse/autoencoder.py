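"""Multi-modal autoencoder with shared latent space and sensitivity analysis.

One encoder/decoder pair per omics layer; all encoders feed a single
latent representation (their outputs are summed after a linear map into
the common L-dimensional space) and every decoder reads that same latent
vector.  Training minimizes the weighted sum of per-layer mean-squared
reconstruction errors

    E = sum_v  w_v * MSE(X_v, g_v(f(X_1..X_m)))     with  sum_v w_v = 1,

by Adam on hand-written gradients.  Feature importance is scored by
sensitivity analysis: the importance of input feature i of a layer is its
standard deviation times the summed absolute first-layer weights leaving
it, S_i = sigma_i * sum_j |W_ij|.  Scores are checkpointed every few
epochs and the per-checkpoint top-N sets are merged into a stable feature
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import MultiOmicsDataset

__all__ = [
    "AEConfig",
    "LatentEmbedding",
    "StableFeature",
    "FeatureScoreReport",
    "TrainingError",
    "sensitivity_scores",
    "extract_stable_features",
    "train_autoencoder",
]


class TrainingError(RuntimeError):
    """Raised when the optimization produces a non-finite loss."""


@dataclass
class AEConfig:
    """Hyperparameters of the multi-modal autoencoder.

    ``hidden_dims`` lists one hidden width per layer; ``None`` picks
    ``clip(d_v // 4, latent_dim, 512)`` for each layer — the smallest
    architecture honoring one hidden level between input and the shared
    latent code.  ``checkpoint_interval`` is the number of epochs between
    sensitivity-score snapshots and ``top_n`` the number of features kept
    per snapshot per layer.
    """

    latent_dim: int = 100
    hidden_dims: list[int] | None = None
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    checkpoint_interval: int = 10
    top_n: int = 100

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("latent_dim, epochs and batch_size must be positive")
        if self.checkpoint_interval < 1 or self.checkpoint_interval > self.epochs:
            raise ValueError("checkpoint_interval must be in [1, epochs]")
        if self.top_n < 1:
            raise ValueError("top_n must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class LatentEmbedding:
    """Shared latent codes: one L-dimensional vector per sample."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sample_ids):
            raise ValueError("embedding must be n_samples x L")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding contains non-finite values")

    @property
    def latent_dim(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        cols = [f"z{j}" for j in range(self.latent_dim)]
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=cols)
        df.index.name = "sample_id"
        return df


@dataclass
class StableFeature:
    """One feature of the merged stable set."""

    feature_id: str
    checkpoints_selected: int
    best_rank: int  # 1-based, best rank over the checkpoints where selected
    best_score: float
    mean_score: float


@dataclass
class FeatureScoreReport:
    """Per-layer sensitivity scores per checkpoint plus the stable sets.

    ``checkpoint_scores[layer]`` is a (n_checkpoints, n_features) array;
    ``stable_sets[layer]`` the merged ranking.  The stable set can hold at
    most ``top_n * n_checkpoints`` features and only ids of its layer.
    """

    feature_ids: dict[str, list[str]]
    checkpoint_scores: dict[str, np.ndarray]
    checkpoint_epochs: list[int]
    stable_sets: dict[str, list[StableFeature]] = field(default_factory=dict)

    def stable_ids(self, layer: str) -> list[str]:
        return [f.feature_id for f in self.stable_sets[layer]]

    def to_frame(self):
        import pandas as pd

        rows = []
        for layer, feats in self.stable_sets.items():
            for f in feats:
                rows.append(
                    {
                        "layer": layer,
                        "feature_id": f.feature_id,
                        "mean_score": f.mean_score,
                        "best_rank": f.best_rank,
                        "checkpoints_selected": f.checkpoints_selected,
                    }
                )
        return pd.DataFrame(rows)


def sensitivity_scores(layer_weights: np.ndarray, feature_stddevs: np.ndarray) -> np.ndarray:
    """Importance S_i = sigma_i * sum_j |W_ij| of each input feature.

    ``layer_weights`` is the first (input -> hidden) weight matrix of one
    layer's encoder, rows indexed by input features; ``feature_stddevs``
    are the standard deviations of the raw input columns.
    """
    W = np.asarray(layer_weights, dtype=float)
    sigma = np.asarray(feature_stddevs, dtype=float)
    if W.ndim != 2 or sigma.ndim != 1 or W.shape[0] != sigma.shape[0]:
        raise ValueError(
            f"weight matrix rows ({W.shape}) must match stddev length ({sigma.shape})"
        )
    return sigma * np.abs(W).sum(axis=1)


def _top_n_indices(scores: np.ndarray, feature_ids: list[str], top_n: int) -> list[int]:
    # deterministic: score descending, then feature id ascending
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], feature_ids[i]))
    return order[:top_n]


def extract_stable_features(
    checkpoint_scores: np.ndarray | list[np.ndarray],
    feature_ids: list[str],
    top_n: int,
) -> list[StableFeature]:
    """Merge per-checkpoint top-N selections into the stable feature set.

    Per checkpoint the ``top_n`` highest-scoring features are taken (ties
    broken by feature id); the union is returned sorted by (selection
    count desc, best score desc, feature id asc).
    """
    scores = np.atleast_2d(np.asarray(checkpoint_scores, dtype=float))
    if scores.shape[0] < 1:
        raise ValueError("need at least one checkpoint")
    d = scores.shape[1]
    if len(feature_ids) != d:
        raise ValueError("feature_ids length does not match score vectors")
    if top_n > d:
        warnings.warn(f"top_n={top_n} exceeds {d} features; using all {d}")
        top_n = d
    count = np.zeros(d, dtype=int)
    best_rank = np.full(d, d + 1, dtype=int)
    for ck in scores:
        chosen = _top_n_indices(ck, feature_ids, top_n)
        for rank, idx in enumerate(chosen, start=1):
            count[idx] += 1
            best_rank[idx] = min(best_rank[idx], rank)
    selected = np.nonzero(count)[0]
    feats = [
        StableFeature(
            feature_id=feature_ids[i],
            checkpoints_selected=int(count[i]),
            best_rank=int(best_rank[i]),
            best_score=float(scores[:, i].max()),
            mean_score=float(scores[:, i].mean()),
        )
        for i in selected
    ]
    feats.sort(key=lambda f: (-f.checkpoints_selected, -f.best_score, f.feature_id))
    return feats


# ---------------------------------------------------------------------------
# network internals (NumPy, hand-written gradients)
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Adam:
    """Minimal Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _MultiModalAE:
    """Parameters and forward/backward passes of the shared-latent AE."""

    def __init__(self, dims: list[int], hidden: list[int], latent: int,
                 rng: np.random.Generator):
        self.dims, self.hidden, self.latent = dims, hidden, latent
        self.enc_W1 = [_glorot(rng, d, h) for d, h in zip(dims, hidden)]
        self.enc_b1 = [np.zeros(h) for h in hidden]
        self.enc_W2 = [_glorot(rng, h, latent) for h in hidden]
        self.enc_b2 = [np.zeros(latent) for _ in hidden]
        self.dec_W1 = [_glorot(rng, latent, h) for h in hidden]
        self.dec_b1 = [np.zeros(h) for h in hidden]
        self.dec_W2 = [_glorot(rng, h, d) for d, h in zip(dims, hidden)]
        self.dec_b2 = [np.zeros(d) for d in dims]

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for group in (self.enc_W1, self.enc_b1, self.enc_W2, self.enc_b2,
                      self.dec_W1, self.dec_b1, self.dec_W2, self.dec_b2):
            out.extend(group)
        return out

    def encode(self, Xs: list[np.ndarray]) -> np.ndarray:
        z = np.zeros((Xs[0].shape[0], self.latent))
        for v, X in enumerate(Xs):
            h = np.maximum(X @ self.enc_W1[v] + self.enc_b1[v], 0.0)
            z += h @ self.enc_W2[v] + self.enc_b2[v]
        return z

    def loss_and_grads(
        self, Xs: list[np.ndarray], weights: np.ndarray
    ) -> tuple[float, list[float], list[np.ndarray]]:
        """Weighted reconstruction loss, per-layer losses and gradients.

        Returns gradients in the same order as :meth:`parameters`.
        """
        m = len(Xs)
        B = Xs[0].shape[0]
        # forward
        enc_h = []
        z = np.zeros((B, self.latent))
        for v in range(m):
            h = np.maximum(Xs[v] @ self.enc_W1[v] + self.enc_b1[v], 0.0)
            enc_h.append(h)
            z += h @ self.enc_W2[v] + self.enc_b2[v]
        dec_h, recon = [], []
        for v in range(m):
            h = np.maximum(z @ self.dec_W1[v] + self.dec_b1[v], 0.0)
            dec_h.append(h)
            recon.append(h @ self.dec_W2[v] + self.dec_b2[v])
        layer_losses = [float(np.mean((recon[v] - Xs[v]) ** 2)) for v in range(m)]
        total = float(np.dot(weights, layer_losses))
        # backward
        g_enc_W1 = [np.zeros_like(p) for p in self.enc_W1]
        g_enc_b1 = [np.zeros_like(p) for p in self.enc_b1]
        g_enc_W2 = [np.zeros_like(p) for p in self.enc_W2]
        g_enc_b2 = [np.zeros_like(p) for p in self.enc_b2]
        g_dec_W1 = [np.zeros_like(p) for p in self.dec_W1]
        g_dec_b1 = [np.zeros_like(p) for p in self.dec_b1]
        g_dec_W2 = [np.zeros_like(p) for p in self.dec_W2]
        g_dec_b2 = [np.zeros_like(p) for p in self.dec_b2]
        dz = np.zeros_like(z)
        for v in range(m):
            d_out = weights[v] * 2.0 * (recon[v] - Xs[v]) / recon[v].size
            g_dec_W2[v] = dec_h[v].T @ d_out
            g_dec_b2[v] = d_out.sum(axis=0)
            dh = (d_out @ self.dec_W2[v].T) * (dec_h[v] > 0)
            g_dec_W1[v] = z.T @ dh
            g_dec_b1[v] = dh.sum(axis=0)
            dz += dh @ self.dec_W1[v].T
        for v in range(m):
            g_enc_W2[v] = enc_h[v].T @ dz
            g_enc_b2[v] = dz.sum(axis=0)
            dh = (dz @ self.enc_W2[v].T) * (enc_h[v] > 0)
            g_enc_W1[v] = Xs[v].T @ dh
            g_enc_b1[v] = dh.sum(axis=0)
        grads: list[np.ndarray] = []
        for group in (g_enc_W1, g_enc_b1, g_enc_W2, g_enc_b2,
                      g_dec_W1, g_dec_b1, g_dec_W2, g_dec_b2):
            grads.extend(group)
        return total, layer_losses, grads


def _default_hidden(d: int, latent: int) -> int:
    return int(np.clip(d // 4, latent, 512))


def train_autoencoder(
    dataset: MultiOmicsDataset,
    config: AEConfig | None = None,
    *,
    loss_weights: list[float] | None = None,
) -> tuple[LatentEmbedding, FeatureScoreReport, list[float]]:
    """Fit the multi-modal autoencoder and score features along the way.

    Returns the latent codes after the final epoch, the feature report
    built from the checkpoint schedule, and the per-epoch weighted loss
    trace.  Deterministic given ``config.seed``.  ``loss_weights``
    overrides the dataset's layer weights (must be nonnegative, sum 1);
    a zero weight removes that layer's reconstruction from the objective
    while its encoder still feeds the shared latent space.
    """
    config = config or AEConfig()
    layers = dataset.layers
    Xs = [layer.matrix for layer in layers]
    dims = [X.shape[1] for X in Xs]
    n = dataset.n_samples
    if loss_weights is not None:
        weights = np.asarray(loss_weights, dtype=float)
        if weights.shape != (len(layers),) or (weights < 0).any():
            raise ValueError("loss_weights must be one nonnegative value per layer")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("loss_weights must sum to 1")
    else:
        weights = np.array([layer.weight for layer in layers])
    if config.latent_dim >= min(dims):
        warnings.warn(
            f"latent_dim={config.latent_dim} is not smaller than the narrowest "
            f"layer (width {min(dims)}); the code is not compressive there"
        )
    hidden = config.hidden_dims or [_default_hidden(d, config.latent_dim) for d in dims]
    if len(hidden) != len(layers):
        raise ValueError("hidden_dims must list one width per layer")

    rng = np.random.default_rng(config.seed)
    model = _MultiModalAE(dims, hidden, config.latent_dim, rng)
    opt = _Adam(model.parameters(), lr=config.learning_rate)
    stddevs = [X.std(axis=0) for X in Xs]

    checkpoint_epochs: list[int] = []
    ck_scores: dict[str, list[np.ndarray]] = {layer.name: [] for layer in layers}
    loss_trace: list[float] = []
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch = [X[idx] for X in Xs]
            loss, _, grads = model.loss_and_grads(batch, weights)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.step(grads)
            epoch_loss += loss
            n_batches += 1
        loss_trace.append(epoch_loss / n_batches)
        if epoch % config.checkpoint_interval == 0 or epoch == config.epochs:
            if epoch not in checkpoint_epochs:
                checkpoint_epochs.append(epoch)
                for v, layer in enumerate(layers):
                    ck_scores[layer.name].append(
                        sensitivity_scores(model.enc_W1[v], stddevs[v])
                    )

    embedding = LatentEmbedding(values=model.encode(Xs), sample_ids=dataset.sample_ids)
    report = FeatureScoreReport(
        feature_ids={layer.name: layer.feature_ids for layer in layers},
        checkpoint_scores={k: np.array(v) for k, v in ck_scores.items()},
        checkpoint_epochs=checkpoint_epochs,
    )
    for layer in layers:
        report.stable_sets[layer.name] = extract_stable_features(
            report.checkpoint_scores[layer.name], layer.feature_ids, config.top_n
        )
    return embedding, report, loss_trace
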