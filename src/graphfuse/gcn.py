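"""Semi-supervised node classification on the patient similarity network.

Each graph-convolution layer propagates node features through a
normalized adjacency operator before its linear transform,

    H^(l+1) = sigma( L H^(l) W^(l) ),      H^(0) = X,

with L = D~^{-1/2} A~ D~^{-1/2} (symmetric mode) or D~^{-1} A~
(random-walk mode), A~ = A + I.  Training is transductive: every node
participates in propagation, but the cross-entropy loss is computed on
the training mask only, so held-out labels never touch the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autoencoder import LatentEmbedding, TrainingError, _Adam, _glorot
from .snf import FusedNetwork

__all__ = [
    "GCNConfig",
    "NodeClassification",
    "normalize_adjacency",
    "sparsify_adjacency",
    "gcn_forward",
    "train_gcn",
]


@dataclass
class GCNConfig:
    """Hyperparameters of the graph convolutional classifier."""

    hidden_dims: list[int] = field(default_factory=lambda: [64])
    laplacian_mode: str = "symmetric"  # or "random_walk"
    dropout: float = 0.0
    epochs: int = 200
    learning_rate: float = 1e-2
    weight_decay: float = 5e-4
    seed: int = 0
    adjacency_sparsify_k: int | None = None
    patience: int | None = 30  # early stop after this many non-improving epochs
    class_weighting: str | None = None  # None (plain CE) or "balanced"
    standardize_features: bool = True

    def __post_init__(self) -> None:
        if not self.hidden_dims:
            raise ValueError("need at least one graph-conv layer")
        if self.laplacian_mode not in ("symmetric", "random_walk"):
            raise ValueError("laplacian_mode must be 'symmetric' or 'random_walk'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class NodeClassification:
    """Per-node class probabilities and argmax predictions."""

    class_probabilities: np.ndarray
    predicted: np.ndarray
    train_mask: np.ndarray
    test_mask: np.ndarray | None = None
    sample_ids: list[str] | None = None
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        rows = self.class_probabilities.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")


def normalize_adjacency(A: np.ndarray, mode: str = "symmetric") -> np.ndarray:
    """Normalized propagation operator of the graph with self-loops added.

    Returns D~^{-1/2} (A+I) D~^{-1/2} (``symmetric``) or D~^{-1} (A+I)
    (``random_walk``), where D~ holds the row sums of A+I.  Self-loops
    guarantee positive degrees.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    A_tilde = A + np.eye(n)
    deg = A_tilde.sum(axis=1)
    if mode == "symmetric":
        d = 1.0 / np.sqrt(deg)
        return (A_tilde * d[:, None]) * d[None, :]
    if mode == "random_walk":
        return A_tilde / deg[:, None]
    raise ValueError("mode must be 'symmetric' or 'random_walk'")


def sparsify_adjacency(A: np.ndarray, k: int) -> np.ndarray:
    """Keep each row's k largest off-diagonal weights, then symmetrize.

    Symmetrization is by elementwise maximum, so a kept edge keeps its
    weight even when only one endpoint selected it.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    out = np.zeros_like(A)
    for i in range(n):
        row = A[i].copy()
        row[i] = -np.inf
        top = np.argsort(-row, kind="stable")[:k]
        out[i, top] = A[i, top]
    return np.maximum(out, out.T)


def gcn_forward(
    L: np.ndarray,
    X: np.ndarray,
    weights: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Forward pass of the stacked graph-conv layers; returns logits.

    ``weights`` lists one ``(W, b)`` pair per layer.  ReLU between
    layers, linear output (softmax is applied by the caller).  With
    L = I this is exactly a multilayer perceptron on X.
    """
    H = np.asarray(X, dtype=float)
    n_layers = len(weights)
    for li, (W, b) in enumerate(weights):
        if H.shape[1] != W.shape[0]:
            raise ValueError(
                f"layer {li}: features of width {H.shape[1]} vs weight rows {W.shape[0]}"
            )
        H = L @ H @ W + b
        if li < n_layers - 1:
            H = np.maximum(H, 0.0)
    return H


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def train_gcn(
    embedding: LatentEmbedding | np.ndarray,
    network: FusedNetwork | np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    config: GCNConfig | None = None,
    n_classes: int | None = None,
) -> NodeClassification:
    """Fit the GCN transductively and classify every node.

    ``labels`` is an int array over the sample axis (-1 for unlabeled);
    only ``train_mask`` nodes contribute to the loss.  Returns class
    probabilities for all nodes.  Deterministic given ``config.seed``.
    """
    config = config or GCNConfig()
    sample_ids = None
    if isinstance(embedding, LatentEmbedding):
        sample_ids = embedding.sample_ids
        X = embedding.values
    else:
        X = np.asarray(embedding, dtype=float)
    if isinstance(network, FusedNetwork):
        A = network.P_fused
        if sample_ids is None:
            sample_ids = network.sample_ids
    else:
        A = np.asarray(network, dtype=float)
    labels = np.asarray(labels, dtype=int)
    train_mask = np.asarray(train_mask, dtype=bool)
    n = X.shape[0]
    if A.shape[0] != n or labels.shape[0] != n or train_mask.shape[0] != n:
        raise ValueError("features, graph, labels and mask must share the sample axis")
    if (labels[train_mask] < 0).any():
        raise ValueError("train_mask selects unlabeled nodes")

    C = n_classes if n_classes is not None else int(labels.max()) + 1
    present = set(np.unique(labels[train_mask]).tolist())
    missing = sorted(set(range(C)) - present)
    if missing:
        warnings.warn(f"classes {missing} absent from the training mask")

    if config.standardize_features:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - mean) / std
    if config.adjacency_sparsify_k is not None:
        A = sparsify_adjacency(A, config.adjacency_sparsify_k)
    A = A.copy()
    np.fill_diagonal(A, 0.0)  # self-connections are added by normalization
    L = normalize_adjacency(A, config.laplacian_mode)

    rng = np.random.default_rng(config.seed)
    dims = [X.shape[1], *config.hidden_dims, C]
    Ws = [_glorot(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
    bs = [np.zeros(b) for b in dims[1:]]
    opt = _Adam(Ws + bs, lr=config.learning_rate)

    y_train = labels[train_mask]
    if config.class_weighting == "balanced":
        counts = np.bincount(y_train, minlength=C).astype(float)
        counts[counts == 0] = 1.0
        cw = y_train.size / (C * counts)
    else:
        cw = np.ones(C)
    node_w = cw[y_train]
    node_w = node_w / node_w.sum()

    n_layers = len(Ws)
    loss_trace: list[float] = []
    best_loss = np.inf
    stall = 0
    for epoch in range(1, config.epochs + 1):
        # forward with cached activations
        Hs = [X]
        drop_masks = []
        H = X
        for li in range(n_layers):
            if config.dropout > 0:
                keep = rng.random(H.shape) >= config.dropout
                H = H * keep / (1.0 - config.dropout)
                drop_masks.append(keep)
            else:
                drop_masks.append(None)
            H = L @ H @ Ws[li] + bs[li]
            if li < n_layers - 1:
                H = np.maximum(H, 0.0)
            Hs.append(H)
        probs = _softmax(Hs[-1])
        p_train = probs[train_mask]
        ce = -np.log(np.clip(p_train[np.arange(y_train.size), y_train], 1e-12, None))
        loss = float(node_w @ ce)
        loss += 0.5 * config.weight_decay * sum(float((W**2).sum()) for W in Ws)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        loss_trace.append(loss)

        # backward: gradients only flow from train-mask nodes
        dZ = np.zeros_like(probs)
        grad_logits = probs[train_mask].copy()
        grad_logits[np.arange(y_train.size), y_train] -= 1.0
        dZ[train_mask] = grad_logits * node_w[:, None]
        gWs: list[np.ndarray] = [None] * n_layers  # type: ignore[list-item]
        gbs: list[np.ndarray] = [None] * n_layers  # type: ignore[list-item]
        dH = dZ
        for li in range(n_layers - 1, -1, -1):
            H_in = Hs[li]
            if li < n_layers - 1:
                dH = dH * (Hs[li + 1] > 0)
            if drop_masks[li] is not None:
                H_in = H_in * drop_masks[li] / (1.0 - config.dropout)
            LH = L @ H_in
            gWs[li] = LH.T @ dH + config.weight_decay * Ws[li]
            gbs[li] = dH.sum(axis=0)
            dH = L.T @ (dH @ Ws[li].T)
            if drop_masks[li] is not None:
                dH = dH * drop_masks[li] / (1.0 - config.dropout)
        opt.step(gWs + gbs)

        if loss < best_loss - 1e-6:
            best_loss = loss
            stall = 0
        else:
            stall += 1
            if config.patience is not None and stall >= config.patience:
                break

    logits = gcn_forward(L, X, list(zip(Ws, bs)))
    probs = _softmax(logits)
    return NodeClassification(
        class_probabilities=probs,
        predicted=probs.argmax(axis=1),
        train_mask=train_mask,
        sample_ids=sample_ids,
        loss_trace=loss_trace,
    )
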