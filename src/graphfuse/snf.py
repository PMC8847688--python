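"""Similarity network fusion: per-view patient kernels and cross-diffusion.

Each omics view yields a scaled-exponential affinity

    W(i,j) = exp( -rho^2(x_i, x_j) / (mu * eps_ij) ),

where rho is the Euclidean distance and eps_ij is the local-scale term
(mean distance of i to its K nearest neighbors, likewise for j, plus
rho(i,j), averaged).  From W two row-stochastic kernels follow: the full
status kernel P (off-diagonal mass 1/2, diagonal 1/2) and the K-nearest
sparse kernel S supported on each sample's neighborhood.  Fusion
cross-diffuses every view's status matrix through the others,

    P^(v)  <-  S^(v) ( mean_{k != v} P^(k) ) S^(v)^T ,

iterating until the matrices stop changing, and averages the final
status matrices into one fused patient similarity network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AffinityMatrix",
    "TransitionKernel",
    "FusedNetwork",
    "affinity_matrix",
    "transition_kernels",
    "diffusion_step",
    "snf_fuse",
    "fuse_views",
    "between_within_ratio",
    "default_k",
]

_EPS_FLOOR = 1e-12


def default_k(n: int) -> int:
    """Default neighborhood size: max(n // 10, 10), capped at n - 1."""
    return min(max(n // 10, 10), n - 1)


@dataclass
class AffinityMatrix:
    """Scaled-exponential similarity matrix of one view."""

    W: np.ndarray
    mu: float
    K: int
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("affinity must be square")
        if not np.allclose(self.W, self.W.T, atol=1e-10):
            raise ValueError("affinity must be symmetric")
        if not np.allclose(np.diagonal(self.W), 1.0):
            raise ValueError("affinity diagonal must be 1 (zero self-distance)")
        if (self.W <= 0).any() or (self.W > 1 + 1e-12).any():
            raise ValueError("affinity entries must lie in (0, 1]")

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class TransitionKernel:
    """Row-stochastic kernels P (full) and S (K-nearest) of one view."""

    P: np.ndarray
    S: np.ndarray
    neighbors: list[np.ndarray]
    sample_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class FusedNetwork:
    """Fused patient similarity network (symmetric, nonnegative)."""

    P_fused: np.ndarray
    iterations_run: int
    change_norms: list[float] = field(default_factory=list)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.P_fused = np.asarray(self.P_fused, dtype=float)
        if not np.isfinite(self.P_fused).all():
            raise ValueError("fused network contains non-finite values")

    @property
    def n(self) -> int:
        return self.P_fused.shape[0]


def affinity_matrix(
    X: np.ndarray,
    mu: float = 0.5,
    K: int | None = None,
    *,
    precomputed_distances: bool = False,
    sample_ids: list[str] | None = None,
) -> AffinityMatrix:
    """Build the scaled-exponential affinity of one view.

    ``X`` is a samples x features matrix, or a precomputed symmetric
    distance matrix when ``precomputed_distances=True``.  ``K`` controls
    the local scale (and downstream neighborhoods); defaults to
    :func:`default_k`.  Identical samples would drive the scale to zero,
    so it is floored with a warning.
    """
    X = np.asarray(X, dtype=float)
    if precomputed_distances:
        dist = X
        if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T, atol=1e-10):
            raise ValueError("precomputed distances must be square symmetric")
    else:
        dist = cdist(X, X, metric="euclidean")
    n = dist.shape[0]
    if mu <= 0:
        raise ValueError("mu must be positive")
    if K is None:
        K = default_k(n)
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must be in [1, n-1]; got K={K}, n={n}")
    # mean distance of each sample to its K nearest neighbors (self excluded)
    sorted_d = np.sort(dist, axis=1)[:, 1 : K + 1]
    mean_knn = sorted_d.mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + dist) / 3.0
    if (eps <= _EPS_FLOOR).any():
        warnings.warn("duplicate or near-identical samples; flooring local scale")
        eps = np.maximum(eps, _EPS_FLOOR)
    W = np.exp(-(dist**2) / (mu * eps))
    np.fill_diagonal(W, 1.0)
    W = (W + W.T) / 2.0
    return AffinityMatrix(W=W, mu=mu, K=K, sample_ids=sample_ids)


def transition_kernels(affinity: AffinityMatrix) -> TransitionKernel:
    """Derive the full (P) and K-nearest (S) row-stochastic kernels.

    P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k)) off the diagonal and 1/2 on
    it, so every row sums to exactly 1.  S(i,j) = W(i,j) / sum_{k in N_i}
    W(i,k) on the K nearest neighbors of i (self excluded, distance ties
    broken by sample order) and 0 elsewhere.
    """
    W = affinity.W
    n = affinity.n
    K = affinity.K
    # sum off-diagonal entries directly: subtracting the unit diagonal from
    # the row sum cancels catastrophically when similarities are tiny
    W_off = W.copy()
    np.fill_diagonal(W_off, 0.0)
    off_mass = W_off.sum(axis=1)
    if (off_mass <= 0).any():
        bad = int(np.nonzero(off_mass <= 0)[0][0])
        raise ValueError(f"sample {bad} has zero off-diagonal affinity (disconnected)")
    P = W_off / (2.0 * off_mass[:, None])
    np.fill_diagonal(P, 0.5)

    S = np.zeros_like(W)
    neighbors: list[np.ndarray] = []
    for i in range(n):
        w = W[i].copy()
        w[i] = -np.inf  # exclude self
        # argsort ascending on -w: ties broken by index order (stable)
        nbr = np.argsort(-w, kind="stable")[:K]
        nbr = np.sort(nbr)
        neighbors.append(nbr)
        S[i, nbr] = W[i, nbr] / W[i, nbr].sum()
    return TransitionKernel(P=P, S=S, neighbors=neighbors, sample_ids=affinity.sample_ids)


def _p_normalize(M: np.ndarray) -> np.ndarray:
    """Renormalize a status matrix to the P form of the kernel definition:
    off-diagonal row mass 1/2, diagonal 1/2."""
    off = M.copy()
    np.fill_diagonal(off, 0.0)
    mass = off.sum(axis=1)
    mass[mass <= 0] = 1.0
    out = off / (2.0 * mass[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def diffusion_step(Ps: list[np.ndarray], Ss: list[np.ndarray]) -> list[np.ndarray]:
    """One raw cross-diffusion update, before any renormalization.

    Each view's status matrix becomes S^(v) (mean of the other views'
    status matrices) S^(v)^T; with two views this is exactly the
    alternating two-view scheme.
    """
    m = len(Ps)
    out = []
    for v in range(m):
        others = sum(Ps[j] for j in range(m) if j != v) / (m - 1)
        out.append(Ss[v] @ others @ Ss[v].T)
    return out


def snf_fuse(
    kernels: list[TransitionKernel],
    t_max: int = 20,
    tol: float = 1e-6,
) -> FusedNetwork:
    """Cross-diffuse the views' status matrices into one fused network.

    Synchronous update: every view's status matrix is diffused against
    the average of the other views' current matrices through its own
    K-nearest kernel.  With two views this is exactly the alternating
    two-view scheme.  After each update the matrices are renormalized to
    the P form and averaged with their transpose.  Iteration stops at
    ``t_max`` or when the largest entrywise change drops below ``tol``.
    The output is the average of the final status matrices, symmetrized.
    A single view is returned unchanged (no diffusion partner).
    """
    m = len(kernels)
    if m == 0:
        raise ValueError("need at least one kernel")
    n = kernels[0].n
    for k in kernels[1:]:
        if k.n != n:
            raise ValueError("kernels must share one sample axis")
    if m == 1:
        return FusedNetwork(
            P_fused=kernels[0].P.copy(),
            iterations_run=0,
            change_norms=[],
            sample_ids=kernels[0].sample_ids,
        )
    Ps = [k.P.copy() for k in kernels]
    Ss = [k.S for k in kernels]
    change_norms: list[float] = []
    iterations = 0
    for _ in range(t_max):
        new_Ps = [
            _p_normalize((Pn + Pn.T) / 2.0) for Pn in diffusion_step(Ps, Ss)
        ]
        delta = max(float(np.abs(a - b).max()) for a, b in zip(new_Ps, Ps))
        Ps = new_Ps
        change_norms.append(delta)
        iterations += 1
        if delta < tol:
            break
    fused = sum(Ps) / m
    fused = (fused + fused.T) / 2.0
    return FusedNetwork(
        P_fused=fused,
        iterations_run=iterations,
        change_norms=change_norms,
        sample_ids=kernels[0].sample_ids,
    )


def between_within_ratio(
    M: np.ndarray, labels: np.ndarray, top_k: int | None = None
) -> float:
    """Mean between-cluster over mean within-cluster similarity; lower is
    better separation.

    With ``top_k`` the ratio is measured on the realized network — each
    node's ``top_k`` strongest edges, symmetrized by maximum — rather
    than the dense matrix bulk, since fusion concentrates its signal in
    the strong connections it keeps.
    """
    M = np.asarray(M, dtype=float).copy()
    labels = np.asarray(labels)
    np.fill_diagonal(M, 0.0)
    if top_k is not None:
        kept = np.zeros_like(M)
        for i in range(M.shape[0]):
            idx = np.argsort(-M[i], kind="stable")[:top_k]
            kept[i, idx] = M[i, idx]
        M = np.maximum(kept, kept.T)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    within = M[same].mean()
    between = M[~same].mean()
    if within <= 0:
        raise ValueError("no within-cluster similarity mass")
    return float(between / within)


def fuse_views(
    views: list[np.ndarray],
    mu: float = 0.5,
    K: int | None = None,
    t_max: int = 20,
    tol: float = 1e-6,
    sample_ids: list[str] | None = None,
) -> FusedNetwork:
    """Convenience wrapper: affinity -> kernels -> fusion for raw views."""
    kernels = [
        transition_kernels(affinity_matrix(X, mu=mu, K=K, sample_ids=sample_ids))
        for X in views
    ]
    return snf_fuse(kernels, t_max=t_max, tol=tol)
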