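"""Metrics and the 10-fold cross-validation harness.

Accuracy is the fraction of samples judged correctly (trace of the
confusion matrix over its total); the F1 score is the harmonic mean of
precision and recall per class, aggregated macro or weighted by class
frequency.  Cross-validation is transductive: the unsupervised stages
(autoencoder, similarity network fusion) see all samples in every fold —
only the classifier's loss is masked — matching the semi-supervised
graph setting.  Aggregates are means and standard deviations over folds,
not pooled predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autoencoder import AEConfig, train_autoencoder
from .data_io import MultiOmicsDataset
from .gcn import GCNConfig, train_gcn
from .snf import fuse_views

__all__ = [
    "FoldPlan",
    "CVResult",
    "PipelineConfig",
    "confusion_matrix",
    "accuracy",
    "f1_score",
    "make_fold_plan",
    "cross_validate",
    "run_ablation",
    "ABLATION_ARMS",
]

ABLATION_ARMS = ("full", "ae_only", "snf_only")


@dataclass
class PipelineConfig:
    """Everything needed to run autoencoder -> fusion -> classifier once."""

    ae: AEConfig = field(default_factory=AEConfig)
    gcn: GCNConfig = field(default_factory=GCNConfig)
    snf_mu: float = 0.5
    snf_k: int | None = None
    snf_t_max: int = 20
    snf_tol: float = 1e-6
    mode: str = "full"  # full | ae_only | snf_only

    def __post_init__(self) -> None:
        if self.mode not in ABLATION_ARMS:
            raise ValueError(f"mode must be one of {ABLATION_ARMS}")


@dataclass
class FoldPlan:
    """Partition of the labeled samples into near-equal folds."""

    assignments: dict[str, int]
    n_folds: int
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]


@dataclass
class CVResult:
    """Per-fold accuracy and F1 with fold-level mean and standard deviation."""

    fold_accuracy: list[float]
    fold_f1_weighted: list[float]
    fold_f1_macro: list[float]
    metadata: dict = field(default_factory=dict)

    def _agg(self, values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values)
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    @property
    def accuracy_mean(self) -> float:
        return self._agg(self.fold_accuracy)[0]

    @property
    def accuracy_std(self) -> float:
        return self._agg(self.fold_accuracy)[1]

    @property
    def f1_weighted_mean(self) -> float:
        return self._agg(self.fold_f1_weighted)[0]

    @property
    def f1_weighted_std(self) -> float:
        return self._agg(self.fold_f1_weighted)[1]

    @property
    def f1_macro_mean(self) -> float:
        return self._agg(self.fold_f1_macro)[0]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "fold": range(len(self.fold_accuracy)),
                "accuracy": self.fold_accuracy,
                "f1_weighted": self.fold_f1_weighted,
                "f1_macro": self.fold_f1_macro,
            }
        )
        return df


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """Counts[i, j] = samples of true class i predicted as class j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    out = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(out, (y_true, y_pred), 1)
    return out


def accuracy(confusion: np.ndarray) -> float:
    """Proportion of all samples judged correctly: trace / total."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if confusion.size == 0 or total <= 0:
        raise ValueError("confusion matrix is empty")
    if (confusion < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    return float(np.trace(confusion) / total)


def f1_score(confusion: np.ndarray, averaging: str = "weighted") -> float:
    """Harmonic mean of per-class precision and recall, aggregated.

    Per class c: precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R) (0 when P+R = 0).  ``averaging`` is ``"macro"``
    (unweighted class mean) or ``"weighted"`` (by true class frequency).
    """
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if confusion.size == 0 or total <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diagonal(confusion)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    if averaging == "macro":
        return float(f1.mean())
    if averaging == "weighted":
        support = confusion.sum(axis=1)
        return float((f1 * support).sum() / support.sum())
    raise ValueError("averaging must be 'macro' or 'weighted'")


def make_fold_plan(
    dataset: MultiOmicsDataset,
    n_folds: int = 10,
    seed: int = 0,
    stratified: bool = False,
) -> FoldPlan:
    """Randomly partition the labeled samples into ``n_folds`` subsets.

    Fold sizes differ by at most one.  ``stratified=True`` deals each
    class round-robin across folds instead of a plain random split.
    """
    labeled = [s for s in dataset.sample_ids if s in dataset.labels]
    if len(labeled) < n_folds:
        raise ValueError(f"{len(labeled)} labeled samples cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    if stratified:
        fold_cursor = 0
        for c in range(dataset.n_classes):
            members = [s for s in labeled if dataset.labels[s] == c]
            rng.shuffle(members)
            for s in members:
                assignments[s] = fold_cursor % n_folds
                fold_cursor += 1
    else:
        shuffled = list(labeled)
        rng.shuffle(shuffled)
        for i, s in enumerate(shuffled):
            assignments[s] = i % n_folds
    return FoldPlan(assignments=assignments, n_folds=n_folds, seed=seed)


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def compute_stage_inputs(
    dataset: MultiOmicsDataset, config: PipelineConfig, seed: int
):
    """Run the unsupervised stages once: AE embedding and fused network.

    Returns (features, adjacency) for the classifier according to the
    pipeline mode: the ablation arms replace the graph by an edgeless one
    (``ae_only``) or the node features by one-hot indicators
    (``snf_only``).
    """
    n = dataset.n_samples
    ae_seed, _ = _sub_seeds(seed, 2)
    features = None
    adjacency = None
    embedding = None
    report = None
    fused = None
    if config.mode in ("full", "ae_only"):
        ae_cfg = replace(config.ae, seed=ae_seed)
        embedding, report, _ = train_autoencoder(dataset, ae_cfg)
        features = embedding.values
    else:
        features = np.eye(n)
    if config.mode in ("full", "snf_only"):
        fused = fuse_views(
            [layer.matrix for layer in dataset.layers],
            mu=config.snf_mu,
            K=config.snf_k,
            t_max=config.snf_t_max,
            tol=config.snf_tol,
            sample_ids=dataset.sample_ids,
        )
        adjacency = fused.P_fused
    else:
        adjacency = np.zeros((n, n))
    return features, adjacency, embedding, report, fused


def cross_validate(
    dataset: MultiOmicsDataset,
    config: PipelineConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    stratified: bool = False,
    fold_plan: FoldPlan | None = None,
) -> CVResult:
    """K-fold cross-validation of the full pipeline.

    Each fold's samples are masked out of the classifier loss and scored
    on the trained model; the unsupervised stages are shared across folds
    (they are label-free and identical in every fold).  Fully
    reproducible from ``seed``.
    """
    config = config or PipelineConfig()
    if not dataset.labels:
        raise ValueError("cross-validation requires labels")
    plan = fold_plan or make_fold_plan(dataset, n_folds, seed, stratified)
    features, adjacency, *_ = compute_stage_inputs(dataset, config, seed)
    labels = dataset.label_array()
    sid_index = {s: i for i, s in enumerate(dataset.sample_ids)}
    C = dataset.n_classes
    gcn_seeds = _sub_seeds(seed + 1, plan.n_folds)

    fold_acc, fold_f1w, fold_f1m = [], [], []
    for fold in range(plan.n_folds):
        test_idx = np.array([sid_index[s] for s in plan.fold_ids(fold)], dtype=int)
        train_mask = labels >= 0
        train_mask[test_idx] = False
        gcn_cfg = replace(config.gcn, seed=gcn_seeds[fold])
        result = train_gcn(features, adjacency, labels, train_mask, gcn_cfg, n_classes=C)
        conf = confusion_matrix(labels[test_idx], result.predicted[test_idx], C)
        fold_acc.append(accuracy(conf))
        fold_f1w.append(f1_score(conf, "weighted"))
        fold_f1m.append(f1_score(conf, "macro"))
    return CVResult(
        fold_accuracy=fold_acc,
        fold_f1_weighted=fold_f1w,
        fold_f1_macro=fold_f1m,
        metadata={
            "n_folds": plan.n_folds,
            "seed": seed,
            "mode": config.mode,
            "stratified": stratified,
            "f1_default_averaging": "weighted",
        },
    )


def run_ablation(
    dataset: MultiOmicsDataset,
    config: PipelineConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> dict[str, CVResult]:
    """Cross-validate the full model and both single-input arms.

    All three arms share one fold plan and seed so differences reflect
    the inputs, not the split: ``full`` = AE features + fused graph,
    ``ae_only`` = AE features + edgeless graph, ``snf_only`` = one-hot
    features + fused graph.
    """
    config = config or PipelineConfig()
    plan = make_fold_plan(dataset, n_folds, seed)
    results = {}
    for arm in ABLATION_ARMS:
        arm_cfg = replace(config, mode=arm)
        results[arm] = cross_validate(
            dataset, arm_cfg, n_folds=n_folds, seed=seed, fold_plan=plan
        )
    return results
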