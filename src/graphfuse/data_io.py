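"""Reading, aligning and exporting sample-aligned omics tables.

The unit of multi-view input is the :class:`OmicsLayer`: one named
samples x features matrix with a loss weight.  A :class:`MultiOmicsDataset`
holds several layers over one shared, canonically ordered sample axis plus
optional class labels.  Patient similarity networks are exported through
:class:`LabeledGraph` as GraphML or a Cytoscape-importable weighted edge
list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "OmicsLayer",
    "MultiOmicsDataset",
    "LabeledGraph",
    "load_omics_table",
    "load_labels",
    "align_dataset",
    "export_graph",
    "write_omics_table",
]


@dataclass
class OmicsLayer:
    """One omics data type: a real-valued samples x features matrix.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"CNV"``, ``"mRNA"``, ``"RPPA"``.
    matrix
        ``(n_samples, n_features)`` float array with no missing values.
    sample_ids, feature_ids
        Ordered, unique row and column identifiers.
    weight
        Relative weight of this layer's reconstruction loss in the
        multi-modal autoencoder objective; positive, normalized to sum
        to one across the layers of a dataset.
    """

    name: str
    matrix: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.matrix.ndim != 2:
            raise ValueError(f"layer {self.name!r}: matrix must be 2-D")
        n, d = self.matrix.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"layer {self.name!r}: {n} rows but {len(self.sample_ids)} sample ids"
            )
        if d != len(self.feature_ids):
            raise ValueError(
                f"layer {self.name!r}: {d} columns but {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.sample_ids, "sample", self.name)
        _check_unique(self.feature_ids, "feature", self.name)
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"layer {self.name!r}: non-finite values in matrix")
        if not self.weight > 0:
            raise ValueError(f"layer {self.name!r}: weight must be > 0")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, sample_ids: list[str]) -> "OmicsLayer":
        """Return a copy restricted to ``sample_ids``, in that order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return OmicsLayer(
            name=self.name,
            matrix=self.matrix[rows],
            sample_ids=list(sample_ids),
            feature_ids=list(self.feature_ids),
            weight=self.weight,
        )


@dataclass
class MultiOmicsDataset:
    """Sample-aligned collection of omics layers plus optional labels.

    All layers share one sample axis (same ids, same order) and the layer
    weights sum to one.  ``labels`` maps sample id to a class index into
    ``class_names``; unlabeled datasets leave it empty.
    """

    layers: list[OmicsLayer]
    labels: dict[str, int] = field(default_factory=dict)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("dataset needs at least one layer")
        ref = self.layers[0].sample_ids
        for layer in self.layers[1:]:
            if layer.sample_ids != ref:
                raise ValueError(
                    f"layer {layer.name!r} sample axis differs from {self.layers[0].name!r}"
                )
        total = sum(layer.weight for layer in self.layers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"layer weights sum to {total}, expected 1")
        known = set(ref)
        for sid in self.labels:
            if sid not in known:
                raise ValueError(f"labeled sample {sid!r} not in the sample axis")
        if self.labels:
            n_classes = len(self.class_names)
            bad = {c for c in self.labels.values() if not 0 <= c < n_classes}
            if bad:
                raise ValueError(f"label indices {sorted(bad)} outside class_names")

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    @property
    def n_samples(self) -> int:
        return self.layers[0].n_samples

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_array(self) -> np.ndarray:
        """Labels as an int array over the sample axis, -1 for unlabeled."""
        return np.array([self.labels.get(s, -1) for s in self.sample_ids], dtype=int)


@dataclass
class LabeledGraph:
    """A weighted patient network with optional per-node attributes."""

    nodes: list[str]
    edge_weights: np.ndarray
    node_attributes: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        n = len(self.nodes)
        if self.edge_weights.shape != (n, n):
            raise ValueError("edge_weights must be n x n over the node list")
        if not np.allclose(self.edge_weights, self.edge_weights.T, atol=1e-8):
            raise ValueError("edge_weights must be symmetric")
        if (self.edge_weights < 0).any():
            raise ValueError("edge weights must be nonnegative")
        if np.diagonal(self.edge_weights).any():
            warnings.warn("graph has nonzero self-weights; they are ignored on export")
        for name, values in self.node_attributes.items():
            if len(values) != n:
                raise ValueError(f"node attribute {name!r} has wrong length")


def _check_unique(ids: list[str], kind: str, name: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"layer {name!r}: duplicate {kind} id {i!r}")
        seen.add(i)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path, transpose: bool) -> pd.DataFrame:
    # C parser with round_trip so load->write->load is exact to the bit
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     float_precision="round_trip")
    if transpose:
        df = df.T
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    if len(non_numeric):
        # name the first offending cell for the error message
        col = non_numeric[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()]
        row = bad_rows[0] if len(bad_rows) else df.index[0]
        raise ValueError(
            f"{path}: non-numeric value in column {col!r}, row {row!r}"
        )
    return df


def load_omics_table(
    path,
    name: str,
    weight: float = 1.0,
    *,
    transpose: bool = False,
    impute_median: bool = False,
    zscore: bool = False,
) -> OmicsLayer:
    """Load one delimited omics table (rows = samples, columns = features).

    The first column holds sample ids and the header row holds feature ids;
    ``transpose=True`` handles the transposed dialect.  Missing values are
    rejected unless ``impute_median=True``, which fills each feature's NaNs
    with that feature's median.  ``zscore=True`` standardizes each feature
    to zero mean and unit variance (constant features are left centered).
    """
    df = _read_table(path, transpose)
    if df.isna().any().any():
        if not impute_median:
            raise ValueError(
                f"{path}: missing values present; pass impute_median=True to fill "
                "them with per-feature medians"
            )
        df = df.fillna(df.median())
        if df.isna().any().any():
            raise ValueError(f"{path}: a feature is entirely missing; cannot impute")
    matrix = df.to_numpy(dtype=float)
    if zscore:
        mean = matrix.mean(axis=0)
        std = matrix.std(axis=0)
        std[std == 0] = 1.0
        matrix = (matrix - mean) / std
    return OmicsLayer(
        name=name,
        matrix=matrix,
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(f) for f in df.columns],
        weight=weight,
    )


def write_omics_table(layer: OmicsLayer, path, sep: str = "\t") -> None:
    """Write a layer back to delimited text (inverse of :func:`load_omics_table`)."""
    df = pd.DataFrame(layer.matrix, index=layer.sample_ids, columns=layer.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)  # default repr round-trips doubles exactly


def load_labels(path) -> dict[str, str]:
    """Read a two-column sample_id,class_label table into a dict."""
    df = pd.read_csv(path, sep=None, engine="python", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label table needs two columns (sample_id, class)")
    sids = df.iloc[:, 0].astype(str)
    if sids.duplicated().any():
        dup = sids[sids.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r} in label table")
    return dict(zip(sids, df.iloc[:, 1].astype(str)))


def align_dataset(
    layers: list[OmicsLayer],
    labels: dict[str, str] | None = None,
    *,
    normalize_weights: bool = True,
    verbose: bool = False,
) -> MultiOmicsDataset:
    """Restrict layers (and labels) to their common samples in canonical order.

    The shared axis is the intersection of all layers' sample ids (and the
    label table's, when given), sorted lexicographically so every downstream
    matrix is reproducible regardless of file order.  Layer weights default
    to equal shares and are normalized to sum to one.
    """
    if not layers:
        raise ValueError("need at least one layer")
    common = set(layers[0].sample_ids)
    for layer in layers[1:]:
        common &= set(layer.sample_ids)
    if labels:
        common &= set(labels)
    if not common:
        raise ValueError("no samples shared by all layers (and labels)")
    order = sorted(common)
    if verbose:
        for layer in layers:
            dropped = len(layer.sample_ids) - len(order)
            if dropped:
                print(f"align: dropped {dropped} samples from layer {layer.name!r}")
        if labels and len(labels) > len(order):
            print(f"align: dropped {len(labels) - len(order)} labeled samples")
    aligned = [layer.subset(order) for layer in layers]
    if normalize_weights:
        total = sum(layer.weight for layer in aligned)
        for layer in aligned:
            layer.weight = layer.weight / total
    label_map: dict[str, int] = {}
    class_names: list[str] = []
    if labels:
        class_names = sorted({labels[s] for s in order})
        index = {c: i for i, c in enumerate(class_names)}
        label_map = {s: index[labels[s]] for s in order}
    return MultiOmicsDataset(layers=aligned, labels=label_map, class_names=class_names)


def export_graph(
    graph: LabeledGraph,
    path,
    format: str = "graphml",
    min_weight: float = 0.0,
) -> int:
    """Write the network for external visualization (e.g. Cytoscape).

    Keeps exactly the edges with weight >= ``min_weight``, excluding
    self-edges; all nodes are retained even when isolated.  ``format`` is
    ``"graphml"`` or ``"edge-list"`` (3-column TSV: source, target, weight).
    Returns the number of edges written.
    """
    g = nx.Graph()
    for i, node in enumerate(graph.nodes):
        attrs = {name: vals[i] for name, vals in graph.node_attributes.items()}
        g.add_node(node, **attrs)
    n = len(graph.nodes)
    w = graph.edge_weights
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] >= min_weight and w[i, j] > 0:
                g.add_edge(graph.nodes[i], graph.nodes[j], weight=float(w[i, j]))
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge-list":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{data['weight']:.17g}\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'graphml' or 'edge-list'")
    return g.number_of_edges()
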