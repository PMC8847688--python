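import numpy as np
import pandas as pd
import pytest

from graphfuse.data_io import (
    LabeledGraph,
    MultiOmicsDataset,
    OmicsLayer,
    align_dataset,
    export_graph,
    load_labels,
    load_omics_table,
    write_omics_table,
)


def _write(tmp_path, text, name="t.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadOmicsTable:
    def test_parses_small_table(self, tmp_path):
        p = _write(tmp_path, "sample\tg1\tg2\nS1\t1.0\t2.0\nS2\t3\t4\nS3\t5\t6\n")
        layer = load_omics_table(p, name="toy")
        assert layer.n_samples == 3 and layer.n_features == 2
        assert layer.sample_ids == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(layer.matrix, [[1, 2], [3, 4], [5, 6]])

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = _write(tmp_path, "id\tg1\nS1\t1\nS1\t2\n")
        with pytest.raises(ValueError, match="duplicate sample id 'S1'"):
            load_omics_table(p, name="dup")

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = _write(tmp_path, "id\tg1\tg2\nS1\t1\tx\nS2\t2\t3\n")
        with pytest.raises(ValueError, match="g2"):
            load_omics_table(p, name="bad")

    def test_missing_values_rejected_unless_imputed(self, tmp_path):
        p = _write(tmp_path, "id\tg1\tg2\nS1\t1\t\nS2\t2\t3\nS3\t4\t5\n")
        with pytest.raises(ValueError, match="missing"):
            load_omics_table(p, name="na")
        layer = load_omics_table(p, name="na", impute_median=True)
        assert layer.matrix[0, 1] == 4.0  # median of {3, 5}

    def test_transpose_dialect(self, tmp_path):
        p = _write(tmp_path, "gene\tS1\tS2\ng1\t1\t2\ng2\t3\t4\n")
        layer = load_omics_table(p, name="t", transpose=True)
        assert layer.sample_ids == ["S1", "S2"]
        assert layer.feature_ids == ["g1", "g2"]

    def test_zscore_standardizes_features(self, tmp_path):
        p = _write(tmp_path, "id\tg1\tg2\nS1\t1\t7\nS2\t2\t7\nS3\t3\t7\n")
        layer = load_omics_table(p, name="z", zscore=True)
        np.testing.assert_allclose(layer.matrix.mean(axis=0), 0, atol=1e-12)
        assert layer.matrix[:, 1].std() == 0  # constant feature left centered

    def test_brca_shaped_fixture(self, tmp_path, rng=np.random.default_rng(0)):
        # cohort-shaped table: 511 samples x 223 protein-array features
        ids = [f"P{i:03d}" for i in range(511)]
        df = pd.DataFrame(rng.normal(size=(511, 223)), index=ids,
                          columns=[f"ab{j}" for j in range(223)])
        df.index.name = "sample_id"
        p = tmp_path / "rppa.tsv"
        df.to_csv(p, sep="\t")
        layer = load_omics_table(p, name="RPPA")
        assert layer.n_samples == 511 and layer.n_features == 223


def test_roundtrip_full_precision(tmp_path):
    rng = np.random.default_rng(1)
    layer = OmicsLayer("x", rng.normal(size=(5, 3)), [f"S{i}" for i in range(5)],
                       [f"g{j}" for j in range(3)])
    write_omics_table(layer, tmp_path / "x.tsv")
    back = load_omics_table(tmp_path / "x.tsv", name="x")
    np.testing.assert_array_equal(back.matrix, layer.matrix)
    assert back.sample_ids == layer.sample_ids
    assert back.feature_ids == layer.feature_ids


class TestAlignDataset:
    def _layer(self, name, ids):
        rng = np.random.default_rng(abs(hash(name)) % 2**31)
        return OmicsLayer(name, rng.normal(size=(len(ids), 4)), ids,
                          [f"{name}_g{j}" for j in range(4)])

    def test_intersection(self):
        ds = align_dataset(
            [self._layer("a", ["A", "B", "C"]), self._layer("b", ["B", "C", "D"])]
        )
        assert ds.sample_ids == ["B", "C"]

    def test_identical_sets_no_drop(self):
        ds = align_dataset(
            [self._layer("a", ["A", "B", "C"]), self._layer("b", ["C", "A", "B"])]
        )
        assert ds.sample_ids == ["A", "B", "C"]  # canonical lexicographic order

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="no samples shared"):
            align_dataset([self._layer("a", ["A"]), self._layer("b", ["B"])])

    def test_idempotent(self):
        ds = align_dataset(
            [self._layer("a", ["C", "A", "B"]), self._layer("b", ["B", "C", "A"])]
        )
        again = align_dataset(ds.layers)
        assert again.sample_ids == ds.sample_ids
        for l1, l2 in zip(ds.layers, again.layers):
            np.testing.assert_array_equal(l1.matrix, l2.matrix)

    def test_labels_restrict_and_encode(self):
        labels = {"A": "lumA", "B": "basal", "C": "lumA"}
        ds = align_dataset([self._layer("a", ["A", "B", "C", "D"])], labels)
        assert ds.sample_ids == ["A", "B", "C"]
        assert ds.class_names == ["basal", "lumA"]
        assert ds.labels == {"A": 1, "B": 0, "C": 1}

    def test_weights_normalized(self):
        l1 = self._layer("a", ["A", "B", "C"])
        l2 = self._layer("b", ["A", "B", "C"])
        l1.weight, l2.weight = 2.0, 2.0
        ds = align_dataset([l1, l2])
        assert sum(layer.weight for layer in ds.layers) == pytest.approx(1.0)

    def test_three_layers_sharing_subset(self):
        # 600-id universe, layers each missing a disjoint slice; 511 shared
        universe = [f"S{i:03d}" for i in range(600)]
        keep = [
            universe[:540],             # drops last 60
            universe[29:],              # drops first 29
            universe[:511] + universe[540:],
        ]
        shared = set(keep[0]) & set(keep[1]) & set(keep[2])
        assert len(shared) == 482  # brute-force count is the oracle
        ds = align_dataset([self._layer(n, ids) for n, ids in zip("abc", keep)])
        assert ds.n_samples == len(shared)


def test_dataset_weight_sum_invariant():
    rng = np.random.default_rng(2)
    ids = ["A", "B"]
    mk = lambda name, w: OmicsLayer(name, rng.normal(size=(2, 2)), ids,
                                    [f"{name}{j}" for j in range(2)], weight=w)
    with pytest.raises(ValueError, match="sum"):
        MultiOmicsDataset(layers=[mk("a", 0.5), mk("b", 0.6)])


class TestExportGraph:
    def _complete(self, n=3, w=1.0):
        M = np.full((n, n), w)
        np.fill_diagonal(M, 0.0)
        return LabeledGraph(nodes=[f"N{i}" for i in range(n)], edge_weights=M)

    def test_complete_graph_edge_count(self, tmp_path):
        n_edges = export_graph(self._complete(3), tmp_path / "g.graphml")
        assert n_edges == 3  # n(n-1)/2

    def test_min_weight_above_max_keeps_nodes(self, tmp_path):
        import networkx as nx

        p = tmp_path / "g.graphml"
        n_edges = export_graph(self._complete(3), p, min_weight=2.0)
        assert n_edges == 0
        g = nx.read_graphml(p)
        assert g.number_of_nodes() == 3

    def test_edge_list_no_self_edges_no_duplicates(self, tmp_path):
        p = tmp_path / "edges.tsv"
        export_graph(self._complete(4), p, format="edge-list")
        df = pd.read_csv(p, sep="\t")
        assert (df["source"] != df["target"]).all()
        pairs = {frozenset((s, t)) for s, t in zip(df["source"], df["target"])}
        assert len(pairs) == len(df) == 6

    def test_node_attributes_written(self, tmp_path):
        import networkx as nx

        g = self._complete(2)
        g.node_attributes["true_label"] = ["lumA", "basal"]
        p = tmp_path / "g.graphml"
        export_graph(g, p)
        back = nx.read_graphml(p)
        assert back.nodes["N0"]["true_label"] == "lumA"

    def test_topk_threshold_degree(self, small_dataset, tmp_path):
        # min_weight at each row's 5th-largest weight keeps degree >= 5
        from graphfuse.snf import fuse_views

        ds, _ = small_dataset
        sub = [l.matrix[:20] for l in ds.layers]
        fused = fuse_views(sub, K=5)
        M = fused.P_fused.copy()
        np.fill_diagonal(M, 0.0)
        thresh = np.sort(M, axis=1)[:, -5].min()
        graph = LabeledGraph(nodes=[f"N{i}" for i in range(20)], edge_weights=M)
        p = tmp_path / "e.tsv"
        export_graph(graph, p, format="edge-list", min_weight=thresh)
        df = pd.read_csv(p, sep="\t")
        deg = pd.concat([df["source"], df["target"]]).value_counts()
        assert (deg >= 5).all()


def test_load_labels(tmp_path):
    p = tmp_path / "labels.csv"
    p.write_text("sample_id,class\nS1,lumA\nS2,basal\n")
    assert load_labels(p) == {"S1": "lumA", "S2": "basal"}
    p.write_text("sample_id,class\nS1,lumA\nS1,basal\n")
    with pytest.raises(ValueError, match="duplicate"):
        load_labels(p)
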