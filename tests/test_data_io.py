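import numpy as np
import pandas as pd
import pytest

from kernelgrn.data_io import (
    FeatureMatrix,
    GeneGraph,
    RegulationMatrix,
    ScoreMatrix,
    align_universe,
    read_feature_matrix,
    read_gene_graph,
    read_regulations,
    write_feature_matrix,
    write_network,
    write_regulations,
)

import networkx as nx


class TestFeatureMatrix:
    def test_round_trip_preserves_values_and_order(self, tmp_path, rng):
        fm = FeatureMatrix(
            [f"g{i}" for i in range(10)],
            [f"s{j}" for j in range(5)],
            rng.standard_normal((10, 5)),
        )
        path = tmp_path / "expr.tsv"
        write_feature_matrix(fm, path)
        back = read_feature_matrix(path)
        assert back.gene_ids == fm.gene_ids
        assert back.sample_ids == fm.sample_ids
        assert np.allclose(back.values, fm.values, atol=1e-12, rtol=0)

    def test_small_fixture_identity(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\ts1\ts2\ngB\t1\t2\ngA\t3\t4\ngC\t5\t6\n")
        fm = read_feature_matrix(path)
        assert fm.values.shape == (3, 2)
        assert fm.gene_ids == ["gB", "gA", "gC"]  # file order preserved

    def test_duplicate_gene_id_names_offender(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(ValueError, match="g1"):
            read_feature_matrix(path)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ng1\t1\t2\ng2\toops\t3\n")
        with pytest.raises(ValueError, match="g2.*s1"):
            read_feature_matrix(path)

    def test_missing_policies(self, tmp_path):
        path = tmp_path / "na.tsv"
        path.write_text("gene\ts1\ts2\ng1\t1\t\ng2\t3\t4\n")
        with pytest.warns(UserWarning, match="dropped 1"):
            fm = read_feature_matrix(path, missing="reject")
        assert fm.gene_ids == ["g2"]
        fm2 = read_feature_matrix(path, missing="impute")
        assert fm2.values[0, 1] == 1.0  # row mean
        with pytest.raises(ValueError):
            read_feature_matrix(path, missing="error")


class TestRegulations:
    def test_edge_list_construction(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text("TF1\tg2\t1\nTF1\tg3\t1\n")
        R = read_regulations(path, "edge_list", gene_ids=["g1", "g2", "g3", "g4"])
        assert R.tf_ids == ["TF1"]
        assert R.labels[:, 0].tolist() == [-1, 1, 1, -1]
        assert R.known_mask[:, 0].tolist() == [False, True, True, False]

    def test_empty_edge_list_flags_zero_positive_tf(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        R = read_regulations(
            path, "edge_list", gene_ids=["g1", "g2", "g3", "g4"], tf_ids=["TF1"]
        )
        assert (R.labels == -1).all()
        assert R.zero_positive_tfs() == ["TF1"]

    def test_bad_indicator_rejected(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text("TF1\tg2\t2\n")
        with pytest.raises(ValueError, match="indicator"):
            read_regulations(path, "edge_list", gene_ids=["g1", "g2"])

    def test_matrix_zero_entry_needs_unknown_mode(self, tmp_path):
        path = tmp_path / "mat.tsv"
        path.write_text("gene\tTF1\ng1\t1\ng2\t0\n")
        with pytest.raises(ValueError, match=r"\+1/-1"):
            read_regulations(path, "matrix")
        R = read_regulations(path, "matrix", allow_unknown=True)
        assert R.labels[1, 0] == 0
        assert not R.known_mask[1, 0]
        # training still treats unknown as -1
        assert R.training_labels("TF1").tolist() == [1.0, -1.0]

    def test_edge_list_and_matrix_agree(self, tmp_path):
        genes = ["g1", "g2", "g3"]
        el = tmp_path / "el.tsv"
        el.write_text("TF1\tg1\t1\nTF2\tg3\t1\n")
        R1 = read_regulations(el, "edge_list", gene_ids=genes)
        mat = tmp_path / "mat.tsv"
        write_regulations(R1, mat, format="matrix")
        R2 = read_regulations(mat, "matrix")
        assert R1.gene_ids == R2.gene_ids and R1.tf_ids == R2.tf_ids
        assert (R1.labels == R2.labels).all()

    def test_self_regulating_sole_target_warns(self, tmp_path):
        path = tmp_path / "self.tsv"
        path.write_text("g1\tg1\t1\n")
        with pytest.warns(UserWarning, match="own sole target"):
            read_regulations(path, "edge_list", gene_ids=["g1", "g2"])


class TestGeneGraph:
    def test_read_edge_list_with_weights(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("g1\tg2\t0.5\ng2\tg3\t2\n")
        gg = read_gene_graph(path)
        assert gg.graph["g1"]["g2"]["weight"] == 0.5
        A = gg.adjacency(["g1", "g2", "g3"])
        assert np.allclose(A, A.T)
        assert np.all(np.diag(A) == 0)

    def test_self_loops_dropped_with_warning(self):
        g = nx.Graph()
        g.add_edge("a", "a")
        g.add_edge("a", "b")
        with pytest.warns(UserWarning, match="self-loop"):
            gg = GeneGraph(g)
        assert not list(nx.selfloop_edges(gg.graph))

    def test_negative_weight_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-1.0)
        with pytest.raises(ValueError, match="negative"):
            GeneGraph(g)


class TestAlignUniverse:
    def _expr(self, genes):
        return FeatureMatrix(genes, ["s1"], np.zeros((len(genes), 1)))

    def test_intersection_and_dropped_report(self):
        g = nx.Graph()
        g.add_edge("g2", "g3")
        g.add_node("g4")
        aligned, dropped = align_universe(
            {"expression": self._expr(["g1", "g2", "g3"]), "ppi": GeneGraph(g)}
        )
        assert aligned["expression"].gene_ids == ["g2", "g3"]
        assert aligned["ppi"].gene_ids == ["g2", "g3"]
        assert dropped == {"expression": ["g1"], "ppi": ["g4"]}

    def test_single_input_canonical_order(self):
        aligned, dropped = align_universe({"expression": self._expr(["gB", "gA"])})
        assert aligned["expression"].gene_ids == ["gA", "gB"]
        assert dropped["expression"] == []

    def test_idempotent(self):
        inputs = {"expression": self._expr(["g3", "g1", "g2"])}
        once, _ = align_universe(inputs)
        twice, _ = align_universe(once)
        assert once["expression"].gene_ids == twice["expression"].gene_ids
        assert np.array_equal(once["expression"].values, twice["expression"].values)

    def test_disjoint_universes_error(self):
        with pytest.raises(ValueError, match="empty intersection"):
            align_universe(
                {"a": self._expr(["g1"]), "b": self._expr(["g2"])}
            )


class TestWriteNetwork:
    def _ds(self):
        return ScoreMatrix(["a", "b", "c"], ["TF1"], np.array([[0.5], [0.9], [0.5]]))

    def test_sort_with_tie_break(self, tmp_path):
        df = write_network(self._ds(), tmp_path / "net.tsv")
        assert df["gene"].tolist() == ["b", "a", "c"]

    def test_top_k(self, tmp_path):
        df = write_network(self._ds(), tmp_path / "net.tsv", top_k=1)
        assert len(df) == 1 and df.iloc[0]["gene"] == "b"
        with pytest.raises(ValueError):
            write_network(self._ds(), tmp_path / "net.tsv", top_k=0)

    def test_round_trip_ordering(self, tmp_path, rng):
        ds = ScoreMatrix(
            [f"g{i}" for i in range(8)], ["TF1", "TF2"], rng.standard_normal((8, 2))
        )
        path = tmp_path / "net.tsv"
        df = write_network(ds, path)
        back = pd.read_csv(path, sep="\t")
        assert back["gene"].tolist() == df["gene"].tolist()
        assert np.allclose(back["score"], df["score"], atol=1e-12)
        assert (back["score"].diff().dropna() <= 0).all()

    def test_known_positive_exclusion(self, tmp_path):
        R = RegulationMatrix(["a", "b", "c"], ["TF1"], np.array([[-1], [1], [-1]]))
        df = write_network(
            self._ds(), tmp_path / "net.tsv", known=R, known_policy="exclude"
        )
        assert "b" not in df["gene"].tolist()
        df2 = write_network(
            self._ds(), tmp_path / "net2.tsv", known=R, known_policy="mark"
        )
        assert df2.loc[df2["gene"] == "b", "known"].item() == 1

    def test_skipped_columns_omitted(self, tmp_path):
        ds = ScoreMatrix(
            ["a", "b"],
            ["TF1", "TF2"],
            np.array([[1.0, np.nan], [0.0, np.nan]]),
            column_status={"TF2": "skipped"},
        )
        df = write_network(ds, tmp_path / "net.tsv")
        assert set(df["tf"]) == {"TF1"}
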