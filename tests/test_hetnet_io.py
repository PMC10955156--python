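import numpy as np
import pytest

from hetdti.exceptions import ConfigurationError, DataValidationError, ParseError
from hetdti.hetnet_io import (
    BipartiteAssociation,
    NodeRegistry,
    SimilarityMatrix,
    assemble,
    read_edge_list,
    read_similarity_matrix,
    write_edge_list,
    write_score_matrix,
    write_similarity_matrix,
)

from .conftest import make_registry


class TestNodeRegistry:
    def test_index_is_bijection(self):
        reg = NodeRegistry("drug", ["a", "b", "c"])
        assert [reg.index[i] for i in reg.ids] == [0, 1, 2]

    def test_duplicates_rejected(self):
        with pytest.raises(DataValidationError):
            NodeRegistry("drug", ["a", "a"])

    def test_file_round_trip(self, tmp_path):
        reg = NodeRegistry("protein", ["p2", "p1", "p9"])
        reg.to_file(tmp_path / "reg.txt")
        again = NodeRegistry.from_file(tmp_path / "reg.txt", "protein")
        assert again.ids == reg.ids and again.index == reg.index


class TestReadEdgeList:
    def test_direct_transcription(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("d1\tp1\nd2\tp2\n")
        rows = NodeRegistry("drug", ["d1", "d2"])
        cols = NodeRegistry("protein", ["p1", "p2"])
        a = read_edge_list(f, rows, cols)
        assert np.array_equal(a.matrix, [[1, 0], [0, 1]])

    def test_empty_file_gives_zero_matrix(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("# only a comment\n")
        a = read_edge_list(f, NodeRegistry("drug", ["d1", "d2"]),
                           NodeRegistry("protein", ["p1", "p2"]))
        assert np.array_equal(a.matrix, np.zeros((2, 2)))

    def test_same_type_edges_are_mirrored(self, tmp_path):
        f = tmp_path / "dd.tsv"
        f.write_text("d1\td2\n")
        reg = NodeRegistry("drug", ["d1", "d2"])
        a = read_edge_list(f, reg, reg)
        assert np.array_equal(a.matrix, [[0, 1], [1, 0]])

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("d1\tp1\nonly_one_column\n")
        with pytest.raises(ParseError, match=":2"):
            read_edge_list(f, NodeRegistry("drug"), NodeRegistry("protein"))

    def test_unknown_id_in_frozen_registry(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("dX\tp1\n")
        with pytest.raises(DataValidationError, match="dX"):
            read_edge_list(f, NodeRegistry("drug", ["d1"]), NodeRegistry("protein", ["p1"]))

    def test_empty_registries_populated_in_file_order(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("d2\tp1\nd1\tp2\n")
        rows, cols = NodeRegistry("drug"), NodeRegistry("protein")
        read_edge_list(f, rows, cols)
        assert rows.ids == ["d2", "d1"] and cols.ids == ["p1", "p2"]

    def test_line_order_invariance_with_frozen_registries(self, tmp_path):
        rows = NodeRegistry("drug", ["d1", "d2", "d3"])
        cols = NodeRegistry("protein", ["p1", "p2"])
        lines = ["d1\tp2", "d3\tp1", "d2\tp2"]
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        f1.write_text("\n".join(lines) + "\n")
        f2.write_text("\n".join(reversed(lines)) + "\n")
        a1 = read_edge_list(f1, rows, cols)
        a2 = read_edge_list(f2, rows, cols)
        assert np.array_equal(a1.matrix, a2.matrix)

    def test_weighted_input_binarized_by_default(self, tmp_path):
        f = tmp_path / "w.tsv"
        f.write_text("d1\tp1\t0.7\n")
        rows = NodeRegistry("drug", ["d1"])
        cols = NodeRegistry("protein", ["p1"])
        assert read_edge_list(f, rows, cols).matrix[0, 0] == 1.0
        assert read_edge_list(f, rows, cols, binary=False).matrix[0, 0] == 0.7

    def test_round_trip(self, tmp_path, rng):
        rows = make_registry("drug", "d", 6)
        cols = make_registry("protein", "p", 4)
        M = (rng.random((6, 4)) < 0.4).astype(float)
        a = BipartiteAssociation("drug", "protein", M)
        write_edge_list(a, rows, cols, tmp_path / "rt.tsv")
        back = read_edge_list(tmp_path / "rt.tsv", rows, cols)
        assert np.array_equal(back.matrix, M)


class TestReadSimilarityMatrix:
    def test_identity_table(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("1\t0\n0\t1\n")
        s = read_similarity_matrix(f, node_type="drug")
        assert np.array_equal(s.matrix, np.eye(2))

    def test_out_of_range_entry(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("1\t1.5\n1.5\t1\n")
        with pytest.raises(DataValidationError, match="outside"):
            read_similarity_matrix(f, node_type="drug")

    def test_tiny_asymmetry_averaged(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("1\t0.3\n0.3000000001\t1\n")
        s = read_similarity_matrix(f, node_type="drug")
        assert s.matrix[0, 1] == pytest.approx(0.30000000005, abs=1e-15)
        assert s.matrix[0, 1] == s.matrix[1, 0]

    def test_gross_asymmetry_rejected(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("1\t0.9\n0.1\t1\n")
        with pytest.raises(DataValidationError, match="asymmetric"):
            read_similarity_matrix(f, node_type="drug")

    def test_non_square_rejected(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("1\t0\t0\n0\t1\t0\n")
        with pytest.raises(DataValidationError, match="square"):
            read_similarity_matrix(f, node_type="drug")

    def test_header_round_trip_in_registry_order(self, tmp_path, rng):
        reg = NodeRegistry("drug", ["a", "b", "c"])
        M = rng.random((3, 3))
        sim = SimilarityMatrix("drug", (M + M.T) / 2)
        write_similarity_matrix(sim, reg, tmp_path / "s.tsv")
        back = read_similarity_matrix(tmp_path / "s.tsv", reg)
        np.testing.assert_allclose(back.matrix, sim.matrix, atol=1e-9)


class TestWriteScoreMatrix:
    def test_single_entry(self, tmp_path):
        write_score_matrix(np.array([[0.7]]), NodeRegistry("drug", ["d1"]),
                           NodeRegistry("protein", ["p1"]), tmp_path / "s.tsv")
        assert (tmp_path / "s.tsv").read_text() == "d1\tp1\t0.7\n"

    def test_top_k_truncates(self, tmp_path, rng):
        drugs = make_registry("drug", "d", 10)
        prots = make_registry("protein", "p", 10)
        write_score_matrix(rng.random((10, 10)), drugs, prots, tmp_path / "s.tsv", top_k=10)
        assert len((tmp_path / "s.tsv").read_text().splitlines()) == 10

    def test_descending_with_lexicographic_ties(self, tmp_path):
        drugs = NodeRegistry("drug", ["dB", "dA"])
        prots = NodeRegistry("protein", ["p1"])
        write_score_matrix(np.array([[0.5], [0.5]]), drugs, prots, tmp_path / "s.tsv")
        lines = (tmp_path / "s.tsv").read_text().splitlines()
        assert lines[0].startswith("dA") and lines[1].startswith("dB")

    def test_training_pairs_excluded(self, tmp_path):
        drugs = NodeRegistry("drug", ["d1"])
        prots = NodeRegistry("protein", ["p1", "p2"])
        mask = np.array([[1.0, 0.0]])
        write_score_matrix(np.array([[0.9, 0.1]]), drugs, prots, tmp_path / "s.tsv",
                           exclude_mask=mask)
        assert (tmp_path / "s.tsv").read_text() == "d1\tp2\t0.1\n"


class TestSimilarityMatrixType:
    def test_diagonal_forced_to_one(self):
        s = SimilarityMatrix("drug", np.array([[0.2, 0.1], [0.1, 0.4]]))
        assert np.array_equal(np.diag(s.matrix), [1.0, 1.0])


class TestAssemble:
    def test_isolated_nodes_dropped(self, dataset):
        hs = dataset.network_set
        # isolate drug 0 across every network it touches
        assoc = {k: BipartiteAssociation(v.row_type, v.col_type, v.matrix.copy())
                 for k, v in hs.associations.items()}
        intra = {k: BipartiteAssociation(v.row_type, v.col_type, v.matrix.copy())
                 for k, v in hs.intra_type.items()}
        for name in ("drug_protein", "drug_disease", "drug_side_effect"):
            assoc[name].matrix[0, :] = 0.0
        intra["drug_drug"].matrix[0, :] = 0.0
        intra["drug_drug"].matrix[:, 0] = 0.0
        out = assemble(hs.registries, assoc, intra, hs.precomputed)
        assert out.n_drugs == hs.n_drugs - 1
        assert hs.registries["drug"].ids[0] not in out.registries["drug"].ids
        out.validate()

    def test_missing_network_is_configuration_error(self, dataset):
        hs = dataset.network_set
        assoc = dict(hs.associations)
        del assoc["drug_disease"]
        with pytest.raises(ConfigurationError, match="drug_disease"):
            assemble(hs.registries, assoc, hs.intra_type, hs.precomputed)
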