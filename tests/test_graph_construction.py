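"""Graph construction: centroids, adjacency, features, and file readers."""

import numpy as np
import pytest

import eqppis as eq
from eqppis.elements import ELEMENT_PROPERTIES, atom_h_count
from eqppis.graph_construction import (
    Atom,
    FileFormatError,
    GROUP_WIDTHS,
    ResidueRecord,
    dssp_row_features,
)
from eqppis.synthetic_data import write_dssp, write_hhm, write_pdb, write_pssm


def _residue(name, atoms, idx=0):
    return ResidueRecord("A", idx, name, atoms)


class TestCentroids:
    def test_single_sidechain_atom_is_its_own_centroid(self):
        res = _residue("ALA", [Atom("C", "CA", [0, 0, 0]), Atom("C", "CB", [1, 1, 1])])
        assert np.allclose(eq.compute_sc_centroids([res]), [[1, 1, 1]])

    def test_glycine_falls_back_to_ca(self):
        res = _residue("GLY", [Atom("N", "N", [9, 9, 9]), Atom("C", "CA", [2, 3, 4])])
        assert np.allclose(eq.compute_sc_centroids([res]), [[2, 3, 4]])

    def test_matches_bruteforce_mean_over_sidechain_heavy_atoms(self, rng):
        backbone = {"N", "CA", "C", "O", "OXT"}
        residues = []
        for i in range(5):
            atoms = [Atom("C", "CA", rng.normal(size=3))]
            for j in range(int(rng.integers(1, 5))):
                atoms.append(Atom("C", f"CB{j}", rng.normal(size=3)))
            residues.append(_residue("XXX", atoms, i))
        got = eq.compute_sc_centroids(residues)
        for i, res in enumerate(residues):
            side = [a.coords for a in res.atoms if a.name not in backbone]
            assert np.allclose(got[i], np.mean(side, axis=0))

    def test_errors(self):
        with pytest.raises(ValueError):
            eq.compute_sc_centroids([])
        bare = ResidueRecord("A", 3, "ALA", [Atom("H", "H1", [0, 0, 0])])
        with pytest.raises(ValueError, match="ALA A:3"):
            eq.compute_sc_centroids([bare])


class TestAdjacency:
    def test_cutoff_is_strict_at_14(self):
        near = np.array([[0, 0, 0], [13.9, 0, 0]])
        far = np.array([[0, 0, 0], [14.1, 0, 0]])
        assert eq.build_adjacency(near, 14.0)[0, 1] == 1
        assert eq.build_adjacency(far, 14.0)[0, 1] == 0
        exact = np.array([[0, 0, 0], [14.0, 0, 0]])
        assert eq.build_adjacency(exact, 14.0)[0, 1] == 0

    def test_single_residue_gives_1x1_zero(self):
        assert eq.build_adjacency(np.zeros((1, 3)), 14.0).tolist() == [[0]]

    def test_matches_bruteforce_distance_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            coords = rng.uniform(-20, 20, size=(n, 3))
            cutoff = float(rng.uniform(5, 20))
            adj = eq.build_adjacency(coords, cutoff)
            expected = np.zeros((n, n), dtype=int)
            for i in range(n):
                for j in range(n):
                    if i != j and np.linalg.norm(coords[i] - coords[j]) < cutoff:
                        expected[i, j] = 1
            assert np.array_equal(adj, expected)
            assert np.array_equal(adj, adj.T)
            assert np.all(np.diag(adj) == 0)

    def test_rejects_bad_inputs(self, rng):
        with pytest.raises(ValueError):
            eq.build_adjacency(np.zeros((2, 3)), -1.0)
        bad = np.array([[0.0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(ValueError):
            eq.build_adjacency(bad, 14.0)


class TestAtomFeatures:
    def test_single_carbon_returns_raw_characteristics(self):
        res = _residue("ALA", [Atom("C", "CB", [0, 0, 0], b_factor=25.0)])
        row = eq.aggregate_atom_features([res])[0]
        mass, electrons, vdw = ELEMENT_PROPERTIES["C"]
        assert row[0] == mass
        assert row[1] == 25.0
        assert row[2] == 1.0  # CB is a side-chain atom
        assert row[3] == electrons
        assert row[4] == atom_h_count("ALA", "CB") == 3
        assert row[5] == 0.0
        assert row[6] == vdw

    def test_b_factor_is_averaged(self):
        res = _residue(
            "ALA",
            [Atom("C", "CA", [0, 0, 0], b_factor=10.0), Atom("C", "CB", [1, 0, 0], b_factor=30.0)],
        )
        assert eq.aggregate_atom_features([res])[0, 1] == 20.0

    def test_matches_bruteforce_column_mean(self, rng):
        elements = ["C", "N", "O", "S"]
        residues = []
        for i in range(6):
            atoms = [
                Atom(elements[int(rng.integers(4))], "CA" if j == 0 else f"X{j}",
                     rng.normal(size=3), b_factor=float(rng.uniform(5, 60)))
                for j in range(int(rng.integers(1, 6)))
            ]
            residues.append(_residue("LEU", atoms, i))
        got = eq.aggregate_atom_features(residues)
        for i, res in enumerate(residues):
            rows = []
            for a in res.atoms:
                mass, el, vdw = ELEMENT_PROPERTIES[a.element]
                rows.append([
                    mass, a.b_factor, float(a.name != "CA"), el,
                    atom_h_count("LEU", a.name), 0.0, vdw,
                ])
            assert np.allclose(got[i], np.mean(rows, axis=0))

    def test_unknown_element_is_named_in_error(self):
        res = _residue("ALA", [Atom("Xx", "CB", [0, 0, 0])])
        with pytest.raises(ValueError, match="Xx"):
            eq.aggregate_atom_features([res])


class TestPositionEmbedding:
    def test_shape_for_single_residue(self):
        assert eq.position_embedding(np.zeros((1, 3))).shape == (1, 1)

    def test_translation_invariance(self, rng):
        coords = rng.normal(size=(12, 3))
        shifted = coords + np.array([100.0, -50.0, 7.0])
        assert np.allclose(
            eq.position_embedding(coords), eq.position_embedding(shifted)
        )

    def test_identical_rows_get_identical_embeddings(self):
        coords = np.array([[1.0, 2, 3], [4, 5, 6], [1.0, 2, 3]])
        pef = eq.position_embedding(coords)
        assert pef[0, 0] == pef[2, 0]


class TestAssembleFeatures:
    def _bundle(self, rng, L=30):
        return eq.FeatureBundle(
            pssm=rng.normal(size=(L, 20)),
            hmm=rng.normal(size=(L, 20)),
            dssp=rng.normal(size=(L, 14)),
            af=rng.normal(size=(L, 7)),
            pef=rng.normal(size=(L, 1)),
        )

    def test_full_assembly_is_62_columns(self, rng):
        assert eq.assemble_features(self._bundle(rng)).shape == (30, 62)

    def test_sequence_only_ablation_width(self, rng):
        out = eq.assemble_features(self._bundle(rng), groups={"pssm", "hmm"})
        assert out.shape == (30, 40)

    def test_pssm_block_occupies_first_20_columns(self, rng):
        b = self._bundle(rng)
        assert np.array_equal(eq.assemble_features(b)[:, :20], b.pssm)

    def test_selected_width_equals_sum_of_block_widths(self, rng):
        b = self._bundle(rng)
        for groups in [{"pssm"}, {"dssp", "pef"}, {"hmm", "af", "pef"}]:
            out = eq.assemble_features(b, groups=groups)
            assert out.shape[1] == sum(GROUP_WIDTHS[g] for g in groups)

    def test_row_mismatch_and_unknown_group_errors(self, rng):
        with pytest.raises(ValueError):
            eq.FeatureBundle(
                pssm=np.zeros((5, 20)), hmm=np.zeros((6, 20)),
                dssp=np.zeros((5, 14)), af=np.zeros((5, 7)), pef=np.zeros((5, 1)),
            )
        with pytest.raises(ValueError, match="nope"):
            eq.assemble_features(self._bundle(rng), groups={"nope"})


class TestReaders:
    def test_pssm_round_trip(self, small_chain, tmp_path):
        path = tmp_path / "c.pssm"
        write_pssm(small_chain, path)
        assert np.array_equal(eq.read_pssm(path), small_chain.bundle.pssm)

    def test_pssm_known_first_row(self, tmp_path):
        content = (
            "\nLast position-specific scoring matrix computed\n"
            "            A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V\n"
            "    1 M    -1  2  0 -3  1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  4"
            "   0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0  0.1 0.2\n"
            "    2 K     0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0"
            "   0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0  0.1 0.2\n"
            "    3 L     5  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0"
            "   0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0  0.1 0.2\n\n"
        )
        path = tmp_path / "tiny.pssm"
        path.write_text(content)
        mat = eq.read_pssm(path)
        assert mat.shape == (3, 20)
        assert mat[0, 0] == -1 and mat[0, 1] == 2 and mat[0, 19] == 4
        assert mat[2, 0] == 5

    def test_hhm_round_trip(self, small_chain, tmp_path):
        path = tmp_path / "c.hhm"
        write_hhm(small_chain, path)
        assert np.array_equal(eq.read_hhm(path), small_chain.bundle.hmm)

    def test_dssp_round_trip_and_onehot(self, small_chain, tmp_path):
        path = tmp_path / "c.dssp"
        write_dssp(small_chain, path)
        mat = eq.read_dssp(path)
        assert np.array_equal(mat, small_chain.bundle.dssp)
        assert np.allclose(mat[:, :9].sum(axis=1), 1.0)

    def test_dssp_feature_helper_torsions(self):
        row = dssp_row_features("ALA", "H", 64.5, -60.0, -45.0)
        assert row.shape == (14,)
        assert row[0] == 1.0 and row[1:9].sum() == 0.0
        assert np.isclose(row[9], 0.5)  # 64.5 / 129
        assert np.isclose(row[10], np.sin(np.radians(-60.0)))
        assert np.isclose(row[13], np.cos(np.radians(-45.0)))

    @pytest.mark.parametrize("reader", [eq.read_pssm, eq.read_hhm, eq.read_dssp])
    def test_empty_file_is_a_parse_error(self, reader, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(FileFormatError):
            reader(path)

    def test_malformed_pssm_reports_line_number(self, tmp_path):
        content = (
            "\nheader\n"
            "            A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V\n"
            "    1 M    bad row\n"
        )
        path = tmp_path / "bad.pssm"
        path.write_text(content)
        with pytest.raises(FileFormatError, match="line 4"):
            eq.read_pssm(path)

    def test_pdb_round_trip_centroids(self, small_chain, tmp_path):
        path = tmp_path / "c.pdb"
        write_pdb(small_chain, path)
        residues = eq.read_pdb_chain(path, "A")
        assert len(residues) == small_chain.graph.n_residues
        got = eq.compute_sc_centroids(residues)
        assert np.allclose(got, small_chain.graph.coords, atol=2e-3)

    def test_pdb_missing_chain_errors(self, small_chain, tmp_path):
        path = tmp_path / "c.pdb"
        write_pdb(small_chain, path)
        with pytest.raises(FileFormatError):
            eq.read_pdb_chain(path, "Z")


class TestGraphContainer:
    def test_save_load_round_trip(self, small_graph, tmp_path):
        path = tmp_path / "g.graph.json"
        eq.save_graph(small_graph, path)
        g2 = eq.load_graph(path)
        assert np.array_equal(g2.adjacency, small_graph.adjacency)
        assert np.allclose(g2.features, small_graph.features)
        assert np.allclose(g2.coords, small_graph.coords)
        assert np.array_equal(g2.labels, small_graph.labels)

    def test_build_graph_end_to_end(self, small_chain):
        g = eq.build_graph(
            small_chain.residues,
            pssm=small_chain.bundle.pssm,
            hmm=small_chain.bundle.hmm,
            dssp=small_chain.bundle.dssp,
            labels=small_chain.graph.labels,
        )
        assert g.features.shape[1] == 62
        assert np.array_equal(g.adjacency, small_chain.graph.adjacency)

    def test_invariant_validation(self, rng):
        coords = rng.normal(size=(4, 3))
        adj = np.ones((4, 4), dtype=int)  # nonzero diagonal
        with pytest.raises(ValueError):
            eq.ProteinGraph(coords=coords, features=np.zeros((4, 62)), adjacency=adj)
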