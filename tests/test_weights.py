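import numpy as np
import pytest
from shapely.geometry import Polygon, box

from sppanel.weights import (
    IsolateError,
    RegionSet,
    WeightsError,
    build_rook_from_edges,
    build_rook_from_polygons,
    china_provinces,
    patch_islands,
    read_gal,
    row_standardize,
    write_gal,
    read_edge_csv,
    write_edge_csv,
    nearest_neighbor_candidates,
)
from conftest import random_connected_weights


ABC = RegionSet(("A", "B", "C"))


class TestBuildFromEdges:
    def test_path_graph_matrix(self):
        w = build_rook_from_edges([("A", "B"), ("B", "C")], ABC)
        assert np.array_equal(w.W0, [[0, 1, 0], [1, 0, 1], [0, 1, 0]])

    def test_empty_edges_all_isolates(self):
        w = build_rook_from_edges([], ABC)
        assert w.isolates() == ["A", "B", "C"]
        with pytest.raises(IsolateError):
            row_standardize(w)

    def test_unknown_id_rejected(self):
        with pytest.raises(WeightsError, match="unknown region id"):
            build_rook_from_edges([("A", "Z")], ABC)

    def test_self_pair_rejected(self):
        with pytest.raises(WeightsError, match="self-pair"):
            build_rook_from_edges([("A", "A")], ABC)

    def test_duplicate_region_ids_rejected(self):
        with pytest.raises(WeightsError, match="duplicate"):
            RegionSet(("A", "A", "B"))

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_zero_diagonal_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        w = random_connected_weights(int(rng.integers(5, 15)), rng)
        assert np.array_equal(w.W0, w.W0.T)
        assert np.all(np.diag(w.W0) == 0)


class TestPatchIslands:
    def test_island_patched_symmetrically(self):
        regions = RegionSet(("A", "B", "C", "D"))
        w = build_rook_from_edges([("A", "B"), ("B", "C"), ("A", "C")], regions)
        assert w.isolates() == ["D"]
        patched = patch_islands(w, [("D", "A")])
        i, j = regions.index("D"), regions.index("A")
        assert patched.W0[i, j] == patched.W0[j, i] == 1
        assert patched.isolates() == []

    def test_empty_patch_on_connected_is_identity(self):
        w = build_rook_from_edges([("A", "B"), ("B", "C")], ABC)
        assert np.array_equal(patch_islands(w, []).W0, w.W0)

    def test_non_isolate_pair_warns_but_applies(self):
        w = build_rook_from_edges([("A", "B"), ("B", "C")], ABC)
        with pytest.warns(UserWarning, match="no isolated region"):
            patched = patch_islands(w, [("A", "C")])
        assert patched.W0[0, 2] == 1

    def test_unpatched_isolate_raises_with_ids(self):
        regions = RegionSet(("A", "B", "C", "D", "E"))
        w = build_rook_from_edges([("A", "B"), ("B", "C")], regions)
        with pytest.raises(IsolateError, match="D.*E|E.*D"):
            patch_islands(w, [])


class TestRowStandardize:
    def test_path_graph_middle_row(self):
        w = row_standardize(build_rook_from_edges([("A", "B"), ("B", "C")], ABC))
        assert np.allclose(w.W[1], [0.5, 0, 0.5])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        w = random_connected_weights(12, rng)
        assert np.allclose(row_standardize(w).W.sum(axis=1), 1.0, atol=1e-12)

    def test_regular_graph_is_scaled_binary(self):
        # 4-cycle: every degree 2
        regions = RegionSet(("A", "B", "C", "D"))
        w = build_rook_from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")], regions
        )
        assert np.allclose(row_standardize(w).W, w.W0 / 2)

    def test_symmetric_w0_generally_asymmetric_w(self):
        w = row_standardize(build_rook_from_edges([("A", "B"), ("B", "C")], ABC))
        assert not np.allclose(w.W, w.W.T)


class TestPolygons:
    def test_shared_edge_is_adjacent(self):
        w = build_rook_from_polygons({"L": box(0, 0, 1, 1), "R": box(1, 0, 2, 1)})
        assert w.W0[0, 1] == 1

    def test_corner_touch_is_not_adjacent(self):
        w = build_rook_from_polygons({"L": box(0, 0, 1, 1), "R": box(1, 1, 2, 2)})
        assert w.W0[0, 1] == 0

    @pytest.mark.parametrize("r,c", [(2, 2), (3, 4), (2, 5)])
    def test_grid_adjacency_count(self, r, c):
        polys = {
            f"p{i}_{j}": box(j, i, j + 1, i + 1) for i in range(r) for j in range(c)
        }
        w = build_rook_from_polygons(polys)
        assert w.n_edges() == r * (c - 1) + c * (r - 1)

    def test_invalid_geometry_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(WeightsError, match="invalid geometry"):
            build_rook_from_polygons({"X": bowtie, "Y": box(5, 5, 6, 6)})

    def test_nearest_neighbor_candidates_ranked(self):
        polys = {"A": box(0, 0, 1, 1), "B": box(2, 0, 3, 1), "C": box(9, 0, 10, 1)}
        cands = nearest_neighbor_candidates(polys, ["A"], k=2)
        assert [c[0] for c in cands["A"]] == ["B", "C"]


class TestGal:
    def test_round_trip_triangle(self, tmp_path):
        w = build_rook_from_edges([("A", "B"), ("B", "C"), ("A", "C")], ABC)
        path = tmp_path / "tri.gal"
        write_gal(w, path)
        w2 = read_gal(path)
        assert w2.regions.ids == w.regions.ids
        assert np.array_equal(w2.W0, w.W0)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_random(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        w = random_connected_weights(int(rng.integers(5, 20)), rng)
        path = tmp_path / f"g{seed}.gal"
        write_gal(w, path)
        w2 = read_gal(path)
        assert w2.regions.ids == w.regions.ids
        assert np.array_equal(w2.W0, w.W0)

    def test_declared_n_mismatch(self, tmp_path):
        path = tmp_path / "bad.gal"
        path.write_text("3\nA 1\nB\nB 1\nA\n")
        with pytest.raises(WeightsError, match="n=3"):
            read_gal(path)

    def test_neighbor_count_mismatch_reports_line(self, tmp_path):
        path = tmp_path / "bad.gal"
        path.write_text("2\nA 2\nB\nB 1\nA\n")
        with pytest.raises(WeightsError, match=":3"):
            read_gal(path)

    def test_asymmetric_rejected_then_symmetrized(self, tmp_path):
        path = tmp_path / "asym.gal"
        path.write_text("3\nA 1\nB\nB 0\nC 1\nB\n")
        with pytest.raises(WeightsError, match="asymmetric"):
            read_gal(path)
        w = read_gal(path, symmetrize=True)
        # union oracle: A-B and B-C edges both present
        expected = build_rook_from_edges([("A", "B"), ("B", "C")], ABC)
        assert np.array_equal(w.W0, expected.W0)


class TestEdgeCsv:
    def test_round_trip(self, tmp_path):
        w = build_rook_from_edges([("A", "B"), ("B", "C")], ABC)
        path = tmp_path / "edges.csv"
        write_edge_csv(w, path)
        edges = read_edge_csv(path)
        assert build_rook_from_edges(edges, ABC).W0.tolist() == w.W0.tolist()

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("A,B\nB,C\n")
        with pytest.raises(WeightsError, match="src,dst"):
            read_edge_csv(path)


class TestChinaFixture:
    def test_structure(self):
        w = china_provinces()
        assert w.n == 31
        assert np.array_equal(w.W0, w.W0.T)
        assert np.all(np.diag(w.W0) == 0)
        assert w.isolates() == []
        assert "Guangdong" in w.neighbors("Hainan")

    def test_unpatched_hainan_is_isolate(self):
        w = china_provinces(patch_hainan=False)
        assert w.isolates() == ["Hainan"]
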