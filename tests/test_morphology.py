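import numpy as np
import pytest

from projectomics.morphology import (
    AXON,
    SWCParseError,
    SWCStructureError,
    branch_orders,
    decompose_arbors,
    rasterize_segments,
    read_swc,
    resample_segments,
    terminal_nodes,
    total_length,
    write_swc,
)

from conftest import make_neuron, random_tree


class TestSWCIO:
    def test_minimal_tree(self, tmp_path):
        f = tmp_path / "toy.swc"
        f.write_text(
            "# toy\n1 1 0 0 0 5 -1\n2 2 10 0 0 1 1\n3 2 20 0 0 1 2\n"
        )
        n = read_swc(f)
        assert n.n_nodes == 3
        assert n.root == 0
        assert list(terminal_nodes(n, "axon")) == [2]

    def test_missing_parent_is_structure_error(self, tmp_path):
        f = tmp_path / "bad.swc"
        f.write_text("1 1 0 0 0 5 -1\n2 2 10 0 0 1 99\n")
        with pytest.raises(SWCStructureError, match="99"):
            read_swc(f)

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "bad.swc"
        f.write_text("1 1 0 0 0 5 -1\n2 2 10 0 0\n")
        with pytest.raises(SWCParseError, match=":2"):
            read_swc(f)

    def test_round_trip_preserves_count_and_length(self, tmp_path):
        rng = np.random.default_rng(7)
        n = random_tree(rng, n_nodes=40)
        write_swc(n, tmp_path / "rt.swc")
        back = read_swc(tmp_path / "rt.swc")
        assert back.n_nodes == n.n_nodes
        assert total_length(back, "axon") == pytest.approx(
            total_length(n, "axon"), abs=1e-9
        )

    def test_cycle_detected(self):
        with pytest.raises(SWCStructureError):
            make_neuron([[0, 0, 0]] * 3, [-1, 2, 1], [1, 2, 2])


class TestBranchOrders:
    def test_unbranched_path(self):
        n = make_neuron([[i * 10, 0, 0] for i in range(5)],
                        [-1, 0, 1, 2, 3], [2] * 5)
        orders = branch_orders(n, "axon")
        assert set(orders.values()) == {0}
        assert len(terminal_nodes(n, "axon")) == 1

    def test_single_bifurcation(self):
        # 0 -> 1 -> {2, 3}
        n = make_neuron([[0, 0, 0], [10, 0, 0], [20, 5, 0], [20, -5, 0]],
                        [-1, 0, 1, 1], [2] * 4)
        orders = branch_orders(n, "axon")
        assert orders[1] == 0 and orders[2] == 0
        assert orders[3] == 1 and orders[4] == 1

    def test_full_binary_tree_depth3(self):
        # brute-force oracle: order = number of strict bifurcation ancestors
        xyz, parent = [[0.0, 0.0, 0.0]], [-1]
        nodes = [0]
        rng = np.random.default_rng(3)
        for _ in range(3):
            new = []
            for p in nodes:
                for _ in range(2):
                    parent.append(p)
                    xyz.append(list(np.asarray(xyz[p]) + rng.normal(size=3)))
                    new.append(len(parent) - 1)
            nodes = new
        n = make_neuron(np.array(xyz), parent, [2] * len(parent))
        orders = branch_orders(n, "axon")

        def oracle(i):
            o, j = 0, n.parent[i]
            kids = n.children()
            while j >= 0:
                if len(kids[j]) >= 2:
                    o += 1
                j = n.parent[j]
            return o

        assert orders == {int(n.node_id[i]): oracle(i) for i in range(n.n_nodes)}
        assert max(orders.values()) == 3
        assert len(terminal_nodes(n, "axon")) == 8

    def test_invariant_under_node_permutation(self):
        rng = np.random.default_rng(11)
        n = random_tree(rng, n_nodes=25)
        orders = branch_orders(n, "axon")
        # re-label node ids arbitrarily; structure (indices) unchanged
        perm = rng.permutation(1000)[: n.n_nodes] + 1
        m = make_neuron(n.xyz, n.parent, n.compartment)
        m.node_id = perm
        orders_perm = branch_orders(m, "axon")
        for i in range(n.n_nodes):
            if n.compartment[i] == AXON:
                assert orders[int(n.node_id[i])] == orders_perm[int(perm[i])]

    def test_unknown_compartment(self):
        n = random_tree(np.random.default_rng(0), 5)
        with pytest.raises(ValueError):
            branch_orders(n, "dendritic_spine")


class TestResample:
    def test_single_segment(self):
        pts = resample_segments(np.array([[0, 0, 0], [10, 0, 0.0]]),
                                np.array([-1, 0]), step=1.0)
        assert len(pts) == 11
        assert np.allclose(pts[:, 1:], 0)
        assert np.allclose(np.sort(pts[:, 0]), np.arange(11))

    def test_large_step_keeps_endpoints(self):
        pts = resample_segments(np.array([[0, 0, 0], [10, 0, 0.0]]),
                                np.array([-1, 0]), step=100.0)
        assert len(pts) == 2

    def test_centroid_matches_length_weighted_oracle(self):
        # symmetric L with equal legs: closed-form length-weighted centroid
        xyz = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0.0]])
        parent = np.array([-1, 0, 1])
        pts = resample_segments(xyz, parent, step=0.01)
        oracle = 0.5 * (np.array([5, 0, 0.0]) + np.array([10, 5, 0.0]))
        assert np.allclose(pts.mean(axis=0), oracle, atol=1e-6)

    def test_bad_step(self):
        with pytest.raises(ValueError):
            resample_segments(np.zeros((2, 3)), np.array([-1, 0]), step=0.0)


def _supersample_cells(xyz, parent, spacing, n_samples=10_000):
    cells = set()
    for i, p in enumerate(parent):
        if p < 0:
            cells.add(tuple(np.floor(xyz[i] / spacing).astype(int)))
            continue
        t = np.linspace(0, 1, n_samples)[:, None]
        pts = xyz[p] + t * (xyz[i] - xyz[p])
        cells.update(map(tuple, np.floor(pts / spacing).astype(int)))
    return cells


class TestRasterize:
    def test_axis_aligned_segment(self):
        xyz = np.array([[5, 5, 5], [45, 5, 5.0]])
        cells = rasterize_segments(xyz, np.array([-1, 0]), 10.0)
        assert cells == {(i, 0, 0) for i in range(5)}

    def test_diagonal_matches_supersampling_oracle(self):
        xyz = np.array([[1, 1, 1], [29, 27, 25.0]])
        parent = np.array([-1, 0])
        cells = rasterize_segments(xyz, parent, 10.0)
        assert cells == _supersample_cells(xyz, parent, 10.0)

    def test_overlapping_segments_union(self):
        xyz = np.array([[5, 5, 5], [45, 5, 5], [5, 5, 5], [45, 5, 5.0]])
        parent = np.array([-1, 0, -1, 2])
        assert rasterize_segments(xyz, parent, 10.0) == {
            (i, 0, 0) for i in range(5)
        }

    def test_random_segments_agree_with_supersampling(self):
        rng = np.random.default_rng(5)
        n = random_tree(rng, n_nodes=40, step=30.0)
        cells = rasterize_segments(n.xyz, n.parent, 10.0)
        oracle = _supersample_cells(n.xyz, n.parent, 10.0)
        agreement = len(cells & oracle) / len(cells | oracle)
        assert agreement >= 0.99


class TestDecompose:
    def test_single_region_conserves_total(self, two_region_atlas):
        rng = np.random.default_rng(2)
        n = random_tree(rng, n_nodes=30, step=5.0)
        n.xyz = np.abs(n.xyz) % 80 + 5  # keep inside region 1
        arbors = decompose_arbors(n, two_region_atlas)
        assert len(arbors) == 1
        assert arbors[0].region_id == 1
        assert arbors[0].axon_length == pytest.approx(
            total_length(n, "axon"), abs=1e-9
        )

    def test_boundary_crossing_conserves_length(self, two_region_atlas):
        n = make_neuron([[50, 50, 50], [95, 50, 50], [150, 50, 50.0]],
                        [-1, 0, 1], [1, 2, 2])
        arbors = decompose_arbors(n, two_region_atlas)
        assert {a.region_id for a in arbors} == {1, 2}
        assert sum(a.axon_length for a in arbors) == pytest.approx(
            total_length(n, "axon"), abs=1e-6
        )

    def test_matches_brute_force_region_lookup(self, two_region_atlas):
        rng = np.random.default_rng(9)
        n = random_tree(rng, n_nodes=60, step=20.0)
        n.xyz = np.abs(n.xyz) % np.array([190.0, 90.0, 90.0]) + 2
        arbors = decompose_arbors(n, two_region_atlas)
        seg = n.segment_lengths()
        expected = {1: 0.0, 2: 0.0}
        for i in range(n.n_nodes):
            if n.compartment[i] == AXON and n.parent[i] >= 0:
                expected[int(two_region_atlas.lookup(n.xyz[i : i + 1])[0])] += seg[i]
        for a in arbors:
            assert a.axon_length == pytest.approx(expected[a.region_id], abs=1e-9)

    def test_hemisphere_relative_to_soma(self, two_region_atlas):
        # soma in right hemisphere: region 2 is ipsi, region 1 contra
        n = make_neuron([[150, 50, 50], [120, 50, 50], [60, 50, 50.0]],
                        [-1, 0, 1], [1, 2, 2])
        arbors = {a.region_id: a for a in decompose_arbors(n, two_region_atlas)}
        assert arbors[2].hemisphere == "ipsi"
        assert arbors[1].hemisphere == "contra"
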