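import numpy as np
import pandas as pd
import pytest

from cascn import io as cio, network
from cascn.errors import ConfigurationError
from cascn.voxelwise import build_pseudo_series

from conftest import make_pts


def cluster_table(peaks):
    return pd.DataFrame({
        "region": ["unlabeled"] * len(peaks),
        "cluster_size_voxels": [50] * len(peaks),
        "peak_x": [p[0] for p in peaks],
        "peak_y": [p[1] for p in peaks],
        "peak_z": [p[2] for p in peaks],
        "peak_stat": np.linspace(6, 4, len(peaks)),
    })


GRID = (40, 40, 40)
AFFINE = np.diag([1.5, 1.5, 1.5, 1.0])
AFFINE[:3, 3] = (-30, -30, -30)
GM = np.ones(GRID, bool)


class TestExtractROIs:
    def test_one_cluster_plus_seed_gives_two_rois(self):
        rois = network.extract_rois(
            cluster_table([(15, 0, 0)]), cio.SeedSpec((0, 0, 0), 6.0),
            GRID, AFFINE, GM,
        )
        assert rois.n_rois == 2
        assert rois.names[0] == network.SEED_NODE

    def test_close_peaks_resolved_to_nearer_center(self):
        rois = network.extract_rois(
            cluster_table([(4, 0, 0)]), cio.SeedSpec((0, 0, 0), 6.0),
            GRID, AFFINE, GM, radius_mm=6.0,
        )
        # spheres of radius 6 at distance 4 overlap; masks must be disjoint
        assert not (rois.masks[0] & rois.masks[1]).any()
        for vox in np.argwhere(rois.masks[1]):
            mm = cio.voxel_to_mm(vox, AFFINE)
            assert (np.linalg.norm(mm - np.array([4.0, 0, 0]))
                    <= np.linalg.norm(mm - np.zeros(3)) + 1e-9)

    def test_peak_within_one_voxel_of_seed_merged_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            rois = network.extract_rois(
                cluster_table([(0.5, 0.5, 0.0), (15, 0, 0)]),
                cio.SeedSpec((0, 0, 0), 6.0), GRID, AFFINE, GM,
            )
        assert rois.n_rois == 2  # seed + the distant cluster only

    def test_empty_cluster_table_rejected(self):
        with pytest.raises(ConfigurationError):
            network.extract_rois(
                cluster_table([]), cio.SeedSpec((0, 0, 0), 6.0), GRID, AFFINE, GM
            )


class TestPairwiseGCA:
    def test_both_directions_computed_and_generally_unequal(self):
        rng = np.random.default_rng(0)
        n = 60
        x = np.cumsum(rng.standard_normal(n)) * 0.1 + rng.standard_normal(n) * 0.05
        y = 0.6 * np.roll(x, 1) + rng.standard_normal(n) * 0.3
        series = np.column_stack([x, y])
        pts = make_pts(series)
        rois = network.ROISet(
            names=["a", "b"],
            centers_mm=np.zeros((2, 3)),
            masks=np.stack([
                np.array([True, False]).reshape(2, 1, 1),
                np.array([False, True]).reshape(2, 1, 1),
            ]),
        )
        coef, tstat, df = network.pairwise_gca(pts, rois)
        assert np.isnan(coef[0, 0]) and np.isnan(coef[1, 1])
        assert np.isfinite(coef[0, 1]) and np.isfinite(coef[1, 0])
        assert coef[0, 1] != pytest.approx(coef[1, 0], abs=1e-6)
        assert df > 0

    def test_duplicated_series_nearly_symmetric(self):
        rng = np.random.default_rng(1)
        n = 80
        base = np.sort(rng.standard_normal(n))  # a shared monotone trend
        a = base + rng.normal(0, 0.2, n)
        b = base + rng.normal(0, 0.2, n)
        pts = make_pts(np.column_stack([a, b]))
        rois = network.ROISet(
            names=["a", "b"], centers_mm=np.zeros((2, 3)),
            masks=np.stack([
                np.array([True, False]).reshape(2, 1, 1),
                np.array([False, True]).reshape(2, 1, 1),
            ]),
        )
        coef, _, _ = network.pairwise_gca(pts, rois)
        assert coef[0, 1] == pytest.approx(coef[1, 0], abs=0.25)


class TestThresholdNetwork:
    def test_all_negative_matrix_gives_empty_network(self):
        coef = -np.abs(np.random.default_rng(2).normal(size=(4, 4)))
        t = np.full((4, 4), 5.0)
        with pytest.warns(UserWarning, match="no edge"):
            net = network.threshold_network(coef, t, 50, list("abcd"))
        assert net.n_edges == 0

    def test_single_strong_edge_among_nulls_retained_alone(self):
        rng = np.random.default_rng(3)
        k = 5
        coef = rng.normal(0, 0.05, (k, k))
        tstat = rng.normal(0, 1.0, (k, k))
        np.fill_diagonal(coef, np.nan)
        np.fill_diagonal(tstat, np.nan)
        coef[1, 3] = 0.6
        tstat[1, 3] = 6.0
        net = network.threshold_network(coef, tstat, 60, list("abcde"), alpha=0.01)
        assert net.edges() == [("b", "d", pytest.approx(0.6 / np.nanstd(
            coef[~np.eye(k, dtype=bool)]), rel=1e-6))]

    def test_nonsignificant_positive_entries_dropped(self):
        coef = np.array([[np.nan, 0.5], [0.6, np.nan]])
        t = np.array([[np.nan, 0.5], [4.0, np.nan]])
        net = network.threshold_network(coef, t, 40, ["a", "b"])
        assert [(u, v) for u, v, _ in net.edges()] == [("b", "a")]

    def test_edge_set_invariant_to_node_relabeling(self):
        rng = np.random.default_rng(4)
        k = 6
        coef = rng.normal(0.1, 0.2, (k, k))
        tstat = rng.normal(1.0, 2.0, (k, k))
        np.fill_diagonal(coef, np.nan)
        np.fill_diagonal(tstat, np.nan)
        nodes = list("abcdef")
        net1 = network.threshold_network(coef, tstat, 50, nodes)
        perm = rng.permutation(k)
        net2 = network.threshold_network(
            coef[np.ix_(perm, perm)], tstat[np.ix_(perm, perm)], 50,
            [nodes[i] for i in perm],
        )
        assert sorted((u, v) for u, v, _ in net1.edges()) == sorted(
            (u, v) for u, v, _ in net2.edges()
        )

    def test_stored_weights_positive(self):
        rng = np.random.default_rng(5)
        coef = rng.normal(0, 0.3, (5, 5))
        tstat = rng.normal(0, 3, (5, 5))
        np.fill_diagonal(coef, np.nan)
        np.fill_diagonal(tstat, np.nan)
        net = network.threshold_network(coef, tstat, 50, list("abcde"))
        assert all(w > 0 for _, _, w in net.edges())


def simple_net(edges, nodes, seed_node="seed"):
    k = len(nodes)
    w = np.full((k, k), np.nan)
    for u, v, wt in edges:
        w[nodes.index(u), nodes.index(v)] = wt
    return network.DirectedNetwork(nodes=nodes, weights=w, seed_node=seed_node)


class TestDegrees:
    def test_single_edge_bookkeeping(self):
        net = simple_net([("a", "b", 2.5)], ["a", "b"], seed_node="a")
        d = network.compute_degrees(net).set_index("node")
        assert d.loc["a", "out_degree"] == 2.5
        assert d.loc["a", "net_degree"] == 2.5
        assert d.loc["b", "net_degree"] == -2.5
        assert d["net_degree"].sum() == 0.0

    def test_three_cycle_hand_computation(self):
        net = simple_net(
            [("a", "b", 1.0), ("b", "c", 2.0), ("c", "a", 3.0)],
            ["a", "b", "c"], seed_node="a",
        )
        d = network.compute_degrees(net).set_index("node")
        assert d.loc["a", "net_degree"] == -2.0
        assert d.loc["b", "net_degree"] == 1.0
        assert d.loc["c", "net_degree"] == 1.0
        assert d.loc["a", "class"] == "target"

    def test_net_degree_sums_to_zero_fuzz(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            k = rng.integers(2, 9)
            w = np.where(rng.random((k, k)) < 0.4,
                         rng.exponential(1.0, (k, k)), np.nan)
            np.fill_diagonal(w, np.nan)
            net = network.DirectedNetwork(
                nodes=[f"n{i}" for i in range(k)], weights=w, seed_node="n0"
            )
            d = network.compute_degrees(net)
            assert d["net_degree"].sum() == pytest.approx(0.0, abs=1e-12)
            assert (d["out_degree"] >= 0).all() and (d["in_degree"] >= 0).all()

    def test_positive_net_with_seed_input_is_transitional(self):
        net = simple_net(
            [("seed", "m", 1.0), ("m", "t", 3.0), ("seed", "t", 1.0)],
            ["seed", "m", "t"],
        )
        d = network.compute_degrees(net).set_index("node")
        assert d.loc["m", "class"] == "transitional"
        assert d.loc["seed", "class"] == "source"
        assert d.loc["t", "class"] == "target"

    def test_positive_net_never_classified_target(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = rng.integers(2, 7)
            w = np.where(rng.random((k, k)) < 0.5,
                         rng.exponential(1.0, (k, k)), np.nan)
            np.fill_diagonal(w, np.nan)
            net = network.DirectedNetwork(
                nodes=[f"n{i}" for i in range(k)], weights=w, seed_node="n0"
            )
            d = network.compute_degrees(net)
            bad = d[(d["net_degree"] > 0) & (d["class"] == "target")]
            assert len(bad) == 0

    def test_zero_net_degree_is_neutral(self):
        net = simple_net([("a", "b", 1.0), ("b", "a", 1.0)], ["a", "b"],
                         seed_node="a")
        d = network.compute_degrees(net).set_index("node")
        assert set(d["class"]) == {"neutral"}


class TestExport:
    def test_graphml_round_trip(self, tmp_path):
        net = simple_net(
            [("seed", "m", 1.5), ("m", "t", 3.25)], ["seed", "m", "t"]
        )
        network.export_network(net, network.compute_degrees(net), tmp_path)
        back = network.read_graphml(tmp_path / "network.graphml")
        assert sorted(back.nodes) == sorted(net.nodes)
        assert sorted(back.edges()) == sorted(net.edges())

    def test_empty_network_writes_header_only_files(self, tmp_path):
        net = network.DirectedNetwork(
            nodes=["a", "b"], weights=np.full((2, 2), np.nan), seed_node="a"
        )
        network.export_network(net, network.compute_degrees(net), tmp_path)
        edges = (tmp_path / "edges.tsv").read_text().strip().splitlines()
        assert edges == ["source\ttarget\tweight_z"]

    def test_degrees_sorted_by_descending_net(self, tmp_path):
        net = simple_net(
            [("a", "b", 1.0), ("b", "c", 2.0), ("c", "a", 3.0)],
            ["a", "b", "c"], seed_node="a",
        )
        network.export_network(net, network.compute_degrees(net), tmp_path)
        d = pd.read_csv(tmp_path / "degrees.tsv", sep="\t")
        assert list(d["net_degree"]) == sorted(d["net_degree"], reverse=True)
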