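"""Filters, normalization, compartments, and hex-grid geometry."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spotlink.dataset import SpotDataset
from spotlink.errors import SpotlinkError, ValidationError
from spotlink.preprocess import (adjacent_cluster_pairs,
                                 build_neighbor_graph,
                                 compartment_proportions,
                                 filter_low_quality_spots,
                                 filter_rare_genes, merge_compartments,
                                 normalize_logcpm, subset_region)
from spotlink.synthetic import hex_grid

from conftest import make_dataset


class TestSpotFilter:
    def test_low_count_spots_removed(self):
        ds = make_dataset(np.array([[0, 10, 500, 800]]))
        out = filter_low_quality_spots(ds, min_counts=100)
        assert out.n_spots == 2

    def test_exclude_list_also_removes(self):
        ds = make_dataset(np.array([[0, 10, 500, 800]]))
        out = filter_low_quality_spots(ds, min_counts=100,
                                       exclude_spot_ids=["s1_sp2"])
        assert list(out.obs.index) == ["s1_sp3"]

    def test_noop_when_thresholds_trivial(self, toy_dataset):
        out = filter_low_quality_spots(toy_dataset, min_counts=0)
        assert out.n_spots == toy_dataset.n_spots

    def test_removing_everything_is_hard_error(self):
        ds = make_dataset(np.array([[1, 1]]))
        with pytest.raises(SpotlinkError):
            filter_low_quality_spots(ds, min_counts=10)


class TestGeneFilter:
    @pytest.mark.parametrize("n_detected,retained", [(2, False), (3, True)])
    def test_boundary_at_2_5_percent_of_100_spots(self, n_detected, retained):
        counts = np.zeros((2, 100), dtype=int)
        counts[0, :n_detected] = 1
        counts[1, :] = 5      # keeps the dataset non-empty
        ds = make_dataset(counts)
        out = filter_rare_genes(ds, 0.025)
        assert ("G0" in out.gene_ids) == retained

    def test_all_zero_gene_dropped(self):
        counts = np.array([[0] * 10, [3] * 10])
        out = filter_rare_genes(make_dataset(counts), 0.025)
        assert list(out.gene_ids) == ["G1"]

    def test_matches_brute_force_scan_and_is_idempotent(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(1, 0.7, size=(80, 60))
        ds = make_dataset(counts)
        thr = 0.1
        out = filter_rare_genes(ds, thr)
        expected = [f"G{i}" for i in range(80)
                    if sum(1 for c in counts[i] if c > 0) / 60 >= thr]
        assert list(out.gene_ids) == expected
        again = filter_rare_genes(out, thr)
        assert list(again.gene_ids) == expected


class TestNormalization:
    def test_closed_forms(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 100
        counts[1, 0] = 10000 - 100
        norm = normalize_logcpm(make_dataset(counts))
        assert norm[0, 0] == pytest.approx(np.log2(101))

    def test_zero_count_is_zero_exactly(self, toy_dataset):
        ds = filter_low_quality_spots(toy_dataset, 1)
        norm = normalize_logcpm(ds)
        assert norm[ds.counts == 0].sum() == 0.0

    def test_scale_invariance_per_spot(self):
        counts = np.array([[3, 1], [7, 9], [0, 2]])
        doubled = counts * 2
        n1 = normalize_logcpm(make_dataset(counts))
        n2 = normalize_logcpm(make_dataset(doubled))
        np.testing.assert_allclose(n1, n2)

    def test_zero_total_spot_is_internal_error(self):
        ds = make_dataset(np.array([[1, 0], [1, 0]]))
        with pytest.raises(SpotlinkError):
            normalize_logcpm(ds)


class TestCompartments:
    def _clustered(self):
        counts = np.ones((1, 6), dtype=int)
        return make_dataset(counts,
                            cluster=["T1", "T2", "I1", "C1", "T1", "I1"])

    def test_merge_and_proportions(self):
        ds = merge_compartments(self._clustered(),
                                {"T1": "tumor", "T2": "tumor",
                                 "I1": "immune", "C1": "CAF"})
        assert set(ds.obs["compartment"]) == {"tumor", "immune", "CAF"}
        props = compartment_proportions(ds)
        assert props.loc["s1"].sum() == pytest.approx(1.0, abs=1e-12)
        assert props.loc["s1", "tumor"] == pytest.approx(3 / 6)

    def test_missing_map_entry_names_cluster(self):
        with pytest.raises(ValidationError, match="C1"):
            merge_compartments(self._clustered(),
                               {"T1": "tumor", "T2": "tumor", "I1": "immune"})

    def test_single_cluster_dataset(self):
        ds = make_dataset(np.ones((1, 3), dtype=int), cluster=["X"] * 3)
        out = merge_compartments(ds, {"X": "tumor"})
        assert (out.obs["compartment"] == "tumor").all()

    def test_one_spot_sample_has_fraction_one(self):
        ds = make_dataset(np.ones((1, 1), dtype=int), cluster=["X"])
        props = compartment_proportions(merge_compartments(ds, {"X": "CAF"}))
        assert props.loc["s1", "CAF"] == 1.0


def brute_force_edges(obs):
    """Quadratic reference adjacency for small patches."""
    idx = list(range(len(obs)))
    edges = set()
    for i, j in itertools.combinations(idx, 2):
        a, b = obs.iloc[i], obs.iloc[j]
        if a["sample_id"] != b["sample_id"]:
            continue
        dr = abs(int(a["array_row"]) - int(b["array_row"]))
        dc = abs(int(a["array_col"]) - int(b["array_col"]))
        if (dr, dc) in {(0, 2), (1, 1)}:
            edges.add((i, j))
    return edges


class TestNeighborGraph:
    def test_neighbor_offsets_of_single_spot(self):
        coords = [(2, 4), (2, 2), (2, 6), (1, 3), (1, 5), (3, 3), (3, 5)]
        counts = np.ones((1, len(coords)), dtype=int)
        ds = make_dataset(counts, rows=[r for r, _ in coords],
                          cols=[c for _, c in coords])
        g = build_neighbor_graph(ds)
        assert g.degrees()[0] == 6

    def test_isolated_spot_degree_zero(self):
        ds = make_dataset(np.ones((1, 2), dtype=int), rows=[0, 10],
                          cols=[0, 10])
        assert build_neighbor_graph(ds).degrees().tolist() == [0, 0]

    def test_full_patch_matches_brute_force_and_degree_bound(self):
        coords = hex_grid(10, 14)     # 70 spots
        ds = make_dataset(np.ones((1, len(coords)), dtype=int),
                          rows=coords[:, 0], cols=coords[:, 1])
        g = build_neighbor_graph(ds)
        expected = brute_force_edges(ds.obs)
        got = {(min(u, v), max(u, v)) for u, v in g.edges}
        assert got == expected
        deg = g.degrees()
        assert deg.max() == 6
        interior = (coords[:, 0] > 0) & (coords[:, 0] < 9) & \
                   (coords[:, 1] > 1) & (coords[:, 1] < 12)
        assert (deg[interior] == 6).all()

    def test_cross_sample_edges_never_created(self):
        counts = np.ones((1, 2), dtype=int)
        obs_rows, obs_cols = [0, 0], [0, 2]
        ds1 = make_dataset(counts, rows=obs_rows, cols=obs_cols)
        obs = ds1.obs.copy()
        obs.loc[obs.index[1], "sample_id"] = "s2"
        ds = SpotDataset(counts, ds1.gene_ids, obs)
        assert len(build_neighbor_graph(ds).edges) == 0

    def test_parity_violation_rejected(self):
        ds = make_dataset(np.ones((1, 2), dtype=int), rows=[0, 0],
                          cols=[0, 1])
        with pytest.raises(ValidationError, match="parity"):
            build_neighbor_graph(ds)


class TestClusterAdjacency:
    def _two_cluster_strip(self, n_contact):
        # two rows of spots; contacts along the (1,1) diagonals
        coords = [(0, 2 * j) for j in range(n_contact)] + \
                 [(1, 2 * j + 1) for j in range(n_contact)]
        counts = np.ones((1, len(coords)), dtype=int)
        cluster = ["A"] * n_contact + ["B"] * n_contact
        return make_dataset(counts, rows=[r for r, _ in coords],
                            cols=[c for _, c in coords], cluster=cluster)

    def test_contact_count_matches_brute_force(self):
        ds = self._two_cluster_strip(8)
        g = build_neighbor_graph(ds)
        brute = 0
        for i, j in brute_force_edges(ds.obs):
            if ds.obs["cluster"].iloc[i] != ds.obs["cluster"].iloc[j]:
                brute += 1
        contacts = g.cluster_contact_counts(ds.obs["cluster"])
        assert contacts[("A", "B")] == brute

    @pytest.mark.parametrize("threshold,expected", [(10, True), (16, False)])
    def test_contact_floor(self, threshold, expected):
        ds = self._two_cluster_strip(8)   # 15 boundary edges
        g = build_neighbor_graph(ds)
        pairs = adjacent_cluster_pairs(g, ds.obs["cluster"], threshold)
        assert (("A", "B") in pairs) == expected


class TestSubsetRegion:
    def test_subset_keeps_gene_universe(self):
        ds = make_dataset(np.ones((2, 4), dtype=int),
                          cluster=["A", "A", "B", "C"])
        out = subset_region(ds, {"A", "B"})
        assert out.n_spots == 3 and out.n_genes == 2

    def test_subset_all_is_identity_on_spots(self):
        ds = make_dataset(np.ones((1, 3), dtype=int),
                          cluster=["A", "B", "B"])
        assert subset_region(ds, {"A", "B"}).n_spots == 3

    def test_empty_or_unknown_subset_rejected(self):
        ds = make_dataset(np.ones((1, 3), dtype=int), cluster=["A"] * 3)
        with pytest.raises(ValidationError):
            subset_region(ds, set())
        with pytest.raises(ValidationError, match="Z"):
            subset_region(ds, {"Z"})


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.floats(min_value=0.05, max_value=0.6))
def test_gene_filter_idempotent_property(seed, threshold):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(0.5, size=(30, 40))
    counts[0, :] = 1      # guarantee a survivor
    ds = make_dataset(counts)
    once = filter_rare_genes(ds, threshold)
    twice = filter_rare_genes(once, threshold)
    assert list(once.gene_ids) == list(twice.gene_ids)
    np.testing.assert_array_equal(once.counts, twice.counts)
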