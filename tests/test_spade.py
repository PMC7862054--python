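import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from cytoprof import synthetic as syn
from cytoprof.preprocessing import EventMatrix
from cytoprof.spade import (
    GatingHierarchy,
    PopulationRule,
    assign_cells,
    build_mst,
    cluster_to_nodes,
    density_dependent_downsample,
    fit_spade,
    gate_cells,
    gate_nodes_to_populations,
    population_counts,
    population_fractions,
)


class TestDownsampling:
    def test_target_one_keeps_everything(self, rng):
        x = rng.normal(size=(200, 3))
        kept = density_dependent_downsample(x, target_fraction=1.0, rng=rng)
        assert np.array_equal(kept, np.arange(200))

    def test_uniform_blob_hits_target_rate(self):
        rates = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(size=(3000, 2))
            kept = density_dependent_downsample(x, 0.10, rng=seed)
            rates.append(len(kept) / 3000)
        assert 0.08 <= np.mean(rates) <= 0.12

    def test_density_equalization(self, rng):
        # dense blob (10x the cells in the same volume) vs sparse blob:
        # after downsampling the kept-count ratio must shrink toward 1
        dense = rng.normal(0, 0.3, size=(4000, 2))
        sparse = rng.normal(8, 0.3, size=(400, 2))
        x = np.vstack([dense, sparse])
        kept = density_dependent_downsample(x, 0.10, rng=1)
        kept_dense = (kept < 4000).sum()
        kept_sparse = (kept >= 4000).sum()
        assert kept_sparse > 0
        assert kept_dense / kept_sparse < 10  # strictly closer to parity

    def test_tiny_input_returned_whole(self):
        x = np.zeros((1, 2))
        assert np.array_equal(density_dependent_downsample(x, 0.1, rng=0), [0])


class TestClustering:
    def test_one_node_per_distinct_cell(self, rng):
        x = rng.normal(size=(12, 2))
        labels, medians = cluster_to_nodes(x, n_nodes=12, rng=0)
        assert sorted(labels) == list(range(12))
        # each node median is the single member itself
        order = np.argsort(labels)
        assert np.allclose(medians[labels[order]], x[order])

    def test_two_separated_blobs(self, rng):
        a = rng.normal(0, 0.2, size=(150, 2))
        b = rng.normal(10, 0.2, size=(150, 2))
        labels, medians = cluster_to_nodes(np.vstack([a, b]), n_nodes=2, rng=0)
        assert len(np.unique(labels)) == 2
        centers = np.sort(medians[:, 0])
        assert abs(centers[0] - 0) < 0.5 and abs(centers[1] - 10) < 0.5

    def test_partition_property_minibatch_path(self, rng):
        x = rng.normal(size=(25_000, 3))
        labels, medians = cluster_to_nodes(x, n_nodes=30, rng=0)
        assert labels.shape == (25_000,)
        counts = np.bincount(labels, minlength=30)
        assert (counts > 0).all()  # exactly 30 non-empty clusters

    def test_too_few_cells_warns_and_reduces(self, rng):
        with pytest.warns(UserWarning, match="reducing node count"):
            labels, medians = cluster_to_nodes(rng.normal(size=(5, 2)),
                                               n_nodes=10, rng=0)
        assert medians.shape[0] == 5


def _exhaustive_mst_weight(points):
    """Minimum total weight over all spanning trees (edge subsets)."""
    n = len(points)
    dist = squareform(pdist(points, metric="cityblock"))
    all_edges = list(itertools.combinations(range(n), 2))
    best = np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(dist[i, j] for i, j in subset))
    return best


class TestMst:
    def test_single_node(self):
        assert build_mst(np.zeros((1, 3))) == []

    def test_collinear_nodes(self):
        edges = build_mst(np.array([[0.0], [1.0], [10.0]]))
        assert edges == [(0, 1), (1, 2)]

    def test_matches_exhaustive_search(self, rng):
        for _ in range(3):
            pts = rng.normal(size=(6, 2))
            edges = build_mst(pts)
            dist = squareform(pdist(pts, metric="cityblock"))
            got = sum(dist[i, j] for i, j in edges)
            assert got == pytest.approx(_exhaustive_mst_weight(pts), rel=1e-9)
            assert len(edges) == 5


class TestAssignment:
    def test_exact_median_match(self):
        medians = np.array([[0.0, 0.0], [5.0, 5.0]])
        labels = assign_cells(medians, np.array([[5.0, 5.0], [0.1, -0.1]]))
        assert labels.tolist() == [1, 0]

    def test_tie_breaks_to_lowest_id(self):
        medians = np.array([[0.0], [2.0]])
        assert assign_cells(medians, np.array([[1.0]])).tolist() == [0]

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_cells(np.zeros((2, 3)), np.zeros((5, 2)))

    def test_blob_sample_lands_on_its_nodes(self, rng):
        a = rng.normal(0, 0.3, size=(300, 2))
        b = rng.normal(6, 0.3, size=(300, 2))
        _, medians = cluster_to_nodes(np.vstack([a, b]), n_nodes=6, rng=0)
        sample = rng.normal(0, 0.3, size=(500, 2))
        labels = assign_cells(medians, sample)
        blob_a_nodes = np.flatnonzero(medians[:, 0] < 3)
        assert np.isin(labels, blob_a_nodes).mean() >= 0.95


class TestFitSpade:
    def test_cell_conservation_and_tree_shape(self, small_cohort):
        samples = [small_cohort.events[s] for s in
                   list(small_cohort.events)[:6]]
        tree = fit_spade(samples, n_nodes=25, downsample_fraction=0.2, rng=0)
        assert len(tree.edges) == tree.n_nodes - 1
        counts = tree.per_sample_node_counts
        for s in samples:
            assert counts.loc[s.sample_id].sum() == s.n_cells

    def test_requires_arcsinh_scale(self):
        m = EventMatrix("x", ["a"], np.ones((10, 1)), scale="raw")
        with pytest.raises(ValueError, match="arcsinh"):
            fit_spade([m], n_nodes=2)


class TestGating:
    def test_rule_chain_reaches_deepest(self, hierarchy):
        chans = syn.default_channels()
        cell = np.full((1, len(chans)), 0.3)
        cell[0, chans.index("CD3")] = 3.0
        cell[0, chans.index("CD8")] = 3.0
        cell[0, chans.index("CD45RA")] = 3.0
        cell[0, chans.index("CD27")] = 3.0
        assert gate_cells(cell, chans, hierarchy)[0] == "CD8 naive"

    def test_failing_root_rule_is_ungated(self, hierarchy):
        chans = syn.default_channels()
        cell = np.full((1, len(chans)), 0.3)
        assert gate_cells(cell, chans, hierarchy)[0] == "ungated"

    def test_contradictory_rules_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            GatingHierarchy([
                PopulationRule("root", None, (("CD3", "above", 2.0),)),
                PopulationRule("kid", "root", (("CD3", "below", 1.0),)),
            ])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            GatingHierarchy([
                PopulationRule("a", "b", ()),
                PopulationRule("b", "a", ()),
            ])

    def test_truth_recovery_on_synthetic_cells(self, small_cohort, hierarchy):
        """>= 90% of generated cells gate back to their true population."""
        ok = tot = 0
        for sid in list(small_cohort.events)[:8]:
            m = small_cohort.events[sid]
            pred = gate_cells(m.values, m.channels, hierarchy)
            truth = small_cohort.cell_labels[sid]
            match = (pred == truth) | ((truth == "other") & (pred == "ungated"))
            ok += match.sum()
            tot += len(match)
        assert ok / tot >= 0.90

    def test_node_gating_matches_cell_gating_on_medians(self, hierarchy):
        from cytoprof.spade import SpadeTree

        chans = syn.default_channels()
        rng = np.random.default_rng(0)
        medians = rng.uniform(0, 4, size=(20, len(chans)))
        tree = SpadeTree(chans, medians, [])
        node_map = gate_nodes_to_populations(tree, hierarchy)
        per_cell = gate_cells(medians, chans, hierarchy)
        assert [node_map[i] for i in range(20)] == list(per_cell)


class TestPopulationFractions:
    def test_worked_example(self):
        hier = GatingHierarchy([
            PopulationRule("parent", None, ()),
            PopulationRule("child", "parent", ()),
        ])
        labels = {"s": np.array(["child"] * 50 + ["parent"] * 50 +
                                ["ungated"] * 100)}
        counts = population_counts(labels, hier)
        assert counts.loc["s", "parent"] == 100  # child cells roll up
        fr = population_fractions(counts, hier).set_index("population")
        assert fr.loc["parent", "pct_total"] == pytest.approx(0.5)
        assert fr.loc["child", "pct_parent"] == pytest.approx(0.5)
        assert fr.loc["child", "pct_total"] == pytest.approx(0.25)

    def test_child_equals_parent(self):
        hier = GatingHierarchy([
            PopulationRule("p", None, ()),
            PopulationRule("c", "p", ()),
        ])
        counts = population_counts({"s": np.array(["c"] * 10)}, hier)
        fr = population_fractions(counts, hier).set_index("population")
        assert fr.loc["c", "pct_parent"] == pytest.approx(1.0)

    def test_chain_identity_on_synthetic_tables(self, small_cohort, hierarchy):
        """%total(child) == %parent(child) * %total(parent) everywhere."""
        labels = {sid: small_cohort.cell_labels[sid]
                  for sid in list(small_cohort.events)[:6]}
        counts = population_counts(labels, hierarchy)
        fr = population_fractions(counts, hierarchy)
        piv = fr.set_index(["sample_id", "population"])
        for (sid, pop), row in piv.iterrows():
            parent = hierarchy.parent(pop)
            if parent is None or not np.isfinite(row.pct_parent):
                continue
            expected = row.pct_parent * piv.loc[(sid, parent), "pct_total"]
            assert row.pct_total == pytest.approx(expected, abs=1e-9)

    def test_empty_parent_yields_nan_pct_parent(self):
        hier = GatingHierarchy([
            PopulationRule("p", None, ()),
            PopulationRule("c", "p", ()),
        ])
        counts = pd.DataFrame({"p": [0], "c": [0], "total": [100]},
                              index=["s"])
        fr = population_fractions(counts, hier).set_index("population")
        assert np.isnan(fr.loc["c", "pct_parent"])
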