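"""knn graph, diffusion map, Leiden, cluster connectivity, pseudotime."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

import cytolineage as cl
from cytolineage.graph import GraphError, transition_matrix


def chain_graph(n):
    """knn graph of points on a line (a discretized trajectory)."""
    x = np.linspace(0, 1, n)[:, None]
    return cl.build_knn_graph(np.hstack([x, np.zeros_like(x)]), k=2), x.ravel()


class TestKnnGraph:
    def test_equidistant_triplet_is_complete(self):
        X = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        g = cl.build_knn_graph(X, k=2)
        assert g.adjacency.nnz == 6  # complete graph on 3 nodes, both directions
        assert g.adjacency.diagonal().sum() == 0

    def test_separated_blobs_stay_disconnected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (100, 3))
        b = rng.normal(50, 0.1, (100, 3))
        g = cl.build_knn_graph(np.vstack([a, b]), k=5)
        cross = g.adjacency[:100, 100:]
        assert cross.nnz == 0
        n_comp, _ = g.components()
        assert n_comp == 2

    def test_duplicates_no_self_loops_max_weight(self):
        X = np.zeros((10, 2))
        X[5:] = 1.0
        g = cl.build_knn_graph(X, k=3)
        assert g.adjacency.diagonal().sum() == 0
        assert g.adjacency.max() == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        g = cl.build_knn_graph(rng.normal(0, 1, (200, 5)), k=7)
        assert (g.adjacency != g.adjacency.T).nnz == 0
        assert (g.adjacency.data > 0).all()

    def test_min_degree_at_least_k(self):
        rng = np.random.default_rng(2)
        g = cl.build_knn_graph(rng.normal(0, 1, (100, 4)), k=6)
        degrees = np.diff(g.adjacency.indptr)
        assert degrees.min() >= 6  # union symmetrization only adds edges

    @pytest.mark.parametrize("X, k, match", [
        (np.zeros((10, 2)) + 3.0, 3, "variance"),
        (np.random.default_rng(0).normal(0, 1, (5, 2)), 5, "k ="),
    ])
    def test_invalid_inputs(self, X, k, match):
        with pytest.raises(GraphError, match=match):
            cl.build_knn_graph(X, k=k)


class TestDiffusionMap:
    def test_transition_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        g = cl.build_knn_graph(rng.normal(0, 1, (300, 4)), k=10)
        P = transition_matrix(g)
        np.testing.assert_allclose(np.asarray(P.sum(axis=1)).ravel(), 1.0,
                                   atol=1e-10)

    def test_first_component_monotone_on_a_chain(self):
        g, x = chain_graph(20)
        emb = cl.diffusion_map(g, m=3)
        first = emb.coordinates[:, 0]
        diffs = np.diff(first)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_disconnected_graph_embedded_per_component(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (60, 3)), rng.normal(50, 0.1, (60, 3))])
        g = cl.build_knn_graph(X, k=5)
        emb = cl.diffusion_map(g, m=4)
        assert np.isfinite(emb.coordinates).all()
        assert set(np.unique(emb.component)) == {0, 1}

    def test_complete_graph_flagged_degenerate(self):
        X = np.array([[np.cos(a), np.sin(a)] for a in
                      np.linspace(0, 2 * np.pi, 7)[:-1]])
        g = cl.build_knn_graph(X, k=5)  # all-to-all, symmetric spectrum
        emb = cl.diffusion_map(g, m=3)
        assert emb.degenerate

    def test_m_too_large_rejected(self):
        g, _ = chain_graph(10)
        with pytest.raises(GraphError, match="m ="):
            cl.diffusion_map(g, m=10)


class TestLeiden:
    def test_disconnected_cliques_never_merge(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.05, (80, 2)), rng.normal(30, 0.05, (80, 2))])
        g = cl.build_knn_graph(X, k=5)
        for resolution in (0.1, 1.0, 5.0):
            part = cl.leiden_partition(g, resolution=resolution, seed=0)
            left = set(part.labels[:80].tolist())
            right = set(part.labels[80:].tolist())
            assert not (left & right)

    def test_same_seed_same_labels(self):
        rng = np.random.default_rng(4)
        g = cl.build_knn_graph(rng.normal(0, 1, (400, 5)), k=10)
        a = cl.leiden_partition(g, resolution=1.0, seed=3)
        b = cl.leiden_partition(g, resolution=1.0, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_contiguous_from_zero(self):
        rng = np.random.default_rng(5)
        g = cl.build_knn_graph(rng.normal(0, 1, (300, 4)), k=8)
        part = cl.leiden_partition(g, seed=0)
        assert set(np.unique(part.labels)) == set(range(part.n_clusters))


class TestClusterConnectivity:
    def test_no_inter_cluster_edges_scores_zero(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (50, 2)), rng.normal(40, 0.1, (50, 2))])
        g = cl.build_knn_graph(X, k=4)
        part = cl.ClusterPartition(np.repeat([0, 1], 50), 1.0, 0.0, 0)
        cg = cl.cluster_connectivity(g, part)
        assert cg.scores[0, 1] == 0.0

    def test_random_split_scores_near_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1.0, (2500, 4))
        g = cl.build_knn_graph(X, k=10)
        labels = rng.integers(0, 2, size=2500)
        part = cl.ClusterPartition(labels, 1.0, 0.0, 0)
        cg = cl.cluster_connectivity(g, part)
        assert cg.scores[0, 1] == pytest.approx(1.0, abs=0.2)

    def test_path_of_blobs_has_no_skip_edge(self):
        # three touching blobs on a line: A-B and B-C connect, A-C never does
        rng = np.random.default_rng(2)
        blobs = [rng.normal(loc, 0.3, (60, 2)) for loc in (0.0, 1.0, 2.0)]
        g = cl.build_knn_graph(np.vstack(blobs), k=5)
        part = cl.ClusterPartition(np.repeat([0, 1, 2], 60), 1.0, 0.0, 0)
        cg = cl.cluster_connectivity(g, part, threshold=0.05)
        assert cg.scores[0, 2] == 0.0
        retained = {(i, j) for i, j, _ in cg.retained_edges()}
        assert retained == {(0, 1), (1, 2)}


class TestPseudotime:
    def test_root_cell_has_zero_pseudotime(self):
        g, x = chain_graph(50)
        emb = cl.diffusion_map(g, m=3)
        labels = np.where(x < 0.1, "HSC", "other")
        pt = cl.compute_pseudotime(emb, g, "HSC", labels, seed=0)
        assert pt.values[pt.root] == 0.0
        assert labels[pt.root] == "HSC"

    @pytest.mark.parametrize("method", ["diffusion", "geodesic"])
    def test_chain_order_recovered(self, method):
        g, x = chain_graph(80)
        emb = cl.diffusion_map(g, m=3)
        labels = np.where(x <= 0.0, "HSC", "other")  # root at one end
        pt = cl.compute_pseudotime(emb, g, "HSC", labels, seed=0, method=method)
        rho = scipy.stats.spearmanr(pt.values, x).statistic
        assert abs(rho) == pytest.approx(1.0, abs=1e-9)

    def test_zero_noise_lineage_perfectly_ordered(self, lineage):
        # single unbranched arm, no noise: pseudotime == latent-time order
        dyn = cl.build_default_dynamics(lineage).scaled(noise_sd=0.0,
                                                        zero_inflation=0.0)
        effects = cl.identity_batch_effects(["b1"])
        events, truth = cl.simulate_dataset(
            lineage, dyn, effects, 1500,
            [cl.SampleDef("a", "b1", "BM", True)], seed=9)
        ery = truth.table["branch"].to_numpy() == "Ery"
        X = np.arcsinh(events.values[ery] / 5.0)
        g = cl.build_knn_graph(X, k=15)
        emb = cl.diffusion_map(g, m=10)
        pops = truth.table["population"].to_numpy()[ery]
        pt = cl.compute_pseudotime(emb, g, "HSC", pops, seed=1)
        t = truth.table["latent_time"].to_numpy()[ery]
        rho = scipy.stats.spearmanr(pt.values, t).statistic
        assert rho >= 0.99

    def test_rootless_component_flagged_unreachable(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (50, 3)), rng.normal(50, 0.1, (50, 3))])
        g = cl.build_knn_graph(X, k=5)
        emb = cl.diffusion_map(g, m=3)
        labels = np.array(["HSC"] * 50 + ["far"] * 50)
        pt = cl.compute_pseudotime(emb, g, "HSC", labels, seed=0)
        assert pt.unreachable[50:].all()
        assert np.isnan(pt.values[50:]).all()
        assert np.isfinite(pt.values[:50]).all()

    def test_empty_root_population_rejected(self):
        g, x = chain_graph(20)
        emb = cl.diffusion_map(g, m=2)
        with pytest.raises(GraphError, match="HSC"):
            cl.compute_pseudotime(emb, g, "HSC", np.full(20, "other"), seed=0)


class TestSubsetReanalyze:
    def test_all_labels_full_channels_keeps_every_cell(self, corrected_scaled):
        scaled, truth, lineage, panel = corrected_scaled
        pops = scaled.meta["population"].to_numpy()
        res = cl.run_trajectory(scaled.values, pops, seed=0)
        mc = cl.majority_vote_map(res.partition, pops)
        sub = cl.subset_and_reanalyze(
            scaled.values, scaled.channels, res.partition, res.cluster_graph,
            mc.cluster_to_label, set(mc.cluster_to_label.values()),
            scaled.channels, pops, seed=0)
        assert sub.cell_index.size == scaled.n_events

    def test_unsatisfiable_criteria_rejected(self, corrected_scaled):
        scaled, truth, lineage, panel = corrected_scaled
        pops = scaled.meta["population"].to_numpy()
        res = cl.run_trajectory(scaled.values, pops, seed=0)
        mc = cl.majority_vote_map(res.partition, pops)
        with pytest.raises(GraphError):
            cl.subset_and_reanalyze(
                scaled.values, scaled.channels, res.partition, res.cluster_graph,
                mc.cluster_to_label, {"NotALabel"}, scaled.channels, pops, seed=0)
        with pytest.raises(GraphError, match="channel"):
            cl.subset_and_reanalyze(
                scaled.values, scaled.channels, res.partition, res.cluster_graph,
                mc.cluster_to_label, {"HSC", "EMP1"}, ["NotAChannel"], pops,
                seed=0)


class TestScanpyCrossCheck:
    """Independent oracle: scanpy's PAGA on the same graph and partition."""

    def test_connectivity_scores_track_paga(self):
        import anndata as ad
        import pandas as pd
        import scanpy as sc

        rng = np.random.default_rng(0)
        # three touching blobs on a line -> chain topology
        X = np.vstack([rng.normal(loc, 0.35, (150, 3))
                       for loc in (0.0, 1.0, 2.0)])
        g = cl.build_knn_graph(X, k=10)
        part = cl.ClusterPartition(np.repeat([0, 1, 2], 150), 1.0, 0.0, 0)
        cg = cl.cluster_connectivity(g, part, threshold=0.02)

        adata = ad.AnnData(X=X.astype(np.float32))
        adata.obs["groups"] = pd.Categorical(part.labels.astype(str))
        sc.pp.neighbors(adata, n_neighbors=10)
        sc.tl.paga(adata, groups="groups")
        paga = adata.uns["paga"]["connectivities"].toarray()

        # both routes must retain the chain edges and drop the skip edge
        ours = {(i, j) for i, j, _ in cg.retained_edges()}
        theirs = {(i, j) for i in range(3) for j in range(i + 1, 3)
                  if paga[i, j] > 0.01}
        assert ours == theirs == {(0, 1), (1, 2)}
        # and rank the retained edges consistently
        assert ((cg.scores[0, 1] > cg.scores[0, 2])
                == (paga[0, 1] > paga[0, 2]))
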