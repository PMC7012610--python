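"""PCA, SNN graph, modularity clustering, dendrogram, module scores,
ADG-PC correction, doublet flags, and cluster merging."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from habquant.containers import EmbeddingSet, NormalizedMatrix, ScaledMatrix
from habquant.cluster import (
    ADG_GENES,
    ClusterConfig,
    cluster_modularity,
    cluster_tree,
    drop_pc_recluster,
    find_adg_pc,
    flag_doublet_clusters,
    merge_clusters,
    modularity,
    module_score,
    pca,
    snn_graph,
)
from habquant.qc import lognormalize
from habquant.sim import CellTypeSpec, CountSimConfig, generate_counts


def _scaled(dense):
    dense = np.asarray(dense, dtype=float)
    dense = dense - dense.mean(axis=1, keepdims=True)
    return ScaledMatrix(
        X=dense,
        genes=[f"g{i}" for i in range(dense.shape[0])],
        barcodes=[f"c{i}" for i in range(dense.shape[1])],
    )


class TestPCA:
    def test_rank_one_matrix(self, rng):
        u = rng.random(10)
        v = rng.random(8)
        emb = pca(_scaled(np.outer(u, v)), n_pcs=3)
        frac = emb.explained_variance[0] / emb.explained_variance.sum()
        assert frac > 0.999999

    def test_matches_eigendecomposition_oracle(self, rng):
        dense = rng.random((10, 8))
        scaled = _scaled(dense)
        emb = pca(scaled, n_pcs=4)
        Y = scaled.X.T  # cells x genes
        evals, evecs = np.linalg.eigh(Y.T @ Y)
        order = np.argsort(evals)[::-1][:4]
        for j, o in enumerate(order):
            v = evecs[:, o]
            dot = abs(v @ emb.loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-6)
            assert emb.explained_variance[j] == pytest.approx(
                evals[o] / (Y.shape[0] - 1), rel=1e-8
            )
        # scores reproduce the projection
        assert np.allclose(
            np.abs(Y @ emb.loadings), np.abs(emb.scores), atol=1e-6
        )

    def test_loadings_orthonormal(self, rng):
        emb = pca(_scaled(rng.random((20, 15))), n_pcs=5)
        G = emb.loadings.T @ emb.loadings
        assert np.allclose(G, np.eye(5), atol=1e-8)

    def test_n_pcs_too_large(self, rng):
        with pytest.raises(ValueError):
            pca(_scaled(rng.random((5, 4))), n_pcs=10)

    def test_sign_convention_deterministic(self, rng):
        dense = rng.random((12, 9))
        a = pca(_scaled(dense), 3)
        b = pca(_scaled(dense), 3)
        assert np.array_equal(a.scores, b.scores)
        for j in range(3):
            top = np.abs(a.loadings[:, j]).argmax()
            assert a.loadings[top, j] > 0


class TestSNNGraph:
    @staticmethod
    def _brute_force(points, k, prune):
        """Independent neighborhood/Jaccard computation from definitions."""
        n = len(points)
        hoods = []
        for i in range(n):
            d = [(np.linalg.norm(points[i] - points[j]), j) for j in range(n)]
            d.sort()
            hoods.append({j for _, j in d[:k]})
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                jac = len(hoods[i] & hoods[j]) / len(hoods[i] | hoods[j])
                W[i, j] = jac if jac >= prune else 0.0
        return W

    def test_identical_points_complete_graph(self):
        pts = np.zeros((5, 2))
        adj = snn_graph(pts, k=3, prune=0.0).todense()
        expected = self._brute_force(pts, 3, 0.0)
        assert np.allclose(adj, expected)

    def test_line_dyads(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        adj = snn_graph(pts, k=2, prune=1 / 15).todense()
        assert np.allclose(adj, self._brute_force(pts, 2, 1 / 15))
        # the two dyads are mutually disconnected
        assert adj[0, 2] == adj[0, 3] == adj[1, 2] == adj[1, 3] == 0
        assert adj[0, 1] > 0 and adj[2, 3] > 0

    def test_random_points_match_oracle(self, rng):
        pts = rng.random((25, 3))
        adj = snn_graph(pts, k=5, prune=1 / 15).todense()
        assert np.allclose(adj, self._brute_force(pts, 5, 1 / 15))

    def test_prune_removes_weak_edges(self, rng):
        pts = rng.random((30, 2))
        adj = snn_graph(pts, k=5, prune=1 / 15)
        assert adj.data.min() >= 1 / 15


def _set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


class TestClusterModularity:
    def test_two_cliques(self):
        A = np.zeros((6, 6))
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        A[i, j] = 1.0
        labels = cluster_modularity(sp.csr_matrix(A), resolution=1.0, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_partition_search(self, seed):
        """On graphs small enough to enumerate every partition, the returned
        clustering must achieve the global maximum modularity."""
        rng = np.random.default_rng(seed)
        n = 7
        A = (rng.random((n, n)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() == 0:
            A[0, 1] = A[1, 0] = 1.0
        adj = sp.csr_matrix(A)
        labels = cluster_modularity(adj, resolution=1.0, n_iterations=10, seed=3)
        achieved = modularity(adj, labels, 1.0)
        # independent brute force over all partitions
        two_m = A.sum()
        deg = A.sum(axis=1)
        best = -np.inf
        for part in _set_partitions(list(range(n))):
            q = 0.0
            for block in part:
                idx = np.array(block)
                q += A[np.ix_(idx, idx)].sum() / two_m
                q -= (deg[idx].sum() / two_m) ** 2
            best = max(best, q)
        assert achieved == pytest.approx(best, abs=1e-9)

    def test_no_edges_singletons_with_warning(self):
        adj = sp.csr_matrix((4, 4))
        with pytest.warns(UserWarning, match="no edges"):
            labels = cluster_modularity(adj)
        assert len(np.unique(labels)) == 4

    def test_deterministic_and_size_ordered(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.1, (30, 2)), rng.normal(5, 0.1, (10, 2))]
        )
        adj = snn_graph(pts, k=5, prune=1 / 15)
        a = cluster_modularity(adj, 1.0, 5, seed=4)
        b = cluster_modularity(adj, 1.0, 5, seed=4)
        assert np.array_equal(a, b)
        _, counts = np.unique(a, return_counts=True)
        assert (np.diff(counts) <= 0).all()  # label 0 is the biggest

    def test_beats_trivial_partitions(self, rng):
        pts = rng.random((40, 2))
        adj = snn_graph(pts, k=6, prune=0.0)
        labels = cluster_modularity(adj, 1.0, 5, seed=0)
        q = modularity(adj, labels, 1.0)
        assert q >= modularity(adj, np.zeros(40), 1.0) - 1e-12
        assert q >= modularity(adj, np.arange(40), 1.0) - 1e-12

    def test_agrees_with_igraph_reference(self, rng):
        """Independent route: the achieved modularity should not fall below
        what igraph's multilevel algorithm finds on the same graph."""
        igraph = pytest.importorskip("igraph")
        pts = np.vstack([rng.normal(c, 0.3, (25, 2)) for c in (0, 4, 8)])
        adj = snn_graph(pts, k=8, prune=1 / 15)
        labels = cluster_modularity(adj, 1.0, 10, seed=1)
        q_ours = modularity(adj, labels, 1.0)
        coo = sp.triu(adj).tocoo()
        g = igraph.Graph(
            n=adj.shape[0],
            edges=list(zip(coo.row.tolist(), coo.col.tolist())),
            edge_attrs={"weight": coo.data.tolist()},
        )
        ref = g.community_multilevel(weights="weight")
        q_ref = g.modularity(ref.membership, weights="weight")
        assert q_ours >= q_ref - 0.01


class TestClusterTree:
    def test_two_clusters_single_root(self, rng):
        pts = rng.random((10, 3))
        labels = np.array([0] * 5 + [1] * 5)
        tree = cluster_tree(labels, pts)
        nodes = tree.internal_nodes()
        assert len(nodes) == 1
        assert nodes[0][0] | nodes[0][1] == {0, 1}

    def test_rectangle_pairs_nearest_sides(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 5.0], [1.0, 5.0]])
        labels = np.arange(4)
        tree = cluster_tree(labels, pts)
        nodes = tree.internal_nodes()
        first_two = [nodes[0][0] | nodes[0][1], nodes[1][0] | nodes[1][1]]
        assert {frozenset({0, 1}), frozenset({2, 3})} == {
            frozenset(s) for s in first_two
        }

    def test_distances_match_cluster_means(self, rng):
        pts = rng.random((20, 4))
        labels = np.repeat([0, 1], 10)
        tree = cluster_tree(labels, pts)
        d = np.linalg.norm(
            pts[labels == 0].mean(axis=0) - pts[labels == 1].mean(axis=0)
        )
        assert tree.linkage_matrix[0, 2] == pytest.approx(d, rel=1e-9)

    def test_single_cluster_errors(self, rng):
        with pytest.raises(ValueError):
            cluster_tree(np.zeros(5), rng.random((5, 2)))

    def test_newick_contains_all_leaves(self, rng):
        pts = rng.random((12, 2))
        labels = np.repeat([0, 1, 2], 4)
        nwk = cluster_tree(labels, pts).to_newick()
        assert nwk.endswith(";")
        for c in "012":
            assert c in nwk


def _norm_from_dense(dense, genes):
    return NormalizedMatrix(
        X=sp.csr_matrix(np.asarray(dense, dtype=float)),
        genes=genes,
        barcodes=[f"c{i}" for i in range(np.asarray(dense).shape[1])],
    )


class TestModuleScore:
    def test_self_control_limit_is_zero(self, rng):
        # 10 genes, 2 bins of 5; the gene set is exactly one whole bin, so
        # its controls are the same genes and the score vanishes.
        dense = np.vstack([rng.random((5, 8)), 5 + rng.random((5, 8))])
        genes = [f"g{i}" for i in range(10)]
        norm = _norm_from_dense(dense, genes)
        score = module_score(norm, [f"g{i}" for i in range(5, 10)], n_bins=2)
        assert np.allclose(score, 0.0, atol=1e-12)

    def test_small_bin_oracle(self, rng):
        """With bins smaller than n_ctrl the controls are the entire bin,
        making the score an explicit closed form."""
        dense = np.vstack([rng.random((5, 6)), 5 + rng.random((5, 6))])
        genes = [f"g{i}" for i in range(10)]
        norm = _norm_from_dense(dense, genes)
        score = module_score(norm, ["g7", "g9"], n_bins=2, n_ctrl=100)
        set_mean = dense[[7, 9]].mean(axis=0)
        ctrl_mean = np.vstack([dense[5:10], dense[5:10]]).mean(axis=0)
        assert np.allclose(score, set_mean - ctrl_mean, atol=1e-12)

    def test_missing_genes_warn_and_drop(self, rng):
        norm = _norm_from_dense(rng.random((6, 4)), [f"g{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="dropping"):
            module_score(norm, ["g0", "nope"], n_bins=2)

    def test_all_missing_errors(self, rng):
        norm = _norm_from_dense(rng.random((4, 3)), list("abcd"))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                module_score(norm, ["zz"], n_bins=2)


class TestFindAdgPC:
    def _embedding(self, loadings, genes):
        n_pcs = loadings.shape[1]
        return EmbeddingSet(
            scores=np.zeros((3, n_pcs)),
            loadings=loadings,
            explained_variance=np.ones(n_pcs),
            genes=np.array(genes, dtype=object),
        )

    def test_constructed_enrichment_found(self, rng):
        genes = list(ADG_GENES) + [f"g{i}" for i in range(492)]
        loadings = rng.normal(0, 0.01, (500, 5))
        loadings[:8, 2] = 5.0  # all ADGs at the top of PC3
        pc, p = find_adg_pc(self._embedding(loadings, genes), top_n=50)
        assert pc == 2
        assert p < 1e-6

    def test_hypergeometric_matches_tail_sum(self, rng):
        """p for overlap k=6 of K=8 in top n=50 of N=100 equals the
        explicit hypergeometric tail sum."""
        genes = list(ADG_GENES) + [f"g{i}" for i in range(92)]
        loadings = rng.normal(0, 0.01, (100, 1))
        loadings[:6, 0] = 5.0  # 6 of 8 ADGs in the top 50
        loadings[8:52, 0] = 1.0  # fill the rest of the top-50 with others
        pc, p = find_adg_pc(self._embedding(loadings, genes), top_n=50)
        tail = sum(
            math.comb(8, k) * math.comb(92, 50 - k) / math.comb(100, 50)
            for k in range(6, 9)
        )
        assert p == pytest.approx(tail, rel=1e-9)

    def test_scattered_adgs_give_none(self, rng):
        genes = [f"g{i}" for i in range(200)]
        for i, g in enumerate(ADG_GENES):
            genes[i * 25] = g  # spread ADGs evenly through the ranking
        loadings = np.linspace(1.0, 0.0, 200)[:, None] + rng.normal(
            0, 1e-6, (200, 1)
        )
        pc, p = find_adg_pc(self._embedding(loadings, genes), top_n=50)
        assert pc is None
        assert p >= 0.05


class TestDropPcRecluster:
    def test_zero_variance_pc_leaves_labels_unchanged(self, rng):
        pts = np.vstack([rng.normal(0, 0.2, (30, 2)), rng.normal(6, 0.2, (30, 2))])
        scores = np.column_stack([pts, np.zeros(60)])
        emb = EmbeddingSet(
            scores=scores, loadings=np.zeros((3, 3)),
            explained_variance=np.array([1.0, 1.0, 0.0]),
        )
        cfg = ClusterConfig(k_neighbors=10, n_iterations=3, seed=0)
        before = cluster_modularity(
            snn_graph(scores, 10, 1 / 15), cfg.resolution, 3, 0
        )
        after, mapping = drop_pc_recluster(emb, 2, cfg, old_labels=before)
        assert np.array_equal(before, after)
        assert set(mapping.values()) == set(np.unique(after).tolist())

    def test_mapping_is_surjective(self, rng):
        pts = np.vstack([rng.normal(c, 0.3, (25, 3)) for c in (0, 5, 10)])
        emb = EmbeddingSet(
            scores=pts, loadings=np.zeros((3, 3)),
            explained_variance=np.ones(3),
        )
        cfg = ClusterConfig(k_neighbors=10, n_iterations=3, seed=1)
        before = cluster_modularity(snn_graph(pts, 10, 1 / 15), 1.2, 3, 1)
        after, mapping = drop_pc_recluster(emb, 2, cfg, old_labels=before)
        assert set(mapping.keys()) == set(np.unique(before).tolist())
        assert set(mapping.values()) <= set(np.unique(after).tolist())


class TestDoubletFlags:
    def test_requires_two_panels(self, rng):
        norm = _norm_from_dense(rng.random((4, 6)), list("abcd"))
        with pytest.raises(ValueError):
            flag_doublet_clusters(norm, np.zeros(6), {"only": ["a"]})

    def test_planted_doublet_cluster_flagged(self):
        cfg = CountSimConfig(
            n_genes=300,
            n_cells=500,
            cell_types=[
                CellTypeSpec("N", 0.5, 20, 8.0),
                CellTypeSpec("G", 0.5, 20, 8.0),
            ],
            doublet_rate=0.15,
            seed=4,
        )
        counts, truth = generate_counts(cfg)
        norm = lognormalize(counts)
        labels = np.where(
            truth.doublet & (truth.doublet_partner != truth.type_labels),
            "doublet",
            truth.type_labels,
        )
        panels = {
            "N": list(truth.marker_genes["N"]),
            "G": list(truth.marker_genes["G"]),
        }
        flags = flag_doublet_clusters(norm, labels, panels, co_expr_threshold=0.1)
        assert flags["doublet"] is True
        assert flags["N"] is False and flags["G"] is False


class TestMergeClusters:
    def test_identical_distribution_clusters_merge(self, rng):
        # one homogeneous population artificially split in two
        cfg = CountSimConfig(n_genes=200, n_cells=200, seed=6)
        counts, _ = generate_counts(cfg)
        norm = lognormalize(counts)
        pts = rng.normal(0, 1.0, (200, 5))
        labels = np.repeat([0, 1], 100)
        merged = merge_clusters(labels, pts, norm)
        assert len(np.unique(merged)) == 1

    def test_overclustered_two_types_recovered(self, two_type_dataset):
        from sklearn.metrics import adjusted_rand_score

        counts, truth, metrics, norm, scaled = two_type_dataset
        emb = pca(scaled, 20)
        adj = snn_graph(emb, 20, 1 / 15)
        labels = cluster_modularity(adj, resolution=3.0, n_iterations=5, seed=0)
        assert len(np.unique(labels)) > 2  # deliberately over-split
        merged = merge_clusters(labels, emb, norm)
        assert len(np.unique(merged)) == 2
        assert adjusted_rand_score(merged, truth.type_labels) >= 0.9
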