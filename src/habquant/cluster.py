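"""Dimensionality reduction and cluster curation.

PCA on the scaled matrix, a shared-nearest-neighbor (SNN) graph with
Jaccard edge weights, resolution-scaled modularity clustering by local
moving and aggregation with seeded restarts, cluster dendrograms from
cluster-averaged PC vectors, module scoring for the activity-dependent
gene (ADG, immediate-early gene) program, detection and removal of the
ADG-dominated principal component, doublet-cluster flagging, and
rule-based merging of poorly separated clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom

from .containers import EmbeddingSet, NormalizedMatrix, ScaledMatrix
from .sim.counts import ADG_GENES  # noqa: F401  (re-exported default gene set)


@dataclass
class ClusterConfig:
    """Defaults follow the habenula pipeline: 20 PCs, k=20 neighbors,
    SNN prune 1/15, resolution 1.2, 10 seeded restarts."""

    n_pcs: int = 20
    k_neighbors: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 1.2
    n_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pcs, self.k_neighbors, self.n_iterations) <= 0:
            raise ValueError("n_pcs, k_neighbors, n_iterations must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


# ---------------------------------------------------------------------------
# PCA


def pca(scaled: ScaledMatrix, n_pcs: int = 20) -> EmbeddingSet:
    """Truncated PCA of the scaled genes × cells matrix.

    Cells are the observations. The decomposition is deterministic up to
    per-component sign, fixed so the gene with the largest |loading| on
    each component is positive.
    """
    Y = scaled.X.T  # cells x genes, already centered per gene
    n_cells, n_genes = Y.shape
    if n_pcs > min(n_genes, n_cells):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(n_genes, n_cells)={min(n_genes, n_cells)}"
        )
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    loadings = Vt.T  # genes x n_pcs
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_pcs)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = (U * S) * flip
    explained = S**2 / max(n_cells - 1, 1)
    return EmbeddingSet(
        scores=scores,
        loadings=loadings,
        explained_variance=explained,
        genes=scaled.genes,
        barcodes=scaled.barcodes,
    )


# ---------------------------------------------------------------------------
# SNN graph


def snn_graph(
    scores: EmbeddingSet | np.ndarray, k: int = 20, prune: float = 1.0 / 15.0
) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph in PC space.

    Each cell's neighborhood is its k nearest neighbors by Euclidean
    distance, *including itself*; distance ties break by cell index. The
    edge weight between two cells is the Jaccard overlap of their
    neighborhoods; weights below ``prune`` are removed. Returns a
    symmetric sparse adjacency with zero diagonal.
    """
    P = scores.scores if isinstance(scores, EmbeddingSet) else np.asarray(scores)
    n = P.shape[0]
    if k >= n + 1:
        k = n
    D = cdist(P, P)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    B = sp.csr_matrix(
        (np.ones(n * k), (rows, order.ravel())), shape=(n, n), dtype=np.int32
    )
    inter = (B @ B.T).astype(float)
    inter = inter.tocoo()
    jac = inter.data / (2 * k - inter.data)
    keep = (jac >= prune) & (inter.row != inter.col)
    adj = sp.csr_matrix(
        (jac[keep], (inter.row[keep], inter.col[keep])), shape=(n, n)
    )
    return adj


# ---------------------------------------------------------------------------
# Modularity clustering (Louvain-style local moving + aggregation)


def modularity(
    adj: sp.spmatrix, labels: np.ndarray, resolution: float = 1.0
) -> float:
    """Resolution-scaled Newman–Girvan modularity of a hard partition."""
    A = sp.csr_matrix(adj)
    labels = np.asarray(labels)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = np.asarray(A.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        q += A[np.ix_(idx, idx)].sum() / two_m
        q -= resolution * (k[idx].sum() / two_m) ** 2
    return float(q)


def _local_move(neigh, wts, k_str, self_w, labels, sigma_tot, two_m, res, rng):
    """One pass of Louvain local moving; returns True if anything moved."""
    n = len(labels)
    moved = False
    for i in rng.permutation(n):
        ci = labels[i]
        nbr, w = neigh[i], wts[i]
        # remove i from its community
        sigma_tot[ci] -= k_str[i]
        cand: dict[int, float] = {ci: 0.0}
        for j, wij in zip(nbr, w):
            cand[labels[j]] = cand.get(labels[j], 0.0) + wij
        best_c, best_gain = ci, cand[ci] - res * k_str[i] * sigma_tot[ci] / two_m
        for c, kic in cand.items():
            gain = kic - res * k_str[i] * sigma_tot[c] / two_m
            if gain > best_gain + 1e-12:
                best_c, best_gain = c, gain
        sigma_tot[best_c] += k_str[i]
        if best_c != ci:
            labels[i] = best_c
            moved = True
    return moved


def _one_louvain_run(adj: sp.csr_matrix, resolution: float, rng) -> np.ndarray:
    n0 = adj.shape[0]
    node_map = np.arange(n0)  # original node -> current supernode
    A = adj.tocsr().astype(float)
    self_w = np.zeros(n0)
    while True:
        n = A.shape[0]
        indptr, indices, data = A.indptr, A.indices, A.data
        neigh = [indices[indptr[i] : indptr[i + 1]] for i in range(n)]
        wts = [data[indptr[i] : indptr[i + 1]] for i in range(n)]
        k_str = np.asarray(A.sum(axis=1)).ravel() + self_w
        two_m = A.sum() + self_w.sum()
        if two_m == 0:
            break
        labels = np.arange(n)
        sigma_tot = k_str.copy()
        improved = False
        while _local_move(
            neigh, wts, k_str, self_w, labels, sigma_tot, two_m, resolution, rng
        ):
            improved = True
        if not improved:
            break
        # aggregate: communities become supernodes
        uniq, comp = np.unique(labels, return_inverse=True)
        node_map = comp[node_map]
        nc = len(uniq)
        M = sp.csr_matrix(
            (np.ones(n), (np.arange(n), comp)), shape=(n, nc)
        )
        Anew = (M.T @ A @ M).tocsr()
        self_w = np.asarray(Anew.diagonal()).ravel() + np.asarray(
            M.T @ self_w[:, None]
        ).ravel()
        Anew.setdiag(0)
        Anew.eliminate_zeros()
        A = Anew
        if nc == n:
            break
    return node_map


def cluster_modularity(
    adj: sp.spmatrix,
    resolution: float = 1.2,
    n_iterations: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cluster a weighted graph by modularity maximization.

    Louvain-style local moving plus graph aggregation, restarted
    ``n_iterations`` times with seeded random node orders; the partition
    with the highest resolution-scaled modularity wins. Labels are
    relabeled 0..K-1 by decreasing cluster size. Deterministic given the
    seed. A graph with no edges returns singleton clusters with a warning.
    """
    A = sp.csr_matrix(adj)
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if A.nnz == 0:
        warnings.warn("graph has no edges; every node is its own cluster")
        return np.arange(n)
    A = ((A + A.T) / 2).tocsr()
    A.setdiag(0)
    A.eliminate_zeros()
    rng = np.random.default_rng(seed)
    best_q, best_labels = -np.inf, None
    for _ in range(n_iterations):
        labels = _one_louvain_run(A, resolution, np.random.default_rng(rng.integers(2**31)))
        q = modularity(A, labels, resolution)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    # relabel by decreasing size, stable on ties
    uniq, counts = np.unique(best_labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = {int(uniq[o]): r for r, o in enumerate(order)}
    return np.array([remap[int(c)] for c in best_labels])


# ---------------------------------------------------------------------------
# Cluster dendrogram


@dataclass
class ClusterTree:
    """Average-linkage dendrogram over cluster-mean PC vectors."""

    linkage_matrix: np.ndarray
    cluster_ids: np.ndarray  # leaf order used in the linkage

    def internal_nodes(self) -> list[tuple[frozenset, frozenset]]:
        """(left child leaf set, right child leaf set) per internal node,
        ordered by increasing merge height."""
        tree = to_tree(self.linkage_matrix)
        nodes = []

        def leaves(node):
            return frozenset(
                self.cluster_ids[i] for i in node.pre_order(lambda x: x.id)
            )

        def walk(node):
            if node.is_leaf():
                return
            walk(node.left)
            walk(node.right)
            nodes.append((node.dist, leaves(node.left), leaves(node.right)))

        walk(tree)
        nodes.sort(key=lambda t: t[0])
        return [(l, r) for _, l, r in nodes]

    def to_newick(self) -> str:
        def rec(node):
            if node.is_leaf():
                return str(self.cluster_ids[node.id])
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(to_tree(self.linkage_matrix)) + ";"


def cluster_tree(labels: np.ndarray, scores: EmbeddingSet | np.ndarray) -> ClusterTree:
    """Average-linkage hierarchy of Euclidean distances between
    cluster-mean PC vectors."""
    P = scores.scores if isinstance(scores, EmbeddingSet) else np.asarray(scores)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("cluster_tree requires at least 2 clusters")
    means = np.vstack([P[labels == c].mean(axis=0) for c in ids])
    Z = linkage(means, method="average", metric="euclidean")
    return ClusterTree(linkage_matrix=Z, cluster_ids=ids)


# ---------------------------------------------------------------------------
# Module score (ADG score)


def module_score(
    norm: NormalizedMatrix,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell module score: mean expression of the gene set minus the
    mean of bin-matched control genes.

    All genes are binned into ``n_bins`` equal-frequency bins by their mean
    expression; for each set gene, ``n_ctrl`` control genes are sampled
    from its bin (without replacement when the bin is large enough).
    Genes absent from the matrix are dropped with a warning.
    """
    present = [g for g in gene_set if g in set(norm.genes)]
    missing = [g for g in gene_set if g not in set(norm.genes)]
    if missing:
        warnings.warn(f"module_score: dropping genes not in matrix: {missing}")
    if not present:
        raise ValueError("module_score: no genes of the set are in the matrix")
    rng = np.random.default_rng(seed)
    X = norm.X
    gene_means = np.asarray(X.mean(axis=1)).ravel()
    ranks = pd.Series(gene_means).rank(method="first").to_numpy()
    bins = np.ceil(ranks / len(ranks) * n_bins).astype(int) - 1
    set_idx = norm.gene_index(present)
    ctrl_idx: list[int] = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        if len(pool) <= n_ctrl:
            take = pool  # small bin: use every gene in it
        else:
            take = rng.choice(pool, size=n_ctrl, replace=False)
        ctrl_idx.extend(take.tolist())
    set_mean = np.asarray(X[set_idx].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(X[np.array(ctrl_idx)].mean(axis=0)).ravel()
    return set_mean - ctrl_mean


# ---------------------------------------------------------------------------
# ADG-PC detection and removal


def find_adg_pc(
    embedding: EmbeddingSet,
    adg_genes=ADG_GENES,
    top_n: int = 50,
    cutoff: float = 0.05,
) -> tuple[int | None, float]:
    """Find the PC whose top-|loading| genes are enriched for ADGs.

    Per component, the hypergeometric upper-tail probability of the ADG
    overlap with the ``top_n`` genes ranked by |loading|. Returns the
    argmin-p component and its p, or ``(None, best_p)`` when no component
    beats the cutoff.
    """
    genes = np.asarray(embedding.genes, dtype=object)
    adg = [g for g in adg_genes if g in set(genes)]
    if not adg:
        raise ValueError("none of the ADG genes are in the gene universe")
    N, K = len(genes), len(adg)
    adg_mask = np.isin(genes, adg)
    best_pc, best_p = None, 1.0
    for j in range(embedding.n_pcs):
        top = np.argsort(-np.abs(embedding.loadings[:, j]), kind="stable")[:top_n]
        k = int(adg_mask[top].sum())
        p = float(hypergeom.sf(k - 1, N, K, top_n))
        if p < best_p:
            best_pc, best_p = j, p
    if best_p >= cutoff:
        return None, best_p
    return best_pc, best_p


def drop_pc_recluster(
    embedding: EmbeddingSet,
    pc_index: int,
    config: ClusterConfig | None = None,
    old_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, dict | None]:
    """Zero one component of the cell scores and recluster.

    This is the "regress out the ADG principal component" step: the
    offending component's coordinate is removed from every cell before the
    SNN graph is rebuilt. When ``old_labels`` is given, the returned
    mapping sends each old cluster to the new cluster holding the
    plurality of its cells.
    """
    config = config or ClusterConfig()
    if not 0 <= pc_index < embedding.n_pcs:
        raise ValueError(f"pc_index {pc_index} out of range")
    P = embedding.scores.copy()
    P[:, pc_index] = 0.0
    adj = snn_graph(P, k=config.k_neighbors, prune=config.snn_prune)
    new_labels = cluster_modularity(
        adj, config.resolution, config.n_iterations, config.seed
    )
    mapping = None
    if old_labels is not None:
        mapping = {}
        for c in np.unique(old_labels):
            sub = new_labels[np.asarray(old_labels) == c]
            vals, cnt = np.unique(sub, return_counts=True)
            mapping[int(c)] = int(vals[cnt.argmax()])
    return new_labels, mapping


# ---------------------------------------------------------------------------
# Doublet-cluster flagging


def flag_doublet_clusters(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    marker_panels: dict,
    co_expr_threshold: float = 0.1,
    seed: int = 0,
) -> dict:
    """Flag clusters that co-express two or more exclusive class panels.

    A cluster is a putative doublet cluster when its mean module score
    exceeds the threshold for at least two panels (e.g. neuronal and
    glial marker sets).
    """
    if len(marker_panels) < 2:
        raise ValueError("flag_doublet_clusters requires >= 2 marker panels")
    labels = np.asarray(labels)
    scores = {
        name: module_score(norm, panel, seed=seed)
        for name, panel in marker_panels.items()
    }
    flags = {}
    for c in np.unique(labels):
        mask = labels == c
        n_high = sum(
            1 for s in scores.values() if s[mask].mean() > co_expr_threshold
        )
        flags[c] = n_high >= 2
    return flags


# ---------------------------------------------------------------------------
# Merging poorly separated clusters


def merge_clusters(
    labels: np.ndarray,
    scores: EmbeddingSet | np.ndarray,
    norm: NormalizedMatrix,
    artifact_genes=ADG_GENES,
    de_config=None,
    min_markers: int = 5,
    max_artifact_frac: float = 0.5,
    alpha: float = 0.05,
) -> np.ndarray:
    """Iteratively merge dendrogram nodes with weak or artifactual markers.

    Each round rebuilds the cluster tree, walks its internal nodes from
    the tightest merge upward, and tests the node's two children against
    each other. The children merge when the node has fewer than
    ``min_markers`` Bonferroni-significant markers, or when at least
    ``max_artifact_frac`` of its significant markers lie in the artifact
    list (housekeeping / activity-dependent genes). Terminates at a fixed
    point; the cluster count strictly decreases on every merge.
    """
    from .de import DEConfig, find_markers

    de_config = de_config or DEConfig()
    labels = np.asarray(labels).copy()
    artifact = set(artifact_genes)
    while len(np.unique(labels)) > 1:
        tree = cluster_tree(labels, scores)
        merged = False
        P = scores.scores if isinstance(scores, EmbeddingSet) else np.asarray(scores)
        for left, right in tree.internal_nodes():
            n_left = int(np.isin(labels, list(left)).sum())
            n_right = int(np.isin(labels, list(right)).sum())
            if min(n_left, n_right) < 3:
                # too few cells for marker evidence: absorb each cluster on
                # the small side into its nearest cluster on the other side
                small, big = (
                    (left, right) if n_left < n_right else (right, left)
                )
                big_means = {c: P[labels == c].mean(axis=0) for c in big}
                for c in small:
                    cm = P[labels == c].mean(axis=0)
                    target = min(
                        big_means, key=lambda b: np.linalg.norm(big_means[b] - cm)
                    )
                    labels[labels == c] = target
                merged = True
                break
            else:
                table = find_markers(norm, labels, (left, right), de_config)
                sig = table[table["p_val_adj"] < alpha]
                n_sig = len(sig)
                art_frac = (
                    float(np.mean([g in artifact for g in sig["gene"]]))
                    if n_sig
                    else 1.0
                )
            if n_sig < min_markers or art_frac >= max_artifact_frac:
                members = list(left | right)
                labels[np.isin(labels, members)] = min(members)
                merged = True
                break
        if not merged:
            break
    # compact label ids, preserving size order convention
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = {int(uniq[o]): r for r, o in enumerate(order)}
    return np.array([remap[int(c)] for c in labels])
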