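"""Graph construction, diffusion maps, Leiden clustering, and pseudotime.

The trajectory scaffold follows the standard single-cell recipe: a knn graph
in scaled expression space, a diffusion-map embedding of that graph, a second
knn graph in diffusion coordinates, Leiden over-clustering of the second
graph, a coarse cluster-connectivity (PAGA-style) graph, and a root-anchored
pseudotime measured as diffusion distance from a randomly selected root cell
of the root population (HSC).  A subset-and-reanalyze operation re-runs the
whole scaffold on a restricted cell and channel set, which is how the
erythroid and myeloid arms are examined on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

DEFAULT_K = 15
DEFAULT_M = 15
DEFAULT_RESOLUTION = 2.0
DEFAULT_EDGE_THRESHOLD = 0.1


class GraphError(ValueError):
    pass


# ---------------------------------------------------------------------------
# knn graph
# ---------------------------------------------------------------------------

@dataclass
class NeighborGraph:
    """Sparse symmetric weighted knn adjacency (no self-loops)."""

    adjacency: sp.csr_matrix
    k: int
    metric: str = "euclidean"
    space: str = "expression-space"

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def components(self) -> tuple[int, np.ndarray]:
        return connected_components(self.adjacency, directed=False)

    def edge_list(self) -> pd.DataFrame:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return pd.DataFrame({"source": coo.row, "target": coo.col,
                             "weight": coo.data})


def build_knn_graph(X: np.ndarray, k: int = DEFAULT_K,
                    metric: str = "euclidean",
                    space: str = "expression-space") -> NeighborGraph:
    """Union-symmetrized knn graph with adaptive Gaussian-kernel weights.

    The kernel bandwidth is per-node: ``w_ij = exp(-d_ij^2 / (s_i * s_j))``
    where ``s_i`` is node i's distance to its k-th neighbor.  Duplicate
    points (zero distance) get the maximal kernel weight 1; self-loops are
    never created.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k < 1:
        raise GraphError("k must be >= 1")
    if k >= n:
        raise GraphError(f"k = {k} requires more than k+1 = {k + 1} points, got {n}")
    if float(np.ptp(X)) == 0.0:
        raise GraphError("input has zero variance; no neighborhood structure")

    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop the self column; with exact duplicates self may not be first, so
    # remove one zero-distance occurrence of each node's own index instead
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=np.int64)
    dvals = np.empty(n * k, dtype=np.float64)
    for i in range(n):
        nbrs, dd = idx[i], dist[i]
        self_pos = np.flatnonzero(nbrs == i)
        drop = self_pos[0] if self_pos.size else 0
        keep = np.ones(k + 1, dtype=bool)
        keep[drop] = False
        cols[i * k:(i + 1) * k] = nbrs[keep]
        dvals[i * k:(i + 1) * k] = dd[keep]

    bandwidth = np.maximum(dist[:, -1], 1e-12)
    sigma = bandwidth[rows] * bandwidth[cols]
    weights = np.exp(-(dvals**2) / sigma)
    W = sp.csr_matrix((weights, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)  # union symmetrization
    W.setdiag(0.0)
    W.eliminate_zeros()
    return NeighborGraph(W, k=k, metric=metric, space=space)


# ---------------------------------------------------------------------------
# Diffusion maps
# ---------------------------------------------------------------------------

@dataclass
class DiffusionEmbedding:
    """Nontrivial eigenpairs of the knn transition operator.

    ``coordinates[:, i]`` is the i-th nontrivial eigenvector (of the
    row-stochastic transition matrix, computed through its symmetric
    conjugate) scaled by its eigenvalue.  Disconnected graphs are embedded
    per connected component; ``component`` records each node's component and
    ``eigenvalues`` those of the largest component.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    component: np.ndarray
    degenerate: bool = False

    @property
    def m(self) -> int:
        return self.coordinates.shape[1]


def transition_matrix(graph: NeighborGraph) -> sp.csr_matrix:
    """Row-stochastic random-walk matrix D^-1 W."""
    W = graph.adjacency
    deg = np.asarray(W.sum(axis=1)).ravel()
    if (deg == 0).any():
        raise GraphError("graph has isolated nodes with zero degree")
    Dinv = sp.diags(1.0 / deg)
    return Dinv @ W


def _component_diffusion(W: sp.csr_matrix, m: int) -> tuple[np.ndarray, np.ndarray]:
    n = W.shape[0]
    deg = np.asarray(W.sum(axis=1)).ravel()
    dhalf = np.sqrt(deg)
    S = sp.diags(1.0 / dhalf) @ W @ sp.diags(1.0 / dhalf)
    k_eig = min(m + 1, n - 1)
    if k_eig < 1:
        return np.zeros((n, 0)), np.zeros(0)
    if n <= max(2 * (m + 1), 50):
        dense = S.toarray()
        evals, evecs = np.linalg.eigh((dense + dense.T) / 2.0)
    else:
        # fixed start vector: keeps the decomposition bitwise reproducible
        v0 = np.full(n, 1.0 / np.sqrt(n))
        evals, evecs = sp.linalg.eigsh(S, k=k_eig, which="LA", v0=v0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial stationary eigenpair (eigenvalue 1)
    evals, evecs = evals[1:m + 1], evecs[:, 1:m + 1]
    phi = evecs / dhalf[:, None]
    norms = np.linalg.norm(phi, axis=0, keepdims=True)
    phi /= np.where(norms == 0, 1.0, norms)
    # sign convention: the entry of largest magnitude is positive
    for j in range(phi.shape[1]):
        pivot = int(np.argmax(np.abs(phi[:, j])))
        if phi[pivot, j] < 0:
            phi[:, j] = -phi[:, j]
    coords = phi * evals[None, :]
    return coords, evals


def diffusion_map(graph: NeighborGraph, m: int = DEFAULT_M) -> DiffusionEmbedding:
    """Spectral embedding of the symmetric-normalized transition operator.

    Returns the top ``m`` nontrivial eigenpairs; on disconnected graphs each
    component is embedded separately (never silent NaN).  Near-tied leading
    eigenvalues are flagged ``degenerate``.
    """
    n = graph.n_nodes
    if m >= n:
        raise GraphError(f"m = {m} components require more than m nodes, got {n}")
    n_comp, labels = graph.components()
    coords = np.zeros((n, m))
    eigenvalues = np.zeros(0)
    largest = np.argmax(np.bincount(labels))
    if n_comp > 1:
        log.info("diffusion_map: %d connected components; embedding separately",
                 n_comp)
    for c in range(n_comp):
        nodes = np.flatnonzero(labels == c)
        if nodes.size < 2:
            continue
        sub = graph.adjacency[np.ix_(nodes, nodes)].tocsr()
        sub_coords, sub_evals = _component_diffusion(sub, m)
        coords[np.ix_(nodes, np.arange(sub_coords.shape[1]))] = sub_coords
        if c == largest:
            eigenvalues = sub_evals
    degenerate = bool(eigenvalues.size >= 2
                      and np.min(np.abs(np.diff(eigenvalues))) < 1e-10)
    if degenerate:
        log.warning("diffusion_map: tied eigenvalues; coordinates are degenerate")
    return DiffusionEmbedding(coords, eigenvalues, labels, degenerate)


# ---------------------------------------------------------------------------
# Leiden partition
# ---------------------------------------------------------------------------

@dataclass
class ClusterPartition:
    labels: np.ndarray
    resolution: float
    quality: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def leiden_partition(graph: NeighborGraph, resolution: float = DEFAULT_RESOLUTION,
                     seed: int = 0) -> ClusterPartition:
    """Leiden communities of the weighted knn graph (RB-configuration quality).

    The default resolution deliberately over-clusters — many more clusters
    than biological populations — so that downstream metacluster merging
    never fuses distinct small populations.
    """
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    g = ig.Graph(n=graph.n_nodes,
                 edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(), resolution_parameter=resolution,
        seed=int(seed), n_iterations=2)
    labels = np.asarray(part.membership, dtype=np.int64)
    # relabel to contiguous ids ordered by first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterPartition(labels, resolution, float(part.quality()), int(seed))


# ---------------------------------------------------------------------------
# Cluster-connectivity (coarse) graph
# ---------------------------------------------------------------------------

@dataclass
class ClusterGraph:
    """Cluster-level connectivity scores vs a configuration-model expectation."""

    scores: np.ndarray          # n_clusters x n_clusters, symmetric, zero diag
    sizes: np.ndarray
    threshold: float

    @property
    def n_clusters(self) -> int:
        return self.scores.shape[0]

    def retained_edges(self) -> list[tuple[int, int, float]]:
        out = []
        for i in range(self.n_clusters):
            for j in range(i + 1, self.n_clusters):
                if self.scores[i, j] >= self.threshold:
                    out.append((i, j, float(self.scores[i, j])))
        return out

    def component_of(self, cluster_subset: np.ndarray, seeds: np.ndarray) -> np.ndarray:
        """Clusters of ``cluster_subset`` connected (via retained edges within
        the subset) to any cluster in ``seeds``."""
        subset = list(cluster_subset)
        pos = {c: i for i, c in enumerate(subset)}
        g = ig.Graph(n=len(subset))
        edges = [(pos[i], pos[j]) for i, j, _ in self.retained_edges()
                 if i in pos and j in pos]
        g.add_edges(edges)
        comps = np.asarray(g.connected_components().membership)
        keep_comps = {comps[pos[s]] for s in seeds if s in pos}
        return np.array([c for c in subset if comps[pos[c]] in keep_comps])


def cluster_connectivity(graph: NeighborGraph, partition: ClusterPartition,
                         threshold: float = DEFAULT_EDGE_THRESHOLD) -> ClusterGraph:
    """Observed inter-cluster edge counts over their degree-sum expectation.

    Under random edge placement proportional to cluster degree sums, the
    expected number of edges between clusters i and j is d_i d_j / (2m).
    The score is observed / expected; pairs with no inter-cluster edges
    score 0.  Edges below ``threshold`` are dropped for downstream use, but
    all scores are retained.
    """
    labels = partition.labels
    if labels.shape[0] != graph.n_nodes:
        raise GraphError("partition does not cover the graph's nodes")
    k = partition.n_clusters
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    ci, cj = labels[coo.row], labels[coo.col]
    m_edges = coo.data.size
    obs = np.zeros((k, k))
    np.add.at(obs, (ci, cj), 1.0)
    obs = obs + obs.T
    deg = np.zeros(k)
    np.add.at(deg, ci, 1.0)
    np.add.at(deg, cj, 1.0)
    expect = np.outer(deg, deg) / max(2.0 * m_edges, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(expect > 0, obs / expect, 0.0)
    np.fill_diagonal(scores, 0.0)
    scores[obs == 0] = 0.0
    return ClusterGraph(scores, partition.sizes(), threshold)


DEFAULT_POPULATION_EDGE_THRESHOLD = 0.002


def merge_partition(partition: ClusterPartition,
                    cluster_labels: dict[int, str]
                    ) -> tuple[ClusterPartition, list[str]]:
    """Collapse a fine partition into one cluster per annotation label."""
    names = sorted({cluster_labels[c] for c in range(partition.n_clusters)})
    lut = {n: i for i, n in enumerate(names)}
    labels = np.array([lut[cluster_labels[c]] for c in partition.labels])
    return ClusterPartition(labels, partition.resolution, 0.0, partition.seed), names


def population_connectivity(graph: NeighborGraph, partition: ClusterPartition,
                            cluster_labels: dict[int, str],
                            threshold: float = DEFAULT_POPULATION_EDGE_THRESHOLD,
                            ) -> dict[frozenset[str], float]:
    """Connectivity scores of the population-projected cluster graph.

    Fine clusters sharing an annotation label are merged and the
    observed/expected connectivity score recomputed on the merged partition;
    this aggregate is far more stable than the maximum over fine cluster
    pairs.  Only scores at or above ``threshold`` are returned.  Merged
    partitions pool many cells per node, so expected edge counts are large
    and scores land on a much smaller scale than fine-grained ones — hence
    the separate threshold default.
    """
    merged, names = merge_partition(partition, cluster_labels)
    cg = cluster_connectivity(graph, merged, threshold=threshold)
    edges: dict[frozenset[str], float] = {}
    for i, j, score in cg.retained_edges():
        edges[frozenset((names[i], names[j]))] = score
    return edges


def population_edges(graph: NeighborGraph, partition: ClusterPartition,
                     cluster_labels: dict[int, str],
                     threshold: float = DEFAULT_POPULATION_EDGE_THRESHOLD,
                     ) -> set[frozenset[str]]:
    """Population-level edges retained in the projected cluster graph."""
    return set(population_connectivity(graph, partition, cluster_labels,
                                       threshold))


# ---------------------------------------------------------------------------
# Pseudotime
# ---------------------------------------------------------------------------

@dataclass
class PseudotimeResult:
    values: np.ndarray            # NaN where unreachable
    root: int
    seed: int
    unreachable: np.ndarray       # boolean mask

    def finite(self) -> np.ndarray:
        return ~self.unreachable


def compute_pseudotime(embedding: DiffusionEmbedding, graph: NeighborGraph,
                       root_population: str, labels: np.ndarray | pd.Series,
                       seed: int = 0, method: str = "diffusion") -> PseudotimeResult:
    """Pseudotime from a randomly selected root cell of ``root_population``.

    ``method="diffusion"`` (default) measures the Euclidean distance from the
    root in diffusion coordinates rescaled per component by lambda/(1-lambda)
    — the diffusion-pseudotime metric.  ``method="geodesic"`` uses shortest
    paths on the knn graph with distance-like weights.  Cells in connected
    components not containing the root are flagged unreachable (NaN), never
    silently assigned.
    """
    labels = np.asarray(labels)
    candidates = np.flatnonzero(labels == root_population)
    if candidates.size == 0:
        raise GraphError(f"no cells labeled {root_population!r} to root at")
    rng = np.random.default_rng(seed)
    root = int(rng.choice(candidates))

    unreachable = embedding.component != embedding.component[root]
    values = np.full(embedding.coordinates.shape[0], np.nan)
    if method == "diffusion":
        lam = embedding.eigenvalues
        coords = embedding.coordinates[:, :lam.size]
        # stored coords are lambda * phi; rescale to (lambda / (1-lambda)) * phi
        factor = 1.0 / np.maximum(1.0 - lam, 1e-8)
        rescaled = coords * factor[None, :]
        delta = rescaled - rescaled[root][None, :]
        values[~unreachable] = np.linalg.norm(delta[~unreachable], axis=1)
    elif method == "geodesic":
        W = graph.adjacency.tocoo()
        # convert affinity weights back to distance-like lengths
        lengths = sp.csr_matrix(
            (-np.log(np.clip(W.data, 1e-12, 1.0)) + 1e-6, (W.row, W.col)),
            shape=W.shape)
        from scipy.sparse.csgraph import dijkstra
        d = dijkstra(lengths, directed=False, indices=root)
        values = d
        unreachable = ~np.isfinite(d)
        values[unreachable] = np.nan
    else:
        raise GraphError(f"unknown pseudotime method {method!r}")
    values[root] = 0.0
    return PseudotimeResult(values, root, int(seed), unreachable)


# ---------------------------------------------------------------------------
# End-to-end scaffold and subset re-analysis
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryResult:
    """All artifacts of one run of the graph -> pseudotime scaffold."""

    knn_expression: NeighborGraph
    embedding: DiffusionEmbedding
    knn_diffusion: NeighborGraph
    partition: ClusterPartition
    cluster_graph: ClusterGraph
    pseudotime: PseudotimeResult
    cell_index: np.ndarray      # positions into the matrix the run was given


def run_trajectory(X: np.ndarray, root_labels: np.ndarray,
                   root_population: str = "HSC",
                   k: int = DEFAULT_K, m: int = DEFAULT_M,
                   resolution: float = DEFAULT_RESOLUTION,
                   edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
                   seed: int = 0,
                   pseudotime_method: str = "diffusion") -> TrajectoryResult:
    """knn -> diffusion map -> second knn -> Leiden -> cluster graph -> pseudotime."""
    g1 = build_knn_graph(X, k=k, space="expression-space")
    emb = diffusion_map(g1, m=m)
    g2 = build_knn_graph(emb.coordinates, k=k, space="diffusion-space")
    part = leiden_partition(g2, resolution=resolution, seed=seed)
    cg = cluster_connectivity(g2, part, threshold=edge_threshold)
    pt = compute_pseudotime(emb, g2, root_population, root_labels, seed=seed,
                            method=pseudotime_method)
    return TrajectoryResult(g1, emb, g2, part, cg, pt,
                            np.arange(X.shape[0]))


def subset_and_reanalyze(X: np.ndarray, channels: list[str],
                         partition: ClusterPartition,
                         cluster_graph: ClusterGraph,
                         metacluster_labels: dict[int, str],
                         allowed_labels: set[str] | list[str],
                         channel_subset: list[str],
                         root_labels: np.ndarray,
                         root_population: str = "HSC",
                         **trajectory_kwargs) -> TrajectoryResult:
    """Restrict to connected, allowed clusters and re-run the scaffold.

    Kept cells belong to clusters that are (a) annotated with an allowed
    label and (b) in the thresholded cluster-graph connected component that
    contains the root-labeled clusters.  The scaffold is re-run on the
    restricted channel subset; ``cell_index`` maps back into ``X``.
    """
    allowed = set(allowed_labels)
    if not allowed:
        raise GraphError("allowed_labels must be non-empty")
    unknown = [c for c in channel_subset if c not in channels]
    if unknown:
        raise GraphError(f"channel subset not in panel: {unknown}")
    candidate = np.array([c for c in range(cluster_graph.n_clusters)
                          if metacluster_labels.get(c) in allowed])
    roots = np.array([c for c in candidate
                      if metacluster_labels.get(c) == root_population])
    if candidate.size == 0 or roots.size == 0:
        raise GraphError("no clusters satisfy the label and connectivity criteria")
    keep_clusters = set(cluster_graph.component_of(candidate, roots).tolist())
    cells = np.flatnonzero(np.isin(partition.labels, list(keep_clusters)))
    if cells.size == 0:
        raise GraphError("no cells left after cluster restriction")
    col_idx = [channels.index(c) for c in channel_subset]
    sub = run_trajectory(X[np.ix_(cells, col_idx)],
                         np.asarray(root_labels)[cells],
                         root_population=root_population, **trajectory_kwargs)
    sub.cell_index = cells
    return sub
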