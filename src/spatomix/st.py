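"""Spatial-transcriptomics spot clustering.

Counts are depth-normalized and log2-transformed, embedded by PCA, linked
into a shared-nearest-neighbor (SNN) graph with Jaccard edge weights, and
partitioned by seeded Louvain modularity optimization.  The defaults
(n_pcs = 20, k_neighbors = 15, pruning below 1/15, resolution calibrated
once on the packaged phantom) are the package's declared equivalent of the
vendor's proprietary graph-based clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .grid import SpotFeatureTable
from .msi import pca_scores

__all__ = [
    "SpotGraph",
    "ClusterAssignment",
    "DEFAULT_RESOLUTION",
    "SNN_PRUNE_THRESHOLD",
    "normalize_counts",
    "build_snn_graph",
    "cluster_graph",
]

SNN_PRUNE_THRESHOLD = 1.0 / 15.0
# Calibrated on the packaged default phantom (scripts/calibrate_resolution.py)
# so Louvain recovers the planted region count.
DEFAULT_RESOLUTION = 1.0
DEFAULT_N_PCS = 20
DEFAULT_K_NEIGHBORS = 15


@dataclass
class SpotGraph:
    """Weighted undirected SNN graph over spot labels."""

    graph: nx.Graph
    k_neighbors: int
    n_pcs: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ClusterAssignment:
    """Spot label -> dense cluster id, with the partition's modularity."""

    labels: pd.Series
    n_clusters: int
    modularity: float

    def __post_init__(self) -> None:
        ids = set(self.labels.unique())
        if ids and ids != set(range(self.n_clusters)):
            raise ValueError("cluster ids must be dense in [0, n_clusters)")


def normalize_counts(
    table: SpotFeatureTable, target_sum: float = 1e4
) -> SpotFeatureTable:
    """Depth-normalize each spot to ``target_sum`` then log2(x + 1).

    Zero-depth spots cannot be scaled; they are flagged missing (excluded
    from graph construction) and left at zero.
    """
    counts = table.values.to_numpy(float)
    depth = counts.sum(axis=1)
    zero = depth == 0
    scale = np.where(zero, 0.0, target_sum / np.where(zero, 1.0, depth))
    norm = np.log2(counts * scale[:, None] + 1.0)
    missing = pd.Series(zero, index=table.values.index)
    if table.missing is not None:
        missing = missing | table.missing
    return SpotFeatureTable(
        pd.DataFrame(norm, index=table.values.index, columns=table.values.columns),
        table.modalities,
        region=table.region,
        true_region=table.true_region,
        missing=missing,
        meta={**table.meta, "normalized": True, "target_sum": target_sum},
    )


def build_snn_graph(
    normalized: SpotFeatureTable,
    n_pcs: int = DEFAULT_N_PCS,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    prune: float = SNN_PRUNE_THRESHOLD,
) -> SpotGraph:
    """Shared-nearest-neighbor graph from PCA-embedded expression profiles.

    Each spot's neighborhood is itself plus its ``k_neighbors`` Euclidean
    nearest neighbors in PC space; the edge weight between two spots is the
    Jaccard overlap of their neighborhoods; edges below ``prune`` are
    dropped.  Flagged-missing spots are excluded.
    """
    keep = (
        ~normalized.missing
        if normalized.missing is not None
        else pd.Series(True, index=normalized.values.index)
    )
    frame = normalized.values[keep.to_numpy()]
    labels = frame.index.to_list()
    n_spots = len(frame)
    if k_neighbors >= n_spots:
        raise ValueError("k_neighbors must be < number of usable spots")
    n_pcs_eff = min(n_pcs, min(frame.shape))
    scores, _, _ = pca_scores(frame.to_numpy(float), n_pcs_eff)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)  # includes self at distance 0
    size = k_neighbors + 1
    rows = np.repeat(np.arange(n_spots), size)
    adj = sparse.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n_spots, n_spots)
    )
    shared = (adj @ adj.T).tocoo()  # |neighborhood_i & neighborhood_j|
    g = nx.Graph()
    g.add_nodes_from(labels)
    upper = shared.row < shared.col
    for i, j, s in zip(shared.row[upper], shared.col[upper], shared.data[upper]):
        w = s / (2 * size - s)  # Jaccard: both neighborhoods have size k+1
        if w >= prune:
            g.add_edge(labels[i], labels[j], weight=float(w))
    return SpotGraph(g, k_neighbors, n_pcs_eff)


def cluster_graph(
    graph: SpotGraph | nx.Graph,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
) -> ClusterAssignment:
    """Seeded Louvain modularity clustering of the SNN graph.

    Communities come from greedy modularity optimization (node moving +
    aggregation) at the given resolution; disconnected components are
    handled naturally.  Cluster ids are re-labelled densely by decreasing
    size (ties by smallest member label) so output is deterministic for a
    fixed seed.
    """
    g = graph.graph if isinstance(graph, SpotGraph) else graph
    if g.number_of_nodes() == 0:
        return ClusterAssignment(pd.Series(dtype=int), 0, 0.0)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(
        (sorted(c, key=str) for c in communities),
        key=lambda c: (-len(c), str(c[0])),
    )
    mapping = {node: cid for cid, comm in enumerate(communities) for node in comm}
    labels = pd.Series({n: mapping[n] for n in g.nodes}, name="cluster")
    labels = labels.loc[list(g.nodes)]
    mod = (
        nx.community.modularity(g, communities, weight="weight", resolution=resolution)
        if g.number_of_edges()
        else 0.0
    )
    # summation order inside modularity follows dict hash order, which is
    # process-dependent in the last ulp; round below meaning, above noise
    return ClusterAssignment(labels, len(communities), round(float(mod), 12))
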