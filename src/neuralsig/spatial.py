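"""Spot adjacency graphs, n-hop subgraphs and node feature matrices.

A spatial sample's spots become nodes of an undirected graph. The pairwise
Euclidean distance matrix is computed, self-distances (the zero diagonal)
are replaced by a constant 1,000 so no spot counts as its own neighbor,
and an edge joins two spots whose distance is at most one unit greater
than the smallest nonzero distance. On a hexagonal Visium lattice this
links each interior spot to exactly its six direct neighbors.

A query spot's n-hop neighborhood (all spots within n edges, breadth-first)
forms a subgraph; subgraphs smaller than a minimum node count are dropped.
Node features are standardized log1p expression of the most variable
genes, with genes unexpressed across a subgraph masked to zero there.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.spatial

__all__ = [
    "SpatialGraph",
    "Subgraph",
    "build_graph",
    "extract_subgraphs",
    "node_features",
    "variable_gene_stats",
    "ZERO_DISTANCE_CONSTANT",
]

logger = logging.getLogger(__name__)

#: Constant substituted for zero entries of the distance matrix.
ZERO_DISTANCE_CONSTANT = 1000.0


@dataclasses.dataclass(frozen=True)
class SpatialGraph:
    """Undirected spot graph with the distance threshold that built it."""

    graph: nx.Graph  # nodes: spot ids with coordinate attributes
    distance_threshold: float

    @property
    def node_ids(self) -> list:
        return list(self.graph.nodes)


@dataclasses.dataclass
class Subgraph:
    """A query spot's bounded-hop neighborhood."""

    query_node: str
    node_ids: list  # sorted; all within n_hops of the query
    feature_matrix: np.ndarray | None = None  # node x gene, row order = node_ids
    target_score: float | None = None


def build_graph(coords: pd.DataFrame) -> SpatialGraph:
    """Build the spot adjacency graph from spot coordinates.

    ``coords`` is indexed by unique spot barcodes with columns x, y.
    Duplicate coordinates produce zero off-diagonal distances; these are
    replaced by the same constant as self-distances and a warning issued.
    """
    if len(coords) == 0:
        raise ValueError("need at least one spot")
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("coordinates must be finite")
    if coords.index.has_duplicates:
        raise ValueError("spot barcodes must be unique")
    n = len(coords)
    graph = nx.Graph()
    for node, (x, y) in zip(coords.index, xy):
        graph.add_node(node, x=float(x), y=float(y))
    if n == 1:
        return SpatialGraph(graph=graph, distance_threshold=ZERO_DISTANCE_CONSTANT)

    dist = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(xy))
    off_diag_zero = (dist == 0) & ~np.eye(n, dtype=bool)
    if off_diag_zero.any():
        warnings.warn(
            f"{int(off_diag_zero.sum() // 2)} spot pair(s) share coordinates; "
            "their zero distances are replaced by the self-distance constant",
            stacklevel=2,
        )
    was_zero = dist == 0
    dist[was_zero] = ZERO_DISTANCE_CONSTANT

    smallest = dist[~was_zero].min(initial=np.inf)
    if not np.isfinite(smallest):
        # every pair was zero-replaced: no usable distances
        raise ValueError("no nonzero pairwise distances to derive a threshold")
    if smallest > ZERO_DISTANCE_CONSTANT - 1:
        raise ValueError(
            "smallest nonzero distance exceeds 999; the zero-replacement "
            "constant would wrongly link self-pairs — rescale coordinates"
        )
    threshold = smallest + 1.0
    rows, cols = np.nonzero(np.triu(dist <= threshold, k=1))
    ids = list(coords.index)
    graph.add_edges_from((ids[i], ids[j]) for i, j in zip(rows, cols))
    return SpatialGraph(graph=graph, distance_threshold=float(threshold))


def extract_subgraphs(
    graph: SpatialGraph,
    n_hops: int = 3,
    n_subgraphs: int = 1000,
    min_nodes: int = 15,
    seed: int = 0,
    max_attempts_factor: int = 50,
) -> list[Subgraph]:
    """Sample query spots (uniform, with replacement) and keep their
    n-hop neighborhoods with at least ``min_nodes`` nodes.

    Undersized neighborhoods are dropped and resampled, up to
    ``max_attempts_factor * n_subgraphs`` attempts.
    """
    nodes = sorted(graph.graph.nodes)
    if not nodes:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(seed)
    out: list[Subgraph] = []
    attempts = 0
    max_attempts = max_attempts_factor * max(n_subgraphs, 1)
    while len(out) < n_subgraphs:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {n_subgraphs} subgraphs with >= {min_nodes} "
                f"nodes in {max_attempts} attempts"
            )
        attempts += 1
        query = nodes[int(rng.integers(len(nodes)))]
        reach = nx.single_source_shortest_path_length(
            graph.graph, query, cutoff=n_hops
        )
        if len(reach) < min_nodes:
            continue
        out.append(Subgraph(query_node=query, node_ids=sorted(reach)))
    return out


def variable_gene_stats(
    expression: pd.DataFrame | Sequence[pd.DataFrame], n_top_genes: int = 5000
):
    """Select the most variable genes and their standardization statistics.

    ``expression`` is one spot x gene matrix, or several (pooled over all
    their spots, for multi-sample experiments). Variance is computed on
    log1p values; returns ``(gene_index, means, stds)`` for the
    ``n_top_genes`` genes of highest variance (ties broken by column
    order), with means/stds of the log1p values of the selected genes.
    """
    if isinstance(expression, pd.DataFrame):
        pooled = expression
    else:
        frames = list(expression)
        pooled = pd.concat(frames, axis=0)
    if n_top_genes > pooled.shape[1]:
        raise ValueError(
            f"n_top_genes={n_top_genes} exceeds gene count {pooled.shape[1]}"
        )
    log = np.log1p(pooled.to_numpy(dtype=float))
    var = log.var(axis=0)
    order = np.argsort(-var, kind="stable")[:n_top_genes]
    order = np.sort(order)  # keep original column order among selected genes
    gene_index = pooled.columns[order]
    means = log[:, order].mean(axis=0)
    stds = log[:, order].std(axis=0)
    return gene_index, means, stds


def node_features(
    expression: pd.DataFrame,
    subgraph_nodes: Sequence,
    n_top_genes: int = 5000,
    gene_index: pd.Index | None = None,
    means: np.ndarray | None = None,
    stds: np.ndarray | None = None,
) -> np.ndarray:
    """Node feature matrix for one subgraph.

    Features are per-gene standardized log1p expression of the top
    variable genes; genes with zero raw expression across the subgraph's
    nodes are masked to 0 in that subgraph. Rows follow sorted node id
    order. Standardization statistics default to this sample's spots but
    can be supplied (e.g. pooled over a training collection).
    """
    if gene_index is None:
        gene_index, means, stds = variable_gene_stats(expression, n_top_genes)
    nodes = sorted(subgraph_nodes)
    raw = expression.loc[nodes, gene_index].to_numpy(dtype=float)
    log = np.log1p(raw)
    stds = np.asarray(stds, dtype=float)
    safe = np.where(stds > 0, stds, 1.0)
    feats = (log - np.asarray(means)) / safe
    feats[:, stds == 0] = 0.0
    feats[:, raw.sum(axis=0) == 0] = 0.0  # mask genes unexpressed in subgraph
    return feats
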