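"""Spot graph construction, subgraph extraction and node features."""

import numpy as np
import pandas as pd
import pytest
import scipy.spatial

from neuralsig.spatial import (
    build_graph,
    extract_subgraphs,
    node_features,
    variable_gene_stats,
)
from neuralsig.synthetic import hexagonal_lattice


def brute_force_neighbors(coords: pd.DataFrame, threshold: float) -> dict:
    """Oracle: adjacency from raw pairwise distances, no graph machinery."""
    xy = coords[["x", "y"]].to_numpy()
    out = {}
    for i, node in enumerate(coords.index):
        d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
        out[node] = {
            coords.index[j] for j in np.flatnonzero((d > 0) & (d <= threshold))
        }
    return out


def brute_force_bfs(neighbors: dict, source, max_depth: int) -> set:
    """Oracle: breadth-first reachability on an adjacency dict."""
    frontier, seen = {source}, {source}
    for _ in range(max_depth):
        frontier = {v for u in frontier for v in neighbors[u]} - seen
        seen |= frontier
    return seen


class TestBuildGraph:
    def test_single_spot_has_no_edges(self):
        graph = build_graph(pd.DataFrame({"x": [0.0], "y": [0.0]}, index=["s"]))
        assert graph.graph.number_of_edges() == 0

    def test_two_spots_threshold_is_distance_plus_one(self):
        coords = pd.DataFrame({"x": [0.0, 100.0], "y": [0.0, 0.0]}, index=["a", "b"])
        graph = build_graph(coords)
        assert graph.distance_threshold == pytest.approx(101.0)
        assert graph.graph.has_edge("a", "b")

    def test_hexagonal_interior_degree_is_six(self):
        coords = hexagonal_lattice(10, 10, 100.0)
        graph = build_graph(coords)
        oracle = brute_force_neighbors(coords, graph.distance_threshold)
        interior = "spot_004_004"
        assert len(oracle[interior]) == 6
        assert set(graph.graph.neighbors(interior)) == oracle[interior]
        degrees = [d for _, d in graph.graph.degree()]
        assert max(degrees) == 6

    def test_adjacency_matches_brute_force_everywhere(self):
        coords = hexagonal_lattice(5, 7, 80.0)
        graph = build_graph(coords)
        oracle = brute_force_neighbors(coords, graph.distance_threshold)
        for node in coords.index:
            assert set(graph.graph.neighbors(node)) == oracle[node]

    def test_edge_symmetry_and_no_self_loops(self):
        graph = build_graph(hexagonal_lattice(4, 4, 50.0))
        for u, v in graph.graph.edges:
            assert u != v
            assert graph.graph.has_edge(v, u)

    def test_duplicate_coordinates_warn_and_stay_unlinked(self):
        coords = pd.DataFrame(
            {"x": [0.0, 0.0, 10.0], "y": [0.0, 0.0, 0.0]}, index=["a", "b", "c"]
        )
        with pytest.warns(UserWarning, match="share coordinates"):
            graph = build_graph(coords)
        assert not graph.graph.has_edge("a", "b")

    def test_huge_pitch_triggers_zero_constant_guard(self):
        coords = pd.DataFrame({"x": [0.0, 5000.0], "y": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="999"):
            build_graph(coords)


class TestExtractSubgraphs:
    def test_interior_three_hop_neighborhood_has_37_nodes(self):
        coords = hexagonal_lattice(12, 12, 100.0)
        graph = build_graph(coords)
        oracle_adj = brute_force_neighbors(coords, graph.distance_threshold)
        assert len(brute_force_bfs(oracle_adj, "spot_005_005", 3)) == 37  # 1+6+12+18
        subs = extract_subgraphs(graph, n_hops=3, n_subgraphs=50, seed=0)
        interior_seen = 0
        for sub in subs:
            oracle_nodes = brute_force_bfs(oracle_adj, sub.query_node, 3)
            assert set(sub.node_ids) == oracle_nodes
            _, r, c = sub.query_node.split("_")
            if 3 <= int(r) <= 8 and 3 <= int(c) <= 8:
                interior_seen += 1
                assert len(sub.node_ids) == 37
        assert interior_seen > 0

    def test_nodes_within_hop_radius(self):
        coords = hexagonal_lattice(9, 9, 100.0)
        graph = build_graph(coords)
        oracle_adj = brute_force_neighbors(coords, graph.distance_threshold)
        for sub in extract_subgraphs(graph, n_hops=3, n_subgraphs=25, seed=5):
            assert set(sub.node_ids) <= brute_force_bfs(oracle_adj, sub.query_node, 3)

    def test_small_component_excluded_by_min_nodes(self):
        lattice = hexagonal_lattice(8, 8, 100.0)
        # a far-away 14-spot chain: its own connected component
        chain = pd.DataFrame(
            {"x": 1e5 + 100.0 * np.arange(14), "y": np.zeros(14)},
            index=[f"chain_{i:02d}" for i in range(14)],
        )
        graph = build_graph(pd.concat([lattice, chain]))
        subs = extract_subgraphs(graph, n_hops=3, n_subgraphs=300, min_nodes=15, seed=2)
        sampled = {n for s in subs for n in s.node_ids}
        assert not any(n.startswith("chain") for n in sampled)

    def test_unreachable_min_nodes_errors_after_retries(self):
        graph = build_graph(hexagonal_lattice(2, 2, 100.0))
        with pytest.raises(RuntimeError, match="attempts"):
            extract_subgraphs(graph, n_subgraphs=5, min_nodes=50, seed=0)

    def test_zero_hops_returns_query_only(self):
        graph = build_graph(hexagonal_lattice(3, 3, 100.0))
        subs = extract_subgraphs(graph, n_hops=0, n_subgraphs=3, min_nodes=1, seed=1)
        for s in subs:
            assert s.node_ids == [s.query_node]

    def test_seeded_extraction_is_reproducible(self):
        graph = build_graph(hexagonal_lattice(8, 8, 100.0))
        a = extract_subgraphs(graph, n_subgraphs=20, seed=9)
        b = extract_subgraphs(graph, n_subgraphs=20, seed=9)
        assert [s.query_node for s in a] == [s.query_node for s in b]
        assert [s.node_ids for s in a] == [s.node_ids for s in b]


class TestNodeFeatures:
    def test_highest_variance_genes_selected(self):
        expr = pd.DataFrame(
            {
                "varying_a": [0.0, 10.0, 0.0, 10.0],
                "varying_b": [0.0, 2.0, 0.0, 2.0],
                "constant": [3.0, 3.0, 3.0, 3.0],
            },
            index=["s0", "s1", "s2", "s3"],
        )
        gene_index, _, _ = variable_gene_stats(expr, n_top_genes=2)
        assert set(gene_index) == {"varying_a", "varying_b"}

    def test_unexpressed_genes_masked_within_subgraph(self):
        expr = pd.DataFrame(
            {"g0": [0.0, 0.0, 5.0], "g1": [1.0, 2.0, 3.0]},
            index=["s0", "s1", "s2"],
        )
        feats = node_features(expr, ["s0", "s1"], n_top_genes=2)
        assert (feats[:, list(expr.columns).index("g0")] == 0).all()

    def test_standardization_uses_supplied_statistics(self):
        expr = pd.DataFrame({"g0": [1.0, 3.0]}, index=["s0", "s1"])
        feats = node_features(
            expr,
            ["s0", "s1"],
            gene_index=pd.Index(["g0"]),
            means=np.array([0.0]),
            stds=np.array([2.0]),
        )
        np.testing.assert_allclose(feats[:, 0], np.log1p([1.0, 3.0]) / 2.0)

    def test_constant_gene_features_are_zero(self):
        expr = pd.DataFrame(
            {"flat": [2.0, 2.0], "var": [1.0, 4.0]}, index=["s0", "s1"]
        )
        feats = node_features(expr, ["s0", "s1"], n_top_genes=2)
        assert (feats[:, list(expr.columns).index("flat")] == 0).all()

    def test_too_many_top_genes_rejected(self):
        expr = pd.DataFrame({"g0": [1.0, 2.0]}, index=["s0", "s1"])
        with pytest.raises(ValueError, match="n_top_genes"):
            variable_gene_stats(expr, n_top_genes=5)
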