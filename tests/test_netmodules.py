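"""Dendrogram, threshold cut, small-module merging, modularity optimization."""

import itertools

import networkx as nx
import numpy as np
import pytest

from moltnet.netmodules import (ModulePartition, build_dendrogram, decompose,
                                merge_small, modularity, optimize_partition,
                                preliminary_partition, summarize_modules)
from moltnet.topology import ReactionGraph


def two_triangles():
    """Two triangles joined by a single bridge edge."""
    g = nx.Graph()
    g.add_edges_from([("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                      ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
                      ("a1", "b1")])
    return g


def two_cliques(size, bridge=1):
    g = nx.Graph()
    left = [f"a{i:02d}" for i in range(size)]
    right = [f"b{i:02d}" for i in range(size)]
    for side in (left, right):
        g.add_edges_from(itertools.combinations(side, 2))
    for i in range(bridge):
        g.add_edge(left[i], right[i])
    return g


def modularity_oracle(assignment, g):
    """Brute-force double-sum Q over all node pairs: Q = (1/2m) *
    sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    m = g.number_of_edges()
    deg = dict(g.degree())
    q = 0.0
    for i in g.nodes:
        for j in g.nodes:
            if assignment[i] != assignment[j]:
                continue
            a_ij = 1.0 if g.has_edge(i, j) else 0.0
            q += a_ij - deg[i] * deg[j] / (2.0 * m)
    return q / (2.0 * m)


class TestDendrogram:
    def test_path_of_four_has_three_merges(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        dnd = build_dendrogram(g)
        assert dnd.n_leaves == 4
        assert dnd.linkage_matrix.shape == (3, 4)
        # nearest pairs (distance 1) merge before distant ones
        assert dnd.linkage_matrix[0, 2] == pytest.approx(1.0)

    def test_two_nodes_single_merge(self):
        g = nx.Graph([("a", "b")])
        assert build_dendrogram(g).linkage_matrix.shape == (1, 4)

    def test_disconnected_input_is_error(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        with pytest.raises(ValueError, match="connected"):
            build_dendrogram(g)

    def test_last_merge_separates_loose_triangles(self):
        dnd = build_dendrogram(two_triangles())
        top = dnd.linkage_matrix[-1]
        # the final merge joins two 3-leaf subtrees
        part = preliminary_partition(dnd, max_size=3)
        modules = part.modules
        assert sorted(len(m) for m in modules.values()) == [3, 3]
        assert {"a1", "a2", "a3"} in modules.values()


class TestPreliminaryPartition:
    def test_sixty_leaves_split_into_two_thirties(self):
        dnd = build_dendrogram(two_cliques(30))
        part = preliminary_partition(dnd, max_size=50)
        assert sorted(len(m) for m in part.modules.values()) == [30, 30]

    def test_small_tree_single_module(self):
        dnd = build_dendrogram(nx.path_graph([f"n{i}" for i in range(10)]))
        part = preliminary_partition(dnd, max_size=50)
        assert part.module_count == 1

    def test_no_module_exceeds_max_size(self, pipeline_result):
        from moltnet.topology import biggest_wcc, graph_from_reconstruction
        wcc = biggest_wcc(graph_from_reconstruction(pipeline_result.recon))
        dnd = build_dendrogram(wcc)
        part = preliminary_partition(dnd, max_size=20)
        assert max(len(m) for m in part.modules.values()) <= 20


class TestMergeSmall:
    def _partition(self, sizes_and_nodes):
        assignment = {}
        for mid, nodes in sizes_and_nodes.items():
            for n in nodes:
                assignment[n] = mid
        return ModulePartition(assignment=assignment)

    def test_small_module_joins_its_only_partner(self):
        g = nx.Graph()
        a = [f"a{i}" for i in range(3)]
        b = [f"b{i}" for i in range(40)]
        c = [f"c{i}" for i in range(45)]
        g.add_edges_from(zip(a, a[1:]))
        g.add_edges_from(zip(b, b[1:]))
        g.add_edges_from(zip(c, c[1:]))
        g.add_edge("a0", "b0")  # A linked only to B
        part = self._partition({1: a, 2: b, 3: c})
        merged = merge_small(part, g, min_size=10)
        modules = merged.modules
        assert sorted(len(m) for m in modules.values()) == [43, 45]

    def test_all_large_modules_unchanged(self):
        g = two_cliques(12)
        part = self._partition({1: [f"a{i:02d}" for i in range(12)],
                                2: [f"b{i:02d}" for i in range(12)]})
        merged = merge_small(part, g, min_size=10)
        assert merged.modules == part.modules

    def test_tied_partners_resolve_to_largest(self):
        g = nx.Graph()
        a = [f"a{i}" for i in range(3)]
        b = [f"b{i:02d}" for i in range(40)]
        c = [f"c{i:02d}" for i in range(45)]
        for chain in (a, b, c):
            g.add_edges_from(zip(chain, chain[1:]))
        g.add_edge(a[0], b[0])
        g.add_edge(a[1], c[0])  # linked to both; C is larger
        part = self._partition({1: a, 2: b, 3: c})
        merged = merge_small(part, g, min_size=10)
        assert sorted(len(m) for m in merged.modules.values()) == [40, 48]


class TestModularity:
    def test_two_triangle_hand_value(self):
        g = two_triangles()
        assignment = {n: 1 if n.startswith("a") else 2 for n in g.nodes}
        assert modularity(assignment, g) == pytest.approx(6 / 7 - 0.5,
                                                          abs=1e-12)

    def test_single_module_is_zero(self):
        g = two_triangles()
        assert modularity({n: 1 for n in g.nodes}, g) == pytest.approx(0.0)

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError):
            modularity({}, nx.Graph())

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(18, 30, seed=int(rng.integers(2**31)))
        assignment = {n: int(rng.integers(3)) for n in g.nodes}
        assert modularity(assignment, g) == pytest.approx(
            modularity_oracle(assignment, g), abs=1e-12)

    def test_random_partitions_of_random_graph_average_near_zero(self):
        rng = np.random.default_rng(7)
        qs = []
        for _ in range(100):
            g = nx.gnm_random_graph(30, 60, seed=int(rng.integers(2**31)))
            assignment = {n: int(rng.integers(3)) for n in g.nodes}
            qs.append(modularity(assignment, g))
        assert abs(np.mean(qs)) < 0.05


class TestOptimizePartition:
    def test_mislabeled_node_moves_home(self):
        g = two_cliques(6)
        assignment = {n: 1 if n.startswith("a") else 2 for n in g.nodes}
        assignment["a05"] = 2  # planted mislabel
        part = ModulePartition(assignment=assignment)
        q_before = modularity(part, g)
        out = optimize_partition(part, g)
        assert out.q > q_before
        modules = out.modules
        assert {f"a{i:02d}" for i in range(6)} in modules.values()

    def test_already_optimal_partition_unchanged(self):
        g = two_cliques(6)
        part = ModulePartition(
            assignment={n: 1 if n.startswith("a") else 2 for n in g.nodes})
        out = optimize_partition(part, g)
        assert out.modules == part.modules

    @pytest.mark.parametrize("seed", range(3))
    def test_q_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(24, 50, seed=int(rng.integers(2**31)))
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        mapping = {n: f"n{n:02d}" for n in g.nodes}
        g = nx.relabel_nodes(g, mapping)
        assignment = {n: int(rng.integers(4)) for n in g.nodes}
        part = ModulePartition(assignment=assignment)
        out = optimize_partition(part, g)
        assert out.q >= modularity(part, g) - 1e-12
        assert out.q == pytest.approx(modularity(out, g), abs=1e-12)


class TestPlantedCommunities:
    @pytest.mark.parametrize("seed", range(5))
    def test_three_planted_modules_recovered(self, seed):
        # intra-module link probability 0.5, inter 0.02, 3 modules of 15
        rng = np.random.default_rng(seed)
        sizes = [15, 15, 15]
        g = nx.stochastic_block_model(
            sizes, [[0.5, 0.02, 0.02], [0.02, 0.5, 0.02], [0.02, 0.02, 0.5]],
            seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        planted = {n: n // 15 for n in g.nodes}
        g = nx.relabel_nodes(g, {n: f"n{n:02d}" for n in g.nodes})
        planted = {f"n{n:02d}": c for n, c in planted.items()}
        part = decompose(g, max_size=20, min_size=5)
        # exact recovery up to relabeling
        recovered = {}
        for node, mid in part.assignment.items():
            recovered.setdefault(mid, set()).add(node)
        planted_sets = {}
        for node, c in planted.items():
            planted_sets.setdefault(c, set()).add(node)
        assert sorted(map(frozenset, recovered.values())) == \
            sorted(map(frozenset, planted_sets.values()))


class TestFinalPartitionInvariants:
    def test_no_small_modules_after_decompose(self, pipeline_result):
        part = pipeline_result.partition
        sizes = [len(m) for m in part.modules.values()]
        assert part.module_count == 1 or min(sizes) >= 5

    def test_assignment_covers_biggest_wcc(self, pipeline_result):
        from moltnet.topology import biggest_wcc, graph_from_reconstruction
        wcc = biggest_wcc(graph_from_reconstruction(pipeline_result.recon))
        assert set(pipeline_result.partition.assignment) == wcc.nodes


def test_summarize_modules_counts_subsystems_and_links():
    graph = ReactionGraph(
        nodes={"r1", "r2", "r3", "r4"},
        arcs={("r1", "r2")},
        edges={frozenset({"r2", "r3"}), frozenset({"r3", "r4"}),
               frozenset({"r1", "r3"})})
    part = ModulePartition(assignment={"r1": 1, "r2": 1, "r3": 2, "r4": 2})
    subsystems = {"r1": "Amino acid metabolism", "r2": "Amino acid metabolism",
                  "r3": "Lipid metabolism", "r4": "Lipid metabolism"}
    summary = summarize_modules(part, subsystems, graph)
    assert summary.subsystems[1] == {"Amino acid metabolism": 2}
    assert summary.links == {(1, 2): 2}
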