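"""Currency pruning, reaction-graph construction, metrics, bow-tie."""

import itertools

import networkx as nx
import numpy as np
import pytest

from moltnet.topology import (BowTiePartition, PrunedReaction, ReactionGraph,
                              bowtie_decompose, build_reaction_graph,
                              degree_ranking, random_cc_ensemble,
                              remove_currency, topo_metrics, write_pajek)

from conftest import make_reaction, make_recon


def pruned(rid, main, reversible=False):
    return PrunedReaction(id=rid, main=dict(main), reversible=reversible)


class TestRemoveCurrency:
    def test_currency_stripped_from_main_equation(self):
        recon = make_recon(make_reaction(
            "R", {"A_c": -1, "C00002_c": -1, "B_c": 1, "C00008_c": 1},
            reversible=False))
        out = remove_currency(recon)
        assert out["R"].main == {"A_c": -1, "B_c": 1}

    def test_all_currency_reaction_dropped(self):
        recon = make_recon(make_reaction(
            "R", {"C00002_c": -1, "C00001_c": -1, "C00008_c": 1, "C00009_c": 1},
            reversible=False))
        assert remove_currency(recon) == {}

    def test_exchange_and_all_currency_dropped_counting(self):
        reactions = [make_reaction(f"R{i}", {f"A{i}_c": -1, f"B{i}_c": 1})
                     for i in range(5)]
        reactions += [make_reaction(f"RC{i}", {"C00002_c": -1, "C00008_c": 1})
                      for i in range(2)]
        reactions += [make_reaction(f"EX_X{i}", {f"X{i}_e": -1},
                                    category="exchange") for i in range(3)]
        recon = make_recon(*reactions)
        assert len(recon.reactions) == 10
        assert len(remove_currency(recon)) == 5

    def test_never_increases_reaction_count(self, pipeline_result):
        recon = pipeline_result.recon
        assert len(remove_currency(recon)) <= len(recon.reactions)


class TestBuildReactionGraph:
    def test_irreversible_chain_gives_arc(self):
        graph = build_reaction_graph({
            "R2": pruned("R2", {"A": -1, "B": 1}),
            "R3": pruned("R3", {"B": -1, "C": 1}),
        })
        assert graph.arcs == {("R2", "R3")}
        assert graph.edges == set()

    def test_reversible_pair_gives_single_edge(self):
        graph = build_reaction_graph({
            "R2": pruned("R2", {"A": -1, "B": 1}, reversible=True),
            "R3": pruned("R3", {"B": -1, "C": 1}, reversible=True),
        })
        assert graph.arcs == set()
        assert graph.edges == {frozenset({"R2", "R3"})}

    def test_irreversible_cycle_gives_three_arcs(self):
        graph = build_reaction_graph({
            "R1": pruned("R1", {"A": -1, "B": 1}),
            "R2": pruned("R2", {"B": -1, "C": 1}),
            "R3": pruned("R3", {"C": -1, "A": 1}),
        })
        assert graph.arcs == {("R1", "R2"), ("R2", "R3"), ("R3", "R1")}
        assert graph.edges == set()

    def test_node_set_equals_pruned_reactions(self, pipeline_result):
        out = remove_currency(pipeline_result.recon)
        graph = build_reaction_graph(out)
        assert graph.nodes == set(out)
        for a, b in graph.arcs:
            assert frozenset({a, b}) not in graph.edges


def triangle_graph():
    return ReactionGraph(nodes={"a", "b", "c"},
                         edges={frozenset(p) for p in
                                itertools.combinations("abc", 2)})


class TestTopoMetrics:
    def test_triangle(self):
        m = topo_metrics(triangle_graph())
        assert m.density == pytest.approx(1.0)
        assert m.average_degree == pytest.approx(2.0)
        assert m.diameter == 1
        assert m.clustering == pytest.approx(1.0)

    def test_path_of_three(self):
        graph = ReactionGraph(nodes={"a", "b", "c"},
                              edges={frozenset("ab"), frozenset("bc")})
        m = topo_metrics(graph)
        assert m.density == pytest.approx(2 / 3)
        assert m.average_path_length == pytest.approx(4 / 3)
        assert m.diameter == 2
        assert m.clustering == pytest.approx(0.0)

    def test_single_node_has_no_path_metrics(self):
        m = topo_metrics(ReactionGraph(nodes={"a"}))
        assert m.density == 0.0
        assert m.average_path_length is None and m.diameter is None

    def test_metrics_invariant_under_arc_flips(self):
        arcs = {("a", "b"), ("b", "c"), ("c", "d")}
        g1 = ReactionGraph(nodes=set("abcd"), arcs=arcs)
        g2 = ReactionGraph(nodes=set("abcd"),
                           arcs={(b, a) for a, b in arcs})
        m1, m2 = topo_metrics(g1), topo_metrics(g2)
        assert (m1.density, m1.average_degree, m1.diameter, m1.clustering) == \
               (m2.density, m2.average_degree, m2.diameter, m2.clustering)


def bowtie_oracle(graph: ReactionGraph) -> BowTiePartition:
    """O(n^2) pairwise-reachability oracle."""
    directed = graph.directed()
    nodes = sorted(graph.collapsed().nodes)
    comps = sorted(nx.connected_components(graph.collapsed()),
                   key=lambda c: (-len(c), min(c)))
    wcc = set(comps[0]) if comps else set()
    reach = {a: set(nx.descendants(directed, a)) | {a} for a in nodes}
    # strongly connected equivalence by mutual reachability
    sccs = []
    remaining = set(wcc)
    while remaining:
        a = min(remaining)
        scc = {b for b in remaining if b in reach[a] and a in reach[b]}
        sccs.append(scc)
        remaining -= scc
    sccs.sort(key=lambda c: (-len(c), min(c)))
    gsc = sccs[0]
    anchor = min(gsc)
    s = {b for b in wcc if anchor in reach[b]} - gsc
    p = (reach[anchor] & wcc) - gsc
    return BowTiePartition(frozenset(gsc), frozenset(s), frozenset(p),
                           frozenset(wcc - gsc - s - p))


class TestBowTie:
    def test_worked_example(self):
        graph = ReactionGraph(
            nodes={"s", "g1", "g2", "p", "x"},
            arcs={("s", "g1"), ("g1", "g2"), ("g2", "g1"), ("g2", "p"),
                  ("s", "x")})
        part = bowtie_decompose(graph)
        assert part.gsc == {"g1", "g2"}
        assert part.s == {"s"}
        assert part.p == {"p"}
        assert part.isolated == {"x"}

    def test_single_cycle_is_all_gsc(self):
        graph = ReactionGraph(nodes={"a", "b", "c"},
                              arcs={("a", "b"), ("b", "c"), ("c", "a")})
        part = bowtie_decompose(graph)
        assert part.gsc == {"a", "b", "c"}
        assert not part.s and not part.p and not part.isolated

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reachability_oracle_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        g = nx.gnp_random_graph(n, 2.0 / n, directed=True,
                                seed=int(rng.integers(2**31)))
        graph = ReactionGraph(
            nodes={str(v) for v in g.nodes},
            arcs={(str(a), str(b)) for a, b in g.edges if a != b})
        ours, oracle = bowtie_decompose(graph), bowtie_oracle(graph)
        assert (ours.gsc, ours.s, ours.p, ours.isolated) == \
               (oracle.gsc, oracle.s, oracle.p, oracle.isolated)

    def test_partition_disjoint_and_exhaustive(self, pipeline_result):
        part = pipeline_result.bowtie
        sets = [part.gsc, part.s, part.p, part.isolated]
        assert sum(len(s) for s in sets) == len(part.wcc)
        for a, b in itertools.combinations(sets, 2):
            assert not a & b


class TestRandomEnsemble:
    def test_complete_graph_cc_is_one(self):
        assert random_cc_ensemble(4, 6, reps=5, seed=1) == (1.0, 1.0)

    def test_sparse_random_graphs_have_low_cc(self):
        low, high = random_cc_ensemble(100, 100, reps=100, seed=1)
        assert 0.0 <= low <= high < 0.3

    def test_too_many_links_rejected(self):
        with pytest.raises(ValueError):
            random_cc_ensemble(4, 7, reps=1, seed=1)

    def test_observed_clustering_exceeds_random(self, pipeline_result):
        low, high = pipeline_result.random_cc_range
        from moltnet.topology import biggest_wcc, graph_from_reconstruction
        wcc = biggest_wcc(graph_from_reconstruction(pipeline_result.recon))
        observed = topo_metrics(wcc).clustering
        assert observed > high


class TestDegreeRanking:
    def test_star_center_first(self):
        graph = ReactionGraph(
            nodes={"h", "l1", "l2", "l3", "l4"},
            edges={frozenset({"h", f"l{i}"}) for i in range(1, 5)})
        ranking = degree_ranking(graph)
        assert ranking[0] == ("h", 4)

    def test_ties_broken_lexicographically(self):
        graph = ReactionGraph(nodes={"a", "b"}, edges={frozenset({"a", "b"})})
        assert degree_ranking(graph) == [("a", 1), ("b", 1)]


def test_pajek_output_sections(tmp_path):
    graph = ReactionGraph(nodes={"a", "b", "c"},
                          arcs={("a", "b")}, edges={frozenset({"b", "c"})})
    path = tmp_path / "net.net"
    write_pajek(graph, path)
    text = path.read_text()
    assert text.startswith("*Vertices 3")
    assert "*Arcs" in text and "*Edges" in text
    assert '1 "a"' in text
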