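"""Reaction-graph topology: currency pruning, metrics, bow-tie structure.

For topological analysis the network is turned into a *reaction graph*:
reactions are nodes and a shared main metabolite is a link.  The link
r1 -> r2 is directed (an "arc") when a product of r1, in a direction the
reaction can run, is a substrate of r2; when the relation holds both ways
(through reversibility) the pair carries a single undirected "edge" instead.
Currency carriers (ATP, NAD(H), water, ...) participate in so many reactions
that they hide the main-substrate transformations, so they are removed
first, along with exchange reactions and any reaction whose main equation
is left empty.

Scalar metrics are computed Pajek-style: the average degree counts every
incident arc and edge, while density, path lengths, diameter and clustering
are taken on the direction-collapsed simple graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .gapfill import DEFAULT_CURRENCY
from .reconstruct import Reconstruction, base_id


@dataclass
class PrunedReaction:
    id: str
    main: dict[str, float]
    reversible: bool


@dataclass
class ReactionGraph:
    """Mixed directed/undirected reaction graph.

    A node pair is linked by either one undirected edge or up to two arcs,
    never both; self-links are excluded by construction.
    """

    nodes: set[str] = field(default_factory=set)
    arcs: set[tuple[str, str]] = field(default_factory=set)
    edges: set[frozenset[str]] = field(default_factory=set)
    attrs: dict[str, dict] = field(default_factory=dict)

    def degree(self, node: str) -> int:
        d = sum(1 for a, b in self.arcs if node in (a, b))
        d += sum(1 for e in self.edges if node in e)
        return d

    def n_links(self) -> int:
        return len(self.arcs) + len(self.edges)

    def directed(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        for e in self.edges:
            a, b = tuple(e)
            g.add_edge(a, b)
            g.add_edge(b, a)
        return g

    def collapsed(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        for e in self.edges:
            a, b = tuple(e)
            g.add_edge(a, b)
        return g

    def subgraph(self, nodes: Iterable[str]) -> "ReactionGraph":
        keep = set(nodes)
        return ReactionGraph(
            nodes=self.nodes & keep,
            arcs={(a, b) for a, b in self.arcs if a in keep and b in keep},
            edges={e for e in self.edges if e <= keep},
            attrs={n: self.attrs[n] for n in keep & self.attrs.keys()},
        )


@dataclass
class BowTiePartition:
    """Bow-tie split of the biggest WCC: GSC is the largest strongly
    connected component, S feeds it, P is fed by it, IS is the rest."""
    gsc: frozenset[str]
    s: frozenset[str]
    p: frozenset[str]
    isolated: frozenset[str]

    @property
    def wcc(self) -> frozenset[str]:
        return self.gsc | self.s | self.p | self.isolated


@dataclass
class TopoSummary:
    n_nodes: int
    n_arcs: int
    n_edges: int
    density: float
    average_degree: float
    average_path_length: float | None
    diameter: int | None
    clustering: float
    wcc_count: int
    wcc_sizes: list[int]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def remove_currency(recon: Reconstruction,
                    currency: frozenset[str] = DEFAULT_CURRENCY
                    ) -> dict[str, PrunedReaction]:
    """Strip currency metabolites from every main equation.

    Exchange and biomass reactions are dropped, as are reactions whose main
    equation contains only currency metabolites."""
    pruned: dict[str, PrunedReaction] = {}
    for rid, rxn in recon.reactions.items():
        if rxn.category in ("exchange", "biomass"):
            continue
        main = {m: c for m, c in rxn.main_stoichiometry.items()
                if base_id(m) not in currency}
        if not main:
            continue
        pruned[rid] = PrunedReaction(id=rid, main=main, reversible=rxn.reversible)
    return pruned


def build_reaction_graph(pruned: Mapping[str, PrunedReaction],
                         attrs: Mapping[str, dict] | None = None
                         ) -> ReactionGraph:
    """Arc r1 -> r2 iff a main product of r1 (in an allowed direction) is a
    main substrate of r2; symmetric connections become one edge."""
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for rid, rxn in pruned.items():
        for met, coef in rxn.main.items():
            if rxn.reversible or coef > 0:
                producers.setdefault(met, set()).add(rid)
            if rxn.reversible or coef < 0:
                consumers.setdefault(met, set()).add(rid)

    connected: set[tuple[str, str]] = set()
    for met, prods in producers.items():
        for r1 in prods:
            for r2 in consumers.get(met, ()):
                if r1 != r2:
                    connected.add((r1, r2))

    graph = ReactionGraph(nodes=set(pruned))
    for r1, r2 in connected:
        if (r2, r1) in connected:
            graph.edges.add(frozenset((r1, r2)))
        else:
            graph.arcs.add((r1, r2))
    if attrs:
        graph.attrs = {n: dict(attrs[n]) for n in graph.nodes if n in attrs}
    return graph


def graph_from_reconstruction(recon: Reconstruction,
                              currency: frozenset[str] = DEFAULT_CURRENCY
                              ) -> ReactionGraph:
    pruned = remove_currency(recon, currency)
    attrs = {rid: {"pathway": recon.reactions[rid].pathway_id,
                   "subsystem": recon.reactions[rid].subsystem}
             for rid in pruned}
    return build_reaction_graph(pruned, attrs)


def topo_metrics(graph: ReactionGraph) -> TopoSummary:
    if not graph.nodes:
        raise ValueError("empty graph")
    n = len(graph.nodes)
    collapsed = graph.collapsed()
    components = sorted((set(c) for c in nx.connected_components(collapsed)),
                        key=lambda c: (-len(c), min(c)))
    density = 0.0
    if n > 1:
        density = collapsed.number_of_edges() / (n * (n - 1) / 2)
    average_degree = 2.0 * graph.n_links() / n

    biggest = collapsed.subgraph(components[0])
    if biggest.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(biggest)
        diameter = nx.diameter(biggest)
    else:
        apl, diameter = None, None

    return TopoSummary(
        n_nodes=n,
        n_arcs=len(graph.arcs),
        n_edges=len(graph.edges),
        density=density,
        average_degree=average_degree,
        average_path_length=apl,
        diameter=diameter,
        clustering=nx.average_clustering(collapsed) if n > 0 else 0.0,
        wcc_count=len(components),
        wcc_sizes=[len(c) for c in components],
    )


def biggest_wcc(graph: ReactionGraph) -> ReactionGraph:
    components = sorted((set(c) for c in nx.connected_components(graph.collapsed())),
                        key=lambda c: (-len(c), min(c)))
    if not components:
        return ReactionGraph()
    return graph.subgraph(components[0])


def bowtie_decompose(graph: ReactionGraph) -> BowTiePartition:
    """Bow-tie partition of the biggest WCC.

    GSC is the largest strongly connected component (ties broken by smallest
    member id); S holds the nodes with a directed path *into* the GSC, P the
    nodes reachable *from* it, IS the remainder of the WCC.
    """
    wcc = biggest_wcc(graph)
    directed = wcc.directed()
    if not wcc.nodes:
        return BowTiePartition(frozenset(), frozenset(), frozenset(), frozenset())
    sccs = sorted((set(c) for c in nx.strongly_connected_components(directed)),
                  key=lambda c: (-len(c), min(c)))
    gsc = sccs[0]
    anchor = min(gsc)
    s = nx.ancestors(directed, anchor) - gsc
    p = nx.descendants(directed, anchor) - gsc
    isolated = set(wcc.nodes) - gsc - s - p
    return BowTiePartition(frozenset(gsc), frozenset(s), frozenset(p),
                           frozenset(isolated))


def random_cc_ensemble(n: int, links: int, reps: int = 100,
                       seed: int = 0) -> tuple[float, float]:
    """Clustering-coefficient range over uniform random simple graphs with
    the same node and link counts."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if links > n * (n - 1) // 2:
        raise ValueError("more links than a simple graph allows")
    rng = np.random.default_rng(seed)
    ccs = []
    for _ in range(reps):
        g = nx.gnm_random_graph(n, links, seed=int(rng.integers(2**31)))
        ccs.append(nx.average_clustering(g))
    return (min(ccs), max(ccs))


def degree_ranking(graph: ReactionGraph) -> list[tuple[str, int]]:
    """Nodes by descending degree (arcs + edges incident), ties by id."""
    return sorted(((node, graph.degree(node)) for node in graph.nodes),
                  key=lambda item: (-item[1], item[0]))


def write_pajek(graph: ReactionGraph, path: str | Path) -> None:
    """Pajek NET format: *Vertices, then *Arcs, then *Edges."""
    nodes = sorted(graph.nodes)
    index = {node: i + 1 for i, node in enumerate(nodes)}
    lines = [f"*Vertices {len(nodes)}"]
    lines += [f'{i + 1} "{node}"' for i, node in enumerate(nodes)]
    lines.append("*Arcs")
    lines += [f"{index[a]} {index[b]}" for a, b in sorted(graph.arcs)]
    lines.append("*Edges")
    lines += [f"{index[a]} {index[b]}"
              for a, b in sorted(tuple(sorted(e)) for e in graph.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_table(graph: ReactionGraph, path: str | Path) -> None:
    lines = ["source\ttarget\tkind"]
    lines += [f"{a}\t{b}\tarc" for a, b in sorted(graph.arcs)]
    lines += [f"{a}\t{b}\tedge"
              for a, b in sorted(tuple(sorted(e)) for e in graph.edges)]
    Path(path).write_text("\n".join(lines) + "\n")
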