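"""Functional module decomposition of the biggest weakly connected component.

The decomposition combines a hierarchical classification tree with Newman
modularity: (1) average-linkage agglomerative clustering on shortest-path
distances of the direction-collapsed graph yields a dendrogram; (2) the tree
is traversed top-down until every subtree holds at most ``max_size`` nodes
(the preliminary partition); (3) modules smaller than ``min_size`` are
merged into the largest module they connect to; (4) greedy single-node moves
between linked modules refine the partition while the modularity Q
increases.  All steps are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .topology import ReactionGraph

DEFAULT_MAX_SIZE = 50
DEFAULT_MIN_SIZE = 10
Q_TOLERANCE = 1e-12


@dataclass
class Dendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    q: float | None = None

    @property
    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, mid in self.assignment.items():
            out.setdefault(mid, set()).add(node)
        return out

    @property
    def module_count(self) -> int:
        return len(set(self.assignment.values()))


def _as_collapsed(graph: ReactionGraph | nx.Graph) -> nx.Graph:
    return graph.collapsed() if isinstance(graph, ReactionGraph) else graph


def build_dendrogram(graph: ReactionGraph | nx.Graph) -> Dendrogram:
    """Average-linkage tree over shortest-path distances; the input graph
    must be connected (use the biggest WCC)."""
    g = _as_collapsed(graph)
    if g.number_of_nodes() < 2:
        raise ValueError("dendrogram needs at least two nodes")
    if not nx.is_connected(g):
        raise ValueError("graph must be connected")
    labels = sorted(g.nodes)
    index = {n: i for i, n in enumerate(labels)}
    dist = np.zeros((len(labels), len(labels)))
    for source, lengths in nx.shortest_path_length(g):
        for target, d in lengths.items():
            dist[index[source], index[target]] = d
    z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(labels=labels, linkage_matrix=z)


def preliminary_partition(dendrogram: Dendrogram,
                          max_size: int = DEFAULT_MAX_SIZE) -> ModulePartition:
    """Top-down traversal: descend until every subtree has <= max_size leaves;
    each such subtree becomes a module (numbered 1.. in traversal order)."""
    root = to_tree(dendrogram.linkage_matrix)
    assignment: dict[str, int] = {}
    next_id = 1
    stack = [root]
    while stack:
        node = stack.pop()
        if node.count <= max_size or node.is_leaf():
            for leaf in node.pre_order(lambda x: x.id):
                assignment[dendrogram.labels[leaf]] = next_id
            next_id += 1
        else:
            # right first so the left child is processed (and numbered) first
            stack.append(node.right)
            stack.append(node.left)
    return ModulePartition(assignment=assignment)


def _renumber(assignment: Mapping[str, int]) -> dict[str, int]:
    order: dict[int, int] = {}
    out = {}
    for node in sorted(assignment):
        mid = assignment[node]
        if mid not in order:
            order[mid] = len(order) + 1
        out[node] = order[mid]
    return out


def merge_small(partition: ModulePartition, graph: ReactionGraph | nx.Graph,
                min_size: int = DEFAULT_MIN_SIZE) -> ModulePartition:
    """Merge each sub-threshold module into the largest module it links to.

    The smallest offender is handled first; a module with no connected
    partner is left in place.  Runs until no mergeable offender remains.
    """
    g = _as_collapsed(graph)
    assignment = dict(partition.assignment)
    stuck: set[int] = set()
    while True:
        modules: dict[int, set[str]] = {}
        for node, mid in assignment.items():
            modules.setdefault(mid, set()).add(node)
        if len(modules) <= 1:
            break
        small = sorted((mid for mid, members in modules.items()
                        if len(members) < min_size and mid not in stuck),
                       key=lambda mid: (len(modules[mid]), mid))
        if not small:
            break
        target_mid = small[0]
        members = modules[target_mid]
        partners: set[int] = set()
        for node in members:
            for neigh in g.neighbors(node):
                other = assignment[neigh]
                if other != target_mid:
                    partners.add(other)
        if not partners:
            stuck.add(target_mid)
            continue
        winner = max(partners, key=lambda mid: (len(modules[mid]), -mid))
        for node in members:
            assignment[node] = winner
    return ModulePartition(assignment=_renumber(assignment))


def modularity(partition: ModulePartition | Mapping[str, int],
               graph: ReactionGraph | nx.Graph) -> float:
    """Newman modularity Q = sum_i (e_ii - a_i^2) on the collapsed simple
    graph, where e_ii is the intra-module link fraction and a_i the fraction
    of link ends in module i."""
    g = _as_collapsed(graph)
    assignment = (partition.assignment if isinstance(partition, ModulePartition)
                  else dict(partition))
    m = g.number_of_edges()
    if g.number_of_nodes() == 0 or m == 0:
        raise ValueError("modularity undefined on an empty graph")
    communities: dict[int, set[str]] = {}
    for node, mid in assignment.items():
        communities.setdefault(mid, set()).add(node)
    return float(nx.algorithms.community.modularity(
        g, list(communities.values())))


def optimize_partition(partition: ModulePartition,
                       graph: ReactionGraph | nx.Graph,
                       tol: float = Q_TOLERANCE) -> ModulePartition:
    """Greedy single-node moves between linked modules; a move is accepted
    iff it raises Q by more than ``tol``.  Deterministic sweep order (sorted
    node ids); terminates at a local optimum, so Q never decreases."""
    g = _as_collapsed(graph)
    assignment = dict(partition.assignment)
    m = g.number_of_edges()
    if m == 0:
        return ModulePartition(assignment=_renumber(assignment),
                               q=modularity(partition, g))

    degree = dict(g.degree())
    two_m = 2.0 * m
    deg_sum: dict[int, float] = {}  # sum of degrees per module
    for node, mid in assignment.items():
        deg_sum[mid] = deg_sum.get(mid, 0.0) + degree[node]

    def delta_q(node: str, source: int, target: int) -> float:
        # move node from source (which contains it) to target:
        # dQ = (l_t - l_s)/m - k (K_t - K_s + k) / (2 m^2)
        l_source = sum(1.0 for nb in g.neighbors(node)
                       if nb != node and assignment[nb] == source)
        l_target = sum(1.0 for nb in g.neighbors(node)
                       if assignment[nb] == target)
        k = degree[node]
        return ((l_target - l_source) / m
                - k * (deg_sum[target] - deg_sum[source] + k) / (two_m * m))

    improved = True
    while improved:
        improved = False
        for node in sorted(assignment):
            source = assignment[node]
            neighbors = {assignment[nb] for nb in g.neighbors(node)} - {source}
            best_gain, best_target = tol, None
            for target in sorted(neighbors):
                gain = delta_q(node, source, target)
                if gain > best_gain:
                    best_gain, best_target = gain, target
            if best_target is not None:
                deg_sum[source] -= degree[node]
                deg_sum[best_target] += degree[node]
                assignment[node] = best_target
                improved = True

    out = ModulePartition(assignment=_renumber(assignment))
    out.q = modularity(out, g)
    return out


def decompose(graph: ReactionGraph | nx.Graph,
              max_size: int = DEFAULT_MAX_SIZE,
              min_size: int = DEFAULT_MIN_SIZE) -> ModulePartition:
    """Full pipeline: dendrogram -> threshold cut -> merge small ->
    modularity refinement -> merge small again (refinement may shrink a
    module below threshold)."""
    dendrogram = build_dendrogram(graph)
    partition = preliminary_partition(dendrogram, max_size=max_size)
    partition = merge_small(partition, graph, min_size=min_size)
    partition = optimize_partition(partition, graph)
    partition = merge_small(partition, graph, min_size=min_size)
    partition.q = modularity(partition, graph)
    return partition


@dataclass
class ModuleSummary:
    subsystems: dict[int, dict[str, int]] = field(default_factory=dict)
    links: dict[tuple[int, int], int] = field(default_factory=dict)


def summarize_modules(partition: ModulePartition,
                      subsystems: Mapping[str, str],
                      graph: ReactionGraph | nx.Graph) -> ModuleSummary:
    """Per-module subsystem composition and inter-module link counts (the
    connection strength between module pairs)."""
    summary = ModuleSummary()
    for node, mid in partition.assignment.items():
        sub = subsystems.get(node, "unassigned")
        bucket = summary.subsystems.setdefault(mid, {})
        bucket[sub] = bucket.get(sub, 0) + 1

    if isinstance(graph, ReactionGraph):
        links = list(graph.arcs) + [tuple(e) for e in graph.edges]
    else:
        links = list(graph.edges())
    for a, b in links:
        ma, mb = partition.assignment.get(a), partition.assignment.get(b)
        if ma is None or mb is None or ma == mb:
            continue
        key = (min(ma, mb), max(ma, mb))
        summary.links[key] = summary.links.get(key, 0) + 1
    return summary


def write_assignment(partition: ModulePartition,
                     subsystems: Mapping[str, str], path: str | Path) -> None:
    lines = ["reaction\tmodule\tsubsystem"]
    for node in sorted(partition.assignment):
        lines.append(f"{node}\t{partition.assignment[node]}"
                     f"\t{subsystems.get(node, 'unassigned')}")
    Path(path).write_text("\n".join(lines) + "\n")
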