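"""Connectivity-driven gap filling over weakly connected components (WCCs).

The reference reactions absent from the reconstruction form the "metabolic
environment".  Gap filling proceeds in two passes: inside each pathway's
subnetwork, then globally.  At each step the candidate environment reaction
that merges the most WCCs is added (greedily, never backtracking), with ties
broken by pathway affinity — a candidate whose pathway matches reactions in
the components it joins is preferred — and finally by reaction id.

Two reactions are adjacent when they share a non-currency main-equation
metabolite; currency carriers (ATP, NADH, water, ...) would otherwise glue
the whole network into one component and hide every real breakpoint.  The
biomass pseudo-reaction is excluded for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .reconstruct import (NetworkReaction, Reconstruction, base_id,
                          reaction_from_record)
from .refdb import ReferenceDatabase

#: ATP, ADP, NAD(H), NADP(H), phosphate, water, H+, O2, CO2
DEFAULT_CURRENCY = frozenset({
    "C00001", "C00002", "C00003", "C00004", "C00005", "C00006",
    "C00007", "C00008", "C00009", "C00011", "C00080",
})


@dataclass
class GapResult:
    added: list[tuple[str, str, int]] = field(default_factory=list)
    #: (reaction id, scale "pathway"|"global", number of components merged)
    wcc_before: int = 0
    wcc_after: int = 0
    dead_ends_before: int = 0
    dead_ends_after: int = 0

    @property
    def added_ids(self) -> frozenset[str]:
        return frozenset(rid for rid, _, _ in self.added)


def reaction_adjacency(reactions: Mapping[str, NetworkReaction],
                       currency: frozenset[str] = DEFAULT_CURRENCY) -> nx.Graph:
    """Undirected reaction-node graph: edge iff two reactions share a
    non-currency main-equation metabolite.  Biomass reactions excluded."""
    graph = nx.Graph()
    by_met: dict[str, list[str]] = {}
    for rid, rxn in reactions.items():
        if rxn.category == "biomass":
            continue
        graph.add_node(rid)
        for met in rxn.main_stoichiometry:
            if base_id(met) in currency:
                continue
            by_met.setdefault(met, []).append(rid)
    for members in by_met.values():
        # a star suffices: only connectivity matters here
        first = members[0]
        for other in members[1:]:
            graph.add_edge(first, other)
    return graph


def wcc_partition(graph: nx.Graph) -> list[set[str]]:
    """WCCs in canonical order: descending size, ties by smallest member."""
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def dead_end_metabolites(reactions: Mapping[str, NetworkReaction],
                         currency: frozenset[str] = DEFAULT_CURRENCY
                         ) -> frozenset[str]:
    """Non-currency metabolites that are only produced or only consumed.

    Reversible reactions (including exchanges) count as both producer and
    consumer of each of their metabolites."""
    produced: set[str] = set()
    consumed: set[str] = set()
    seen: set[str] = set()
    for rxn in reactions.values():
        if rxn.category == "biomass":
            continue
        for met, coef in rxn.stoichiometry.items():
            if base_id(met) in currency:
                continue
            seen.add(met)
            if rxn.reversible:
                produced.add(met)
                consumed.add(met)
            elif coef > 0:
                produced.add(met)
            else:
                consumed.add(met)
    return frozenset(seen - (produced & consumed))


def _touched_components(rxn: NetworkReaction, components: list[set[str]],
                        reactions: Mapping[str, NetworkReaction],
                        currency: frozenset[str]) -> list[int]:
    """Indexes of components sharing a non-currency main metabolite with rxn."""
    mets = {m for m in rxn.main_stoichiometry if base_id(m) not in currency}
    touched = []
    for i, comp in enumerate(components):
        for rid in comp:
            other = reactions[rid]
            if any(m in other.main_stoichiometry for m in mets):
                touched.append(i)
                break
    return touched


def _environment(recon: Reconstruction, db: ReferenceDatabase
                 ) -> dict[str, NetworkReaction]:
    env = {}
    for rid in sorted(db.reactions):
        if rid not in recon.reactions:
            env[rid] = reaction_from_record(db.reactions[rid], db)
    return env


def fill_pathway_scale(recon: Reconstruction, db: ReferenceDatabase,
                       currency: frozenset[str] = DEFAULT_CURRENCY) -> GapResult:
    """Fill gaps inside each pathway's subnetwork.

    Candidates are environment reactions assigned to the pathway under
    consideration; a candidate is added when it merges at least two of the
    pathway's WCCs.  Pathways are processed in sorted order; within a
    pathway, candidates merging more components win, then smaller ids.
    """
    env = _environment(recon, db)
    result = GapResult(
        wcc_before=len(wcc_partition(reaction_adjacency(recon.reactions, currency))),
        dead_ends_before=len(dead_end_metabolites(recon.reactions, currency)),
    )

    env_by_pathway: dict[str, list[str]] = {}
    for rid, rxn in env.items():
        env_by_pathway.setdefault(rxn.pathway_id, []).append(rid)

    pathways = sorted({r.pathway_id for r in recon.reactions.values()
                       if r.category == "metabolic" and r.pathway_id != "unassigned"})
    for pathway in pathways:
        candidates = env_by_pathway.get(pathway, [])
        while candidates:
            members = {rid: r for rid, r in recon.reactions.items()
                       if r.pathway_id == pathway}
            comps = wcc_partition(reaction_adjacency(members, currency))
            if len(comps) < 2:
                break
            best: tuple[int, str] | None = None
            for rid in candidates:
                touched = _touched_components(env[rid], comps, members, currency)
                if len(touched) >= 2:
                    key = (-len(touched), rid)
                    if best is None or key < best:
                        best = key
            if best is None:
                break
            n_merged, rid = -best[0], best[1]
            recon.add_reaction(env.pop(rid), provenance="gap")
            candidates.remove(rid)
            result.added.append((rid, "pathway", n_merged))

    result.wcc_after = len(wcc_partition(reaction_adjacency(recon.reactions, currency)))
    result.dead_ends_after = len(dead_end_metabolites(recon.reactions, currency))
    return result


def _pathway_grade(rxn: NetworkReaction, touched: list[int],
                   components: list[set[str]],
                   reactions: Mapping[str, NetworkReaction]) -> int:
    """Affinity of a candidate with the components it would join:
    3 = its pathway present in >= 2 of them, 2 = in one,
    1 = its subsystem present in one, 0 = none."""
    pathway_hits = 0
    subsystem_hit = False
    for i in touched:
        pathways = {reactions[r].pathway_id for r in components[i]}
        subsystems = {reactions[r].subsystem for r in components[i]}
        if rxn.pathway_id in pathways:
            pathway_hits += 1
        if rxn.subsystem in subsystems:
            subsystem_hit = True
    if pathway_hits >= 2:
        return 3
    if pathway_hits == 1:
        return 2
    return 1 if subsystem_hit else 0


def fill_global_scale(recon: Reconstruction, db: ReferenceDatabase,
                      currency: frozenset[str] = DEFAULT_CURRENCY) -> GapResult:
    """Greedy global fill: while an environment reaction merges >= 2 WCCs,
    add the best candidate (most components, then pathway affinity, then id)
    and recompute the partition."""
    env = _environment(recon, db)
    result = GapResult(
        wcc_before=len(wcc_partition(reaction_adjacency(recon.reactions, currency))),
        dead_ends_before=len(dead_end_metabolites(recon.reactions, currency)),
    )
    while True:
        comps = wcc_partition(reaction_adjacency(recon.reactions, currency))
        if len(comps) < 2:
            break
        reactions = {rid: r for rid, r in recon.reactions.items()
                     if r.category != "biomass"}
        best: tuple[int, int, str] | None = None
        for rid in sorted(env):
            touched = _touched_components(env[rid], comps, reactions, currency)
            if len(touched) < 2:
                continue
            grade = _pathway_grade(env[rid], touched, comps, reactions)
            key = (-len(touched), -grade, rid)
            if best is None or key < best:
                best = key
        if best is None:
            break
        n_merged, rid = -best[0], best[2]
        recon.add_reaction(env.pop(rid), provenance="gap")
        result.added.append((rid, "global", n_merged))

    result.wcc_after = len(wcc_partition(reaction_adjacency(recon.reactions, currency)))
    result.dead_ends_after = len(dead_end_metabolites(recon.reactions, currency))
    return result


def merge_results(*results: GapResult) -> GapResult:
    merged = GapResult(
        wcc_before=results[0].wcc_before,
        wcc_after=results[-1].wcc_after,
        dead_ends_before=results[0].dead_ends_before,
        dead_ends_after=results[-1].dead_ends_after,
    )
    for r in results:
        merged.added.extend(r.added)
    return merged


def write_gap_table(result: GapResult, path) -> None:
    from pathlib import Path
    lines = ["reaction\tscale\tcomponents_merged"]
    lines += [f"{rid}\t{scale}\t{n}" for rid, scale, n in result.added]
    Path(path).write_text("\n".join(lines) + "\n")
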