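"""End-to-end pipeline on synthetic fixtures.

Runs every stage in the order the reconstruction protocol prescribes:
draft from annotations -> chirality unification -> biomass reaction ->
transport/exchange additions -> gap filling (pathway, then global scale) ->
model conversion and evaluation (non-essential amino acids, biomass,
ecdysone) -> topology -> module decomposition -> differential-expression
overlay -> three-network comparison.  Every quantity in the returned result
is computed at run time from seed-derived fixtures whose ground truth is
recorded alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from . import (biomass, cbm, compare, expression, gapfill, netmodules,
               reconstruct, synthdata, topology)

#: fixture-scale module thresholds: the biggest synthetic WCC holds ~50
#: reactions, so the cut/merge sizes keep the same proportion to network
#: size as 50/10 does to a thousand-reaction organ network
MODULE_MAX_SIZE = 20
MODULE_MIN_SIZE = 5

SULFIDE = "C00283"


@dataclass
class PipelineResult:
    seed: int
    draft_reactions: int = 0
    draft_metabolites: int = 0
    draft_unigenes: int = 0
    chirality_reactions_changed: int = 0
    transport_exchange_added: int = 0
    gap: gapfill.GapResult = field(default_factory=gapfill.GapResult)
    gap_recovery_pct: float = 0.0
    aa_fluxes: dict[str, float] = field(default_factory=dict)
    cysteine_flux_before: float = 0.0
    cysteine_flux_after: float = 0.0
    synthesizable_fatty_acids: int = 0
    biomass_flux: float = 0.0
    ecdysone_flux: float = 0.0
    backtrack_report: dict[str, dict] = field(default_factory=dict)
    topo: topology.TopoSummary | None = None
    bowtie: topology.BowTiePartition | None = None
    random_cc_range: tuple[float, float] = (0.0, 0.0)
    top_degree_node: str = ""
    partition: netmodules.ModulePartition | None = None
    module_summary: netmodules.ModuleSummary | None = None
    deu_table: Any = None
    deu_total: int = 0
    deu_recovery_pct: float = 0.0
    deu_false_flag_pct: float = 0.0
    overlay: expression.DeuOverlay | None = None
    comparison: compare.ComparisonReport | None = None
    recon: reconstruct.Reconstruction | None = None
    model: cbm.ConstraintModel | None = None
    truth: synthdata.SyntheticTruth | None = None


def _build_network(db, seed: int, coverage: float, n_gaps: int
                   ) -> tuple[reconstruct.Reconstruction, synthdata.SyntheticTruth]:
    unigenes, truth = synthdata.make_annotations(
        db, coverage=coverage, n_gaps=n_gaps, seed=seed)
    recon = reconstruct.draft_from_annotations(unigenes, db)
    reconstruct.unify_chirality(recon)
    return recon, truth


def _exchange_classes(recon, composition, synthesizable_fa=(), extra=None):
    extra = dict(extra or {})
    return cbm.classify_exchanges(recon, composition,
                                  synthesizable_fa=synthesizable_fa,
                                  extra=extra)


def run_pipeline(seed: int = 0, n_gaps: int = 3, de_n: int = 5000,
                 random_reps: int = 100) -> PipelineResult:
    result = PipelineResult(seed=seed)
    db = synthdata.make_refdb(seed)

    # draft + refinement (coverage 1 aside from the held-out bridges, the
    # condition under which planted-gap recovery is exact by construction)
    unigenes, truth = synthdata.make_annotations(
        db, coverage=1.0, n_gaps=n_gaps, seed=seed)
    result.truth = truth
    recon = reconstruct.draft_from_annotations(unigenes, db)
    result.draft_reactions = len(recon.reactions)
    result.draft_metabolites = len(recon.metabolites)
    result.draft_unigenes = len(recon.unigenes)
    result.chirality_reactions_changed = len(reconstruct.unify_chirality(recon))

    # biomass + boundary reactions
    composition = synthdata.make_composition(seed, db=db)
    _, biomass_rxn = biomass.build_biomass_reaction(composition)
    recon.add_reaction(biomass_rxn, provenance="biomass")
    species = sorted({e.metabolite_id for e in composition
                      if e.nutrient_class != "water"}
                     | {"C00001", "C00080", "C00007"})
    result.transport_exchange_added = reconstruct.add_transport_exchange(
        recon, species)

    # gap filling: pathway scale, then global scale
    pathway_fill = gapfill.fill_pathway_scale(recon, db)
    global_fill = gapfill.fill_global_scale(recon, db)
    result.gap = gapfill.merge_results(pathway_fill, global_fill)
    held_out = truth.held_out_gap_reactions
    recovered = held_out & result.gap.added_ids
    result.gap_recovery_pct = 100.0 * len(recovered) / len(held_out) if held_out else 100.0

    # conversion + evaluation
    extra_classes: dict[str, str] = {}
    fa_ids = [e.metabolite_id for e in composition
              if e.nutrient_class == "fatty acid"]

    def build_model() -> cbm.ConstraintModel:
        classes = _exchange_classes(recon, composition,
                                    synthesizable_fa=synthesizable,
                                    extra=extra_classes)
        return cbm.to_constraint_model(recon, exchange_classes=classes)

    synthesizable: frozenset[str] = frozenset()
    model = build_model()
    synthesizable = cbm.detect_synthesizable_fatty_acids(model, fa_ids)
    result.synthesizable_fatty_acids = len(synthesizable)
    model = build_model()

    # non-essential amino acids; on zero flux, backtrack one step and open
    # uptake for blocked substrates (the sulfide case of the cysteine route)
    for aa in sorted(cbm.NONESSENTIAL_AA):
        flux = cbm.check_synthesis(model, aa)
        if aa == "C00097":
            result.cysteine_flux_before = flux
        if flux <= 1e-6:
            blocked = cbm.find_blocked_substrates(recon, aa)
            if blocked:
                reconstruct.add_transport_exchange(recon, blocked,
                                                   provenance="evaluation")
                for met in blocked:
                    extra_classes[met] = "other_nutrient"
                model = build_model()
                flux = cbm.check_synthesis(model, aa)
        result.aa_fluxes[aa] = flux
    result.cysteine_flux_after = result.aa_fluxes["C00097"]

    fba = cbm.fba_maximize(model, "BIOMASS")
    result.biomass_flux = fba.objective_value if fba.ok else 0.0
    if result.biomass_flux <= 1e-6:
        equation, _ = biomass.build_biomass_reaction(composition)
        result.backtrack_report = cbm.backtrack_precursors(
            model, recon, db, biomass.precursor_ids(equation))
    result.ecdysone_flux = cbm.evaluate_ecdysone(model)
    result.recon = recon
    result.model = model

    # topology on the currency-pruned reaction graph
    graph = topology.graph_from_reconstruction(recon)
    result.topo = topology.topo_metrics(graph)
    result.bowtie = topology.bowtie_decompose(graph)
    wcc = topology.biggest_wcc(graph)
    result.random_cc_range = topology.random_cc_ensemble(
        n=len(wcc.nodes), links=wcc.n_links(), reps=random_reps, seed=seed)
    ranking = topology.degree_ranking(wcc)
    result.top_degree_node = ranking[0][0] if ranking else ""

    # module decomposition of the biggest WCC
    result.partition = netmodules.decompose(
        wcc, max_size=MODULE_MAX_SIZE, min_size=MODULE_MIN_SIZE)
    subsystems = {rid: recon.reactions[rid].subsystem for rid in wcc.nodes}
    result.module_summary = netmodules.summarize_modules(
        result.partition, subsystems, wcc)

    # differential expression + overlay
    counts, de_truth = synthdata.make_counts(
        n=de_n, seed=seed, unigene_ids=sorted(recon.unigenes))
    result.truth.planted_de = de_truth.planted_de
    deu = expression.deu_screen(counts)
    result.deu_table = deu
    flagged = set(deu.loc[deu["direction"] != "ns", "unigene"])
    planted = set(de_truth.planted_de)
    nulls = set(counts["unigene"]) - planted
    result.deu_total = len(flagged)
    result.deu_recovery_pct = 100.0 * len(flagged & planted) / len(planted)
    result.deu_false_flag_pct = 100.0 * len(flagged & nulls) / len(nulls)
    result.overlay = expression.map_deus(recon, result.partition, deu)

    # sibling networks for the comparison stage
    recon_b, _ = _build_network(db, synthdata.derive_seed(seed, "network_b"),
                                coverage=0.9, n_gaps=0)
    recon_c, _ = _build_network(db, synthdata.derive_seed(seed, "network_c"),
                                coverage=0.85, n_gaps=0)
    result.comparison = compare.compare_networks(
        {"primary": recon, "sibling_b": recon_b, "sibling_c": recon_c})
    return result
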