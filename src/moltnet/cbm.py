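"""Constraint-based model: bounds policy, FBA, evaluation procedures, SBML.

The reconstruction is converted into a COBRA model with the steady-state
constraint S.v = 0.  Flux bounds are mmol gDW^-1 h^-1 (the biomass flux is
g h^-1, one flux unit producing one gram dry weight).  Exchange fluxes
follow the usual convention: negative flux is uptake, positive is secretion,
so an uptake allowance of 5 appears as a lower bound of -5.

Bounds policy:

======================================  ================
reversible metabolic / transport        (-1000, 1000)
irreversible metabolic                  (0, 1000)
exchange, non-essential amino acid      (0, 1000)
exchange, synthesizable fatty acid      (0, 1000)
exchange, other nutrient                (-5, 1000)
exchange, trace element                 (-1, 1000)
exchange, H2O / H+ / O2                 (-1000, 1000)
======================================  ================

Non-essential amino acids and synthesizable fatty acids must be produced by
the network itself, so their uptake is closed; which fatty acids count as
synthesizable is detected operationally (close every fatty-acid exchange,
then test each one's maximum production).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
from cobra.util.array import create_stoichiometric_matrix

from .biomass import CompositionEntry
from .reconstruct import (Reconstruction, base_id, compartment_of,
                          gpr_to_string, tag)
from .refdb import ReferenceDatabase

logger = logging.getLogger(__name__)

LP_TOLERANCE = 1e-9
SOLVER = "glpk"

#: the ten non-essential amino acids (Ala, Asn, Asp, Cys, Gln, Glu, Gly,
#: Pro, Ser, Tyr)
NONESSENTIAL_AA = frozenset({
    "C00041", "C00152", "C00049", "C00097", "C00064",
    "C00025", "C00037", "C00148", "C00065", "C00082",
})

#: freely exchanged species: water, protons, oxygen
FREE_EXCHANGE = frozenset({"C00001", "C00080", "C00007"})

EXCHANGE_CLASSES = ("nonessential_aa", "synthesizable_fa", "other_nutrient",
                    "trace_element", "free")


class ModelBuildError(ValueError):
    pass


@dataclass(frozen=True)
class BoundsPolicy:
    reversible: tuple[float, float] = (-1000.0, 1000.0)
    irreversible: tuple[float, float] = (0.0, 1000.0)
    transport: tuple[float, float] = (-1000.0, 1000.0)
    exchange: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "nonessential_aa": (0.0, 1000.0),
        "synthesizable_fa": (0.0, 1000.0),
        "other_nutrient": (-5.0, 1000.0),
        "trace_element": (-1.0, 1000.0),
        "free": (-1000.0, 1000.0),
    })


@dataclass
class ConstraintModel:
    model: cobra.Model
    objective_id: str | None = None
    exchange_classes: dict[str, str] = field(default_factory=dict)

    def stoichiometric_matrix(self) -> np.ndarray:
        return create_stoichiometric_matrix(self.model)

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {r.id: (r.lower_bound, r.upper_bound)
                for r in self.model.reactions}


@dataclass
class FBAResult:
    status: str
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def classify_exchanges(
    recon: Reconstruction,
    composition: Sequence[CompositionEntry] = (),
    synthesizable_fa: Iterable[str] = (),
    extra: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Map every exchange reaction's species to a bounds class.

    Classes come from the biomass composition's nutrient classes plus the
    fixed non-essential amino acid and freely-exchanged id sets; ``extra``
    (species id -> class) overrides or supplements.  Any exchange left
    unclassified raises, listing the offending ids.
    """
    by_class = {e.metabolite_id: e.nutrient_class for e in composition}
    synthesizable = set(synthesizable_fa)
    extra = dict(extra or {})
    out: dict[str, str] = {}
    unknown: list[str] = []
    for rid, rxn in sorted(recon.by_category("exchange").items()):
        species = base_id(next(iter(rxn.stoichiometry)))
        if species in extra:
            out[species] = extra[species]
        elif species in FREE_EXCHANGE:
            out[species] = "free"
        elif species in NONESSENTIAL_AA:
            out[species] = "nonessential_aa"
        elif by_class.get(species) == "fatty acid":
            out[species] = ("synthesizable_fa" if species in synthesizable
                            else "other_nutrient")
        elif by_class.get(species) == "trace element":
            out[species] = "trace_element"
        elif species in by_class:
            out[species] = "other_nutrient"
        else:
            unknown.append(rid)
    if unknown:
        raise ModelBuildError(
            "exchange reactions with unknown nutrient class: "
            + ", ".join(unknown))
    return out


def _cobra_metabolite(model: cobra.Model, met_id: str) -> cobra.Metabolite:
    if met_id in model.metabolites:
        return model.metabolites.get_by_id(met_id)
    met = cobra.Metabolite(met_id, compartment=compartment_of(met_id))
    model.add_metabolites([met])
    return met


def to_constraint_model(
    recon: Reconstruction,
    policy: BoundsPolicy = BoundsPolicy(),
    exchange_classes: Mapping[str, str] | None = None,
    objective: str | None = None,
) -> ConstraintModel:
    """Assemble S, bounds and objective from the reconstruction.

    ``exchange_classes`` maps exchanged species ids to a bounds class (see
    :func:`classify_exchanges`).  The biomass reaction, when present, is the
    default objective.
    """
    exchange_classes = dict(exchange_classes or {})
    model = cobra.Model("moltnet")
    model.solver = SOLVER
    biomass_id = None
    cobra_reactions = []
    for rid, rxn in sorted(recon.reactions.items()):
        cr = cobra.Reaction(rid)
        if rxn.category == "biomass":
            biomass_id = rid
            lb, ub = (0.0, 1000.0)
        elif rxn.category == "exchange":
            species = base_id(next(iter(rxn.stoichiometry)))
            if species not in exchange_classes:
                raise ModelBuildError(
                    f"exchange reactions with unknown nutrient class: {rid}")
            lb, ub = policy.exchange[exchange_classes[species]]
        elif rxn.category == "transport":
            lb, ub = policy.transport
        else:
            lb, ub = policy.reversible if rxn.reversible else policy.irreversible
        cobra_reactions.append((cr, rxn, lb, ub))

    model.add_reactions([cr for cr, _, _, _ in cobra_reactions])
    for cr, rxn, lb, ub in cobra_reactions:
        cr.add_metabolites({
            _cobra_metabolite(model, met): coef
            for met, coef in rxn.stoichiometry.items()})
        cr.bounds = (lb, ub)
        if rxn.gpr:
            cr.gene_reaction_rule = gpr_to_string(rxn.gpr)

    cm = ConstraintModel(model=model, objective_id=None,
                         exchange_classes=exchange_classes)
    target = objective or biomass_id
    if target is not None:
        set_objective(cm, target)
    return cm


def set_objective(cm: ConstraintModel, reaction_id: str) -> None:
    if reaction_id not in cm.model.reactions:
        raise ModelBuildError(f"objective {reaction_id} is not a model reaction")
    cm.model.objective = cm.model.reactions.get_by_id(reaction_id)
    cm.model.objective_direction = "max"
    cm.objective_id = reaction_id


def fba_maximize(cm: ConstraintModel, objective: str | None = None) -> FBAResult:
    """Maximize the objective subject to S.v = 0 and bounds.

    Infeasibility is reported through ``status``, never raised."""
    model = cm.model
    if objective is not None and objective != cm.objective_id:
        set_objective(cm, objective)
    solution = model.optimize()
    if solution.status != "optimal":
        return FBAResult(status=solution.status, objective_value=float("nan"))
    return FBAResult(status="optimal",
                     objective_value=float(solution.objective_value),
                     fluxes={r.id: float(solution.fluxes[r.id])
                             for r in model.reactions})


def _ensure_boundary(model: cobra.Model, species: str,
                     exchange_bounds: tuple[float, float]) -> str:
    """Make sure species has transport + exchange reactions; returns the
    exchange id.  Newly added reactions get the requested exchange bounds and
    reversible transport."""
    ex_id, t_id = f"EX_{species}", f"T_{species}"
    e_id, c_id = tag(species, "e"), tag(species, "c")
    if ex_id not in model.reactions:
        if t_id not in model.reactions and c_id in model.metabolites:
            t = cobra.Reaction(t_id)
            model.add_reactions([t])
            t.add_metabolites({_cobra_metabolite(model, e_id): -1.0,
                               model.metabolites.get_by_id(c_id): 1.0})
            t.bounds = (-1000.0, 1000.0)
        ex = cobra.Reaction(ex_id)
        model.add_reactions([ex])
        ex.add_metabolites({_cobra_metabolite(model, e_id): -1.0})
        ex.bounds = exchange_bounds
    return ex_id


def check_synthesis(cm: ConstraintModel, species: str) -> float:
    """Maximum production flux of a species; 0 means not synthesizable.

    The species' exchange reaction is the objective; if absent, transport
    and exchange reactions are added temporarily with exchange bounds
    (0, 1000) so the species may only be produced, never taken up.
    """
    model = cm.model
    c_id, e_id = tag(species, "c"), tag(species, "e")
    if c_id not in model.metabolites and e_id not in model.metabolites:
        raise ModelBuildError(f"metabolite {species} absent from model")
    with model:
        ex_id = _ensure_boundary(model, species, (0.0, 1000.0))
        model.objective = model.reactions.get_by_id(ex_id)
        model.objective_direction = "max"
        solution = model.optimize()
        if solution.status != "optimal":
            return 0.0
        return float(solution.objective_value)


def find_blocked_substrates(recon: Reconstruction, species: str) -> list[str]:
    """Substrates of the species' producing reactions that have no producer
    and no exchange in the reconstruction — the one-step backtracking used
    when an amino acid or biomass precursor cannot be synthesized."""
    producers = []
    produced_by: dict[str, set[str]] = {}
    has_exchange: set[str] = set()
    target = tag(species, "c")
    for rxn in recon.reactions.values():
        if rxn.category == "exchange":
            has_exchange.add(base_id(next(iter(rxn.stoichiometry))))
            continue
        if rxn.category == "biomass":
            continue
        for met, coef in rxn.stoichiometry.items():
            if rxn.reversible or coef > 0:
                produced_by.setdefault(base_id(met), set()).add(rxn.id)
        if target in rxn.stoichiometry and (
                rxn.reversible or rxn.stoichiometry[target] > 0):
            producers.append(rxn)
    blocked: set[str] = set()
    for rxn in producers:
        for met, coef in rxn.stoichiometry.items():
            b = base_id(met)
            if b == species or b in has_exchange:
                continue
            # a reversible producer cannot feed its own substrates: require
            # production by some *other* reaction
            if (rxn.reversible or coef < 0) \
                    and not (produced_by.get(b, set()) - {rxn.id}):
                blocked.add(b)
    return sorted(blocked)


def backtrack_precursors(cm: ConstraintModel, recon: Reconstruction,
                         db: ReferenceDatabase,
                         precursors: Iterable[str]) -> dict[str, dict]:
    """Check synthesis of each biomass precursor and, for the blocked ones,
    list environment reactions able to produce them.

    Each precursor gets a temporary exchange at (0, 1000); candidates are
    ranked by pathway affinity with the reconstruction reactions already
    touching the precursor, then by id."""
    recon_pathways_by_met: dict[str, set[str]] = {}
    for rxn in recon.reactions.values():
        for met in rxn.stoichiometry:
            recon_pathways_by_met.setdefault(base_id(met), set()).add(rxn.pathway_id)

    report: dict[str, dict] = {}
    for species in sorted(set(precursors)):
        flux = check_synthesis(cm, species)
        if flux > LP_TOLERANCE * 1e3:
            continue
        candidates = []
        local_pathways = recon_pathways_by_met.get(species, set())
        for rid, record in db.reactions.items():
            if rid in recon.reactions or species not in record.whole_equation:
                continue
            coef = record.whole_equation[species]
            if record.direction == "reversible" or coef > 0 or (
                    record.direction == "backward" and coef < 0):
                shared = bool(record.pathway_ids & local_pathways)
                candidates.append((0 if shared else 1, rid))
        report[species] = {
            "flux": flux,
            "candidates": [rid for _, rid in sorted(candidates)],
        }
    return report


def evaluate_ecdysone(cm: ConstraintModel, cholesterol: str = "C00187",
                      ecdysone: str = "C02633") -> float:
    """Maximum ecdysone secretion with cholesterol uptake allowed at 5.

    Cholesterol transport/exchange are added at (-5, 1000) (crabs absorb
    cholesterol from feed) and ecdysone transport/exchange at (0, 1000);
    a positive flux means the hormone route is intact.
    """
    model = cm.model
    for species in (cholesterol, ecdysone):
        if tag(species, "c") not in model.metabolites \
                and tag(species, "e") not in model.metabolites:
            raise ModelBuildError(f"metabolite {species} absent from model")
    with model:
        chol_ex = _ensure_boundary(model, cholesterol, (-5.0, 1000.0))
        model.reactions.get_by_id(chol_ex).bounds = (-5.0, 1000.0)
        ecd_ex = _ensure_boundary(model, ecdysone, (0.0, 1000.0))
        model.objective = model.reactions.get_by_id(ecd_ex)
        model.objective_direction = "max"
        solution = model.optimize()
        if solution.status != "optimal":
            return 0.0
        return float(solution.objective_value)


def detect_synthesizable_fatty_acids(cm: ConstraintModel,
                                     fatty_acids: Iterable[str]) -> frozenset[str]:
    """Close every fatty-acid exchange, then test each acid's production."""
    fatty_acids = sorted(set(fatty_acids))
    model = cm.model
    with model:
        for fa in fatty_acids:
            ex_id = f"EX_{fa}"
            if ex_id in model.reactions:
                ex = model.reactions.get_by_id(ex_id)
                ex.lower_bound = max(ex.lower_bound, 0.0)
        synthesizable = {fa for fa in fatty_acids
                         if tag(fa, "c") in model.metabolites
                         and check_synthesis(cm, fa) > 1e-6}
    return frozenset(synthesizable)


def export_sbml(cm: ConstraintModel, path: str | Path) -> None:
    """Write SBML Level 3 (fbc): compartments c/e, bounds, GPR annotations."""
    if len(cm.model.reactions) == 0:
        raise ModelBuildError("refusing to export an empty model")
    cobra.io.write_sbml_model(cm.model, str(path))


def load_sbml(path: str | Path) -> ConstraintModel:
    model = cobra.io.read_sbml_model(str(path))
    model.solver = SOLVER
    objective_ids = [r.id for r in model.reactions
                     if r.objective_coefficient not in (0, 0.0)]
    return ConstraintModel(model=model,
                           objective_id=objective_ids[0] if objective_ids else None)


def steady_state_residual(cm: ConstraintModel, fluxes: Mapping[str, float]) -> float:
    """max |S.v| over metabolites, for verifying reported flux vectors."""
    S = cm.stoichiometric_matrix()
    v = np.array([fluxes[r.id] for r in cm.model.reactions])
    return float(np.max(np.abs(S @ v))) if S.size else 0.0
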