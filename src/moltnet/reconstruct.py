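"""Draft network assembly from unigene-KO annotations and refinement rules.

The draft network is the union, over all annotated KO identifiers, of the
reference reactions those KOs map to.  Refinement covers: unifying chiral
metabolite variants, assigning exactly one pathway/subsystem per reaction,
building gene-protein-reaction (GPR) rules through the unigene-KO-enzyme
chain, adding transport/exchange reactions for biomass species, and
confidence scoring.

Compartments: all metabolic reactions are cytoplasmic; metabolite ids carry
a ``_c`` (cytoplasm) or ``_e`` (extracellular) suffix.  A GPR is stored as
an OR-of-AND-groups: a tuple of frozensets of unigene ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import refdb
from .refdb import BACKWARD, REVERSIBLE, ReactionRecord, ReferenceDatabase

logger = logging.getLogger(__name__)

Gpr = tuple[frozenset[str], ...]

CATEGORIES = ("metabolic", "transport", "exchange", "biomass")

#: provenance tag -> confidence score (0-4 scale: 4 biochemical, 3 genetic,
#: 2 physiological/sequence, 1 modeling-needed, 0 none)
CONFIDENCE_BY_PROVENANCE = {
    "draft": 2,        # sequence evidence
    "reference": 2,    # curated equations imported from sibling networks
    "transport": 2,    # physiological: nutrient requirement
    "exchange": 2,
    "evaluation": 2,   # needed for biomass / hormone synthesis
    "biomass": 2,
    "gap": 1,          # connectivity only, no direct evidence
}

#: overview/global KEGG maps are never chosen as a reaction's single pathway
GLOBAL_MAP_PREFIXES = ("011",)

#: default chirality unification (the glucose class): variants of D-glucose
#: resolve to the alpha anomer, the predominant cellular form
DEFAULT_CHIRALITY_RULES = {"C00031": "C00267", "C00221": "C00267"}


class ReconstructionError(ValueError):
    pass


def tag(met: str, compartment: str = "c") -> str:
    return f"{met}_{compartment}"


def base_id(tagged: str) -> str:
    return tagged.rsplit("_", 1)[0] if tagged.endswith(("_c", "_e")) else tagged


def compartment_of(tagged: str) -> str:
    return tagged.rsplit("_", 1)[1] if tagged.endswith(("_c", "_e")) else "c"


@dataclass
class NetworkReaction:
    """One reaction of the evolving reconstruction.

    ``stoichiometry`` is forward-signed over compartment-tagged metabolite
    ids; a backward-only reference direction is normalised at draft time by
    negating the coefficients, so ``reversible=False`` always means
    "proceeds left to right as stored".
    """

    id: str
    stoichiometry: dict[str, float]
    main_stoichiometry: dict[str, float]
    reversible: bool
    category: str = "metabolic"
    gpr: Gpr = ()
    pathway_id: str = "unassigned"
    subsystem: str = "unassigned"
    confidence: int = 2

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown reaction category {self.category!r}")
        if not 0 <= self.confidence <= 4:
            raise ValueError("confidence must be within 0..4")


@dataclass
class Reconstruction:
    reactions: dict[str, NetworkReaction] = field(default_factory=dict)
    unigenes: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    degenerate: set[str] = field(default_factory=set)

    def add_reaction(self, rxn: NetworkReaction, provenance: str) -> None:
        if rxn.id in self.reactions:
            raise ReconstructionError(f"reaction {rxn.id} already present")
        rxn.confidence = score_confidence(provenance)
        self.reactions[rxn.id] = rxn
        self.provenance[rxn.id] = provenance

    @property
    def metabolites(self) -> dict[str, set[str]]:
        """Base metabolite id -> set of compartments it occurs in."""
        out: dict[str, set[str]] = {}
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                out.setdefault(base_id(met), set()).add(compartment_of(met))
        return out

    def by_category(self, category: str) -> dict[str, NetworkReaction]:
        return {rid: r for rid, r in self.reactions.items()
                if r.category == category}

    def gene_ids(self) -> frozenset[str]:
        """Unigenes that actually appear in a GPR."""
        leaves: set[str] = set()
        for rxn in self.reactions.values():
            leaves |= gpr_leaves(rxn.gpr)
        return frozenset(leaves)

    def feature_counts(self) -> dict[str, int]:
        mets = self.metabolites
        comps: dict[str, int] = {"c": 0, "e": 0}
        for compartments in mets.values():
            for comp in compartments:
                comps[comp] = comps.get(comp, 0) + 1
        pathways = {r.pathway_id for r in self.reactions.values()
                    if r.category == "metabolic" and r.pathway_id != "unassigned"}
        subsystems = {r.subsystem for r in self.reactions.values()
                      if r.category == "metabolic" and r.subsystem != "unassigned"}
        return {
            "genes": len(self.gene_ids()),
            "reactions": len(self.reactions),
            "metabolic_reactions": len(self.by_category("metabolic")),
            "transport_reactions": len(self.by_category("transport")),
            "exchange_reactions": len(self.by_category("exchange")),
            "metabolites": len(mets),
            "intracellular_metabolites": comps.get("c", 0),
            "extracellular_metabolites": comps.get("e", 0),
            "pathways": len(pathways),
            "subsystems": len(subsystems),
        }


def gpr_to_string(gpr: Gpr) -> str:
    if not gpr:
        return ""
    groups = []
    for group in gpr:
        inner = " and ".join(sorted(group))
        groups.append(f"({inner})" if len(group) > 1 else inner)
    return " or ".join(groups)


def gpr_leaves(gpr: Gpr) -> frozenset[str]:
    out: set[str] = set()
    for group in gpr:
        out |= group
    return frozenset(out)


def score_confidence(provenance: str) -> int:
    try:
        return CONFIDENCE_BY_PROVENANCE[provenance]
    except KeyError:
        raise ReconstructionError(f"unknown provenance tag {provenance!r}") from None


def assign_pathway(record: ReactionRecord, db: ReferenceDatabase) -> tuple[str, str]:
    """Pick the single pathway: smallest numeric metabolic map id.

    Overview/global maps (011xx) are excluded; candidates must have a
    subsystem entry.  With no eligible pathway the sentinel "unassigned" is
    returned and logged.
    """
    def sort_key(pid: str):
        return (0, int(pid)) if pid.isdigit() else (1, pid)

    candidates = [pid for pid in record.pathway_ids
                  if not pid.startswith(GLOBAL_MAP_PREFIXES)
                  and pid in db.pathway_to_subsystem]
    if not candidates:
        logger.info("reaction %s has no eligible pathway", record.id)
        return "unassigned", "unassigned"
    chosen = min(candidates, key=sort_key)
    return chosen, db.pathway_to_subsystem[chosen]


def build_gpr(record: ReactionRecord, db: ReferenceDatabase,
              unigenes: Mapping[str, frozenset[str]]) -> Gpr:
    """GPR = OR over enzymes of (AND over unigenes matching that enzyme).

    Enzymes are the reaction's EC numbers; unigenes reach an enzyme through
    shared KO identifiers.  KOs of the reaction not covered by any EC act as
    singleton enzyme units so annotation without EC linkage still yields a
    rule.  Enzymes with no matched unigene are omitted; an empty result
    means "no GPR", which is legal.
    """
    enzyme_kos: list[frozenset[str]] = []
    covered: set[str] = set()
    for ec in sorted(record.ec_set):
        kos = db.ec_to_ko.get(ec, frozenset()) & record.ko_set
        if kos:
            enzyme_kos.append(kos)
            covered |= kos
    for ko in sorted(record.ko_set - covered):
        enzyme_kos.append(frozenset({ko}))

    groups: set[frozenset[str]] = set()
    for kos in enzyme_kos:
        members = frozenset(u for u, uko in unigenes.items() if uko & kos)
        if members:
            groups.add(members)
    return tuple(sorted(groups, key=lambda g: sorted(g)))


def reaction_from_record(record: ReactionRecord, db: ReferenceDatabase,
                         gpr: Gpr = ()) -> NetworkReaction:
    """Instantiate a cytoplasmic network reaction from a reference record."""
    sign = -1.0 if record.direction == BACKWARD else 1.0
    stoich = {tag(m): sign * c for m, c in record.whole_equation.items()}
    main = {tag(m): sign * c for m, c in record.main_equation.items()}
    pathway, subsystem = assign_pathway(record, db)
    return NetworkReaction(
        id=record.id,
        stoichiometry=stoich,
        main_stoichiometry=main,
        reversible=record.direction == REVERSIBLE,
        category="metabolic",
        gpr=gpr,
        pathway_id=pathway,
        subsystem=subsystem,
    )


def draft_from_annotations(unigenes: Mapping[str, Iterable[str]],
                           db: ReferenceDatabase) -> Reconstruction:
    """KO-bridged draft: the union of reference reactions over all KOs.

    Unigenes are retained only if at least one of their KOs matched a
    reaction; metabolites are those of the included reactions.
    """
    normalized = {u: frozenset(kos) for u, kos in unigenes.items()}
    reaction_ids: set[str] = set()
    kept: dict[str, frozenset[str]] = {}
    for uid in sorted(normalized):
        hits: set[str] = set()
        for ko in normalized[uid]:
            hits |= db.reactions_for_ko(ko)
        if hits:
            kept[uid] = normalized[uid]
            reaction_ids |= hits
    if not reaction_ids:
        raise ReconstructionError("no annotated metabolism")

    recon = Reconstruction(unigenes=kept)
    for rid in sorted(reaction_ids):
        record = db.reactions[rid]
        rxn = reaction_from_record(record, db, gpr=build_gpr(record, db, kept))
        recon.add_reaction(rxn, provenance="draft")
    return recon


def unify_chirality(recon: Reconstruction,
                    rules: Mapping[str, str] = DEFAULT_CHIRALITY_RULES
                    ) -> list[str]:
    """Replace chiral variant metabolite ids with the canonical form.

    Returns the ids of the reactions that changed.  A reaction whose two
    sides collapse onto the canonical id at equal coefficient is flagged
    degenerate (it carries no net transformation afterwards).
    """
    for variant, canonical in rules.items():
        target = rules.get(canonical, canonical)
        if target != canonical:
            raise ReconstructionError(
                f"chirality rule chain: {variant} -> {canonical} -> {target}")

    changed: list[str] = []
    for rid, rxn in recon.reactions.items():
        touched = False
        for attr in ("stoichiometry", "main_stoichiometry"):
            eq: dict[str, float] = getattr(rxn, attr)
            new: dict[str, float] = {}
            for met, coef in eq.items():
                b, comp = base_id(met), compartment_of(met)
                nb = rules.get(b, b)
                if nb != b:
                    touched = True
                new_met = tag(nb, comp)
                new[new_met] = new.get(new_met, 0.0) + coef
            cancelled = {m for m, c in new.items() if c == 0.0}
            if cancelled and attr == "stoichiometry":
                recon.degenerate.add(rid)
            setattr(rxn, attr, {m: c for m, c in new.items() if c != 0.0})
        if touched:
            changed.append(rid)
    return changed


def apply_reference_overrides(
    recon: Reconstruction,
    overrides: Mapping[str, tuple[Mapping[str, float], str]],
) -> list[str]:
    """Replace equations/directions of reactions present in a curated prior
    network.  ``overrides`` maps reaction id -> (signed whole equation over
    bare compound ids, direction).  Applied only to reactions already in the
    reconstruction; returns the ids that changed."""
    applied = []
    for rid, (equation, direction) in overrides.items():
        if rid not in recon.reactions:
            continue
        rxn = recon.reactions[rid]
        sign = -1.0 if direction == BACKWARD else 1.0
        rxn.stoichiometry = {tag(m): sign * c for m, c in equation.items()}
        rxn.main_stoichiometry = {
            m: c for m, c in rxn.stoichiometry.items()
            if base_id(m) in {base_id(k) for k in rxn.main_stoichiometry}
        } or dict(rxn.stoichiometry)
        rxn.reversible = direction == REVERSIBLE
        recon.provenance[rid] = "reference"
        applied.append(rid)
    return applied


def add_transport_exchange(recon: Reconstruction, species: Iterable[str],
                           provenance: str | None = None) -> int:
    """Add one transport (X_e <-> X_c) and one exchange (X_e <->) per species.

    Existing transport/exchange reactions for a species are skipped (logged),
    so the call is idempotent.  Returns the number of reactions added.
    """
    added = 0
    for met in species:
        t_id, ex_id = f"T_{met}", f"EX_{met}"
        for rid, stoich, category in (
            (t_id, {tag(met, "e"): -1.0, tag(met, "c"): 1.0}, "transport"),
            (ex_id, {tag(met, "e"): -1.0}, "exchange"),
        ):
            if rid in recon.reactions:
                logger.info("%s already present; skipped", rid)
                continue
            rxn = NetworkReaction(
                id=rid,
                stoichiometry=dict(stoich),
                main_stoichiometry=dict(stoich),
                reversible=True,
                category=category,
                pathway_id=category,
                subsystem="Transport",
            )
            recon.add_reaction(rxn, provenance=provenance or category)
            added += 1
    return added


def read_annotation_table(text: str) -> dict[str, frozenset[str]]:
    """Parse a unigene-KO TSV: ``unigene_id<TAB>KO[;KO...]`` (KO field may
    be empty for unannotated unigenes)."""
    out: dict[str, frozenset[str]] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        uid = cols[0].strip()
        if uid in out:
            raise refdb.ParseError(f"line {line_no}: duplicate unigene id {uid}")
        kos = frozenset(k for k in (cols[1].split(";") if len(cols) > 1 else [])
                        if k.strip())
        out[uid] = kos
    return out
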