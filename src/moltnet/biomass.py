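"""Biomass reaction construction from a measured cellular composition.

A composition table lists nutrient contents per 100 g wet cells (g/100g, or
mg/kg for trace-level entries).  The water entry fixes the dry weight; every
other entry is converted to mmol per gram dry weight and becomes a precursor
coefficient of the biomass pseudo-reaction.  Growth-associated ATP
maintenance (ATP + H2O -> ADP + Pi) is embedded at a fixed coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .reconstruct import NetworkReaction, tag

NUTRIENT_CLASSES = ("amino acid", "fatty acid", "trace element",
                    "carbohydrate", "nucleotide", "water")

ATP, ADP, PHOSPHATE, WATER = "C00002", "C00008", "C00009", "C00001"

#: growth-associated maintenance, mmol ATP per g dry weight (iCHOv1-style)
DEFAULT_ATP_MAINTENANCE = 29.8303


class BiomassError(ValueError):
    pass


@dataclass
class CompositionEntry:
    name: str
    nutrient_class: str
    content: float            # g/100 g wet cells, or mg/kg wet cells
    unit: str                 # "g/100g" | "mg/kg"
    metabolite_id: str
    molar_mass: float | None  # g/mol; required for non-water entries

    def __post_init__(self) -> None:
        if self.nutrient_class not in NUTRIENT_CLASSES:
            raise BiomassError(f"unknown nutrient class {self.nutrient_class!r}")
        if self.unit not in ("g/100g", "mg/kg"):
            raise BiomassError(f"unknown unit {self.unit!r} for {self.name}")
        if self.content < 0:
            raise BiomassError(f"negative content for {self.name}")


@dataclass
class BiomassEquation:
    coefficients: dict[str, float] = field(default_factory=dict)
    atp_maintenance: float = DEFAULT_ATP_MAINTENANCE


def dry_weight(entries: Sequence[CompositionEntry]) -> float:
    """Grams of dry mass per 100 g wet cells: 100 minus the water content."""
    waters = [e for e in entries if e.nutrient_class == "water"]
    if len(waters) != 1:
        raise BiomassError(f"expected exactly one water entry, found {len(waters)}")
    water = waters[0]
    if water.unit != "g/100g":
        raise BiomassError("water content must be given in g/100g")
    dw = 100.0 - water.content
    if dw <= 0:
        raise BiomassError("no dry mass: water content >= 100 g/100g")
    return dw


def to_coefficient(entry: CompositionEntry, dw: float) -> float:
    """Convert one content entry to mmol per g dry weight.

    g/100g: (content / molar_mass) * 1000 / dry_weight.
    mg/kg : equals content * 1e-4 g/100g, then the same conversion.
    """
    if dw <= 0:
        raise BiomassError("dry weight must be positive")
    if entry.content == 0:
        return 0.0
    if entry.molar_mass is None or entry.molar_mass <= 0:
        raise BiomassError(f"missing molar mass for entry {entry.name!r}")
    grams_per_100g = entry.content * 1e-4 if entry.unit == "mg/kg" else entry.content
    return grams_per_100g / entry.molar_mass * 1000.0 / dw


def build_biomass_reaction(
    entries: Sequence[CompositionEntry],
    atp_maintenance: float = DEFAULT_ATP_MAINTENANCE,
    reaction_id: str = "BIOMASS",
) -> tuple[BiomassEquation, NetworkReaction]:
    """Assemble the biomass pseudo-reaction.

    Precursors are consumed (negative coefficients, mmol/gDW); the ATP
    maintenance term consumes ATP and water and produces ADP and phosphate
    at ``atp_maintenance``.  One flux unit produces one gram of dry biomass.
    """
    dw = dry_weight(entries)
    coefficients: dict[str, float] = {}
    for entry in entries:
        if entry.nutrient_class == "water":
            continue
        coef = to_coefficient(entry, dw)
        if coef == 0.0:
            continue
        coefficients[entry.metabolite_id] = (
            coefficients.get(entry.metabolite_id, 0.0) - coef)

    stoich = {tag(met): c for met, c in coefficients.items()}
    if atp_maintenance:
        for met, sign in ((ATP, -1.0), (WATER, -1.0), (ADP, 1.0), (PHOSPHATE, 1.0)):
            key = tag(met)
            stoich[key] = stoich.get(key, 0.0) + sign * atp_maintenance

    equation = BiomassEquation(coefficients=coefficients,
                               atp_maintenance=atp_maintenance)
    reaction = NetworkReaction(
        id=reaction_id,
        stoichiometry=stoich,
        main_stoichiometry=dict(stoich),
        reversible=False,
        category="biomass",
        pathway_id="biomass",
        subsystem="Biomass",
    )
    return equation, reaction


def precursor_ids(equation: BiomassEquation) -> list[str]:
    return sorted(equation.coefficients)


# ---------------------------------------------------------------------------
# TSV I/O: name, nutrient_class, content, unit, metabolite_id, molar_mass

HEADER = "name\tnutrient_class\tcontent\tunit\tmetabolite_id\tmolar_mass"


def read_composition(text: str) -> list[CompositionEntry]:
    entries = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith(("#", "name\t")):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) != 6:
            raise BiomassError(f"line {line_no}: expected 6 columns")
        name, klass, content, unit, met, mass = cols
        entries.append(CompositionEntry(
            name=name, nutrient_class=klass, content=float(content),
            unit=unit, metabolite_id=met,
            molar_mass=float(mass) if mass.strip() else None))
    return entries


def write_composition(entries: Iterable[CompositionEntry], path: str | Path) -> None:
    lines = [HEADER]
    for e in entries:
        mass = "" if e.molar_mass is None else repr(e.molar_mass)
        lines.append(f"{e.name}\t{e.nutrient_class}\t{e.content!r}\t{e.unit}"
                     f"\t{e.metabolite_id}\t{mass}")
    Path(path).write_text("\n".join(lines) + "\n")
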