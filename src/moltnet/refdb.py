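"""KEGG-style reference database: flat-file parsing and cross-indexing.

The reference database drives the draft reconstruction (unigene -> KO ->
reaction) and supplies the "metabolic environment" for gap filling.  It is
read from five flat files in a fixed dialect:

``reactions.txt``
    One reaction per line: ``R00001: C00001 + 2 C00002 <=> C00003``.
    Stoichiometric multipliers may be integers or decimals.  Directions are
    *not* encoded here; they come from the mapformula file.
``mapformula.txt``
    Per-pathway main equations with directions:
    ``R00001: 00010: C00001 => C00003`` (arrows ``=>``, ``<=``, ``<=>``).
``metabolites.tsv``
    ``id<TAB>name<TAB>molar_mass<TAB>chirality_class`` (last two may be empty).
``ko_reactions.tsv``
    ``KO<TAB>reaction_id`` pairs.
``ec_ko.tsv``
    ``EC<TAB>KO`` pairs.
``pathway_subsystems.tsv``
    ``map_id<TAB>subsystem``.

Real KEGG flat files vary in format; the dialect above is fixed so that
generated fixtures parse deterministically and round-trip exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

FORWARD = "forward"
BACKWARD = "backward"
REVERSIBLE = "reversible"

_ARROWS = {"<=>": REVERSIBLE, "=>": FORWARD, "<=": BACKWARD}
_TOKEN_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")


class ParseError(ValueError):
    """Raised for malformed flat-file input; message names the line."""


@dataclass
class MetaboliteRecord:
    id: str
    name: str = ""
    molar_mass: float | None = None
    chirality_class: str | None = None

    def __post_init__(self) -> None:
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise ValueError(f"molar mass of {self.id} must be positive")


@dataclass
class ReactionRecord:
    """A reference reaction with signed stoichiometry.

    ``whole_equation`` maps metabolite id -> signed coefficient (substrates
    negative, products positive).  ``main_equation`` is the restriction to
    the main metabolites named in the pathway map; ``direction`` is the
    merged per-pathway direction.
    """

    id: str
    whole_equation: dict[str, float]
    main_equation: dict[str, float] = field(default_factory=dict)
    direction: str = REVERSIBLE
    ko_set: frozenset[str] = frozenset()
    ec_set: frozenset[str] = frozenset()
    pathway_ids: frozenset[str] = frozenset()


@dataclass
class MapformulaEntry:
    reaction_id: str
    pathway_id: str
    stoichiometry: dict[str, float]  # left side negative, as written
    direction: str


@dataclass
class ReferenceDatabase:
    metabolites: dict[str, MetaboliteRecord]
    reactions: dict[str, ReactionRecord]
    ko_to_reactions: dict[str, frozenset[str]]
    ec_to_ko: dict[str, frozenset[str]]
    pathway_to_subsystem: dict[str, str]
    flagged_pathways: frozenset[str] = frozenset()
    warnings: list[str] = field(default_factory=list, compare=False)

    def reactions_for_ko(self, ko: str) -> frozenset[str]:
        return self.ko_to_reactions.get(ko, frozenset())


def _parse_side(side: str, line_no: int) -> dict[str, float]:
    out: dict[str, float] = {}
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ParseError(f"line {line_no}: empty term in equation")
        parts = term.split()
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError:
                raise ParseError(
                    f"line {line_no}: bad stoichiometric multiplier {parts[0]!r}"
                ) from None
            met = parts[1]
        else:
            raise ParseError(f"line {line_no}: unparseable term {term!r}")
        if coef <= 0:
            raise ParseError(f"line {line_no}: non-positive multiplier in {term!r}")
        if not _TOKEN_RE.match(met):
            raise ParseError(f"line {line_no}: unknown token {met!r}")
        out[met] = out.get(met, 0.0) + coef
    return out


def _signed(lhs: dict[str, float], rhs: dict[str, float], line_no: int,
            rid: str) -> dict[str, float]:
    eq: dict[str, float] = {}
    for met, c in lhs.items():
        eq[met] = eq.get(met, 0.0) - c
    for met, c in rhs.items():
        eq[met] = eq.get(met, 0.0) + c
    for met in set(lhs) & set(rhs):
        if eq[met] == 0.0:
            raise ParseError(
                f"line {line_no}: metabolite {met} cancels on both sides of {rid}"
            )
    return eq


def parse_reaction_list(text: str) -> dict[str, ReactionRecord]:
    """Parse the reaction list; directions remain unset (reversible)."""
    records: dict[str, ReactionRecord] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ": " not in line:
            raise ParseError(f"line {line_no}: missing 'RID: ' separator")
        rid, eq_text = line.split(": ", 1)
        rid = rid.strip()
        if not _TOKEN_RE.match(rid):
            raise ParseError(f"line {line_no}: bad reaction id {rid!r}")
        if rid in records:
            raise ParseError(f"line {line_no}: duplicate reaction id {rid}")
        if "<=>" not in eq_text:
            raise ParseError(f"line {line_no}: missing '<=>' arrow")
        left, right = eq_text.split("<=>", 1)
        eq = _signed(_parse_side(left, line_no), _parse_side(right, line_no),
                     line_no, rid)
        if not eq:
            raise ParseError(f"line {line_no}: empty equation for {rid}")
        records[rid] = ReactionRecord(id=rid, whole_equation=eq)
    return records


def parse_mapformula(text: str) -> list[MapformulaEntry]:
    """Parse per-pathway main equations: ``RID: MAPID: A + B => C``."""
    entries: list[MapformulaEntry] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(": ", 2)
        if len(parts) != 3:
            raise ParseError(f"line {line_no}: expected 'RID: MAPID: equation'")
        rid, map_id, eq_text = (p.strip() for p in parts)
        arrow = None
        for candidate in ("<=>", "=>", "<="):  # longest first
            if candidate in eq_text:
                arrow = candidate
                break
        if arrow is None:
            raise ParseError(f"line {line_no}: no direction arrow found")
        left, right = eq_text.split(arrow, 1)
        eq = _signed(_parse_side(left, line_no), _parse_side(right, line_no),
                     line_no, rid)
        entries.append(MapformulaEntry(rid, map_id, eq, _ARROWS[arrow]))
    return entries


def merge_directions(directions: Iterable[str]) -> str:
    """Merge per-pathway directions: any conflict or '<=>' -> reversible."""
    seen = set(directions)
    if not seen:
        return REVERSIBLE
    if REVERSIBLE in seen or len(seen) > 1:
        return REVERSIBLE
    return seen.pop()


def parse_metabolite_list(text: str) -> dict[str, MetaboliteRecord]:
    records: dict[str, MetaboliteRecord] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise ParseError(f"line {line_no}: expected at least id and name")
        cid, name = cols[0].strip(), cols[1].strip()
        if cid in records:
            raise ParseError(f"line {line_no}: duplicate metabolite id {cid}")
        mass = float(cols[2]) if len(cols) > 2 and cols[2].strip() else None
        chir = cols[3].strip() if len(cols) > 3 and cols[3].strip() else None
        records[cid] = MetaboliteRecord(cid, name, mass, chir)
    return records


def parse_pairs(text: str) -> list[tuple[str, str]]:
    """Parse two-column TSV (KO links, EC links, pathway subsystems)."""
    pairs = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) != 2:
            raise ParseError(f"line {line_no}: expected two tab-separated columns")
        pairs.append((cols[0].strip(), cols[1].strip()))
    return pairs


def build_indexes(
    metabolites: Mapping[str, MetaboliteRecord],
    reactions: Mapping[str, ReactionRecord],
    mapformula: Iterable[MapformulaEntry],
    ko_links: Iterable[tuple[str, str]],
    ec_links: Iterable[tuple[str, str]],
    pathway_subsystems: Mapping[str, str],
) -> ReferenceDatabase:
    """Assemble all cross-indexes into a consistent ReferenceDatabase.

    KO links to unknown reaction ids are skipped with a warning.  Reactions
    absent from the mapformula get ``main_equation == whole_equation`` and a
    reversible direction.  Pathway ids with no subsystem entry are flagged.
    """
    warnings: list[str] = []
    reactions = {rid: ReactionRecord(
        id=rec.id, whole_equation=dict(rec.whole_equation))
        for rid, rec in reactions.items()}

    per_reaction: dict[str, list[MapformulaEntry]] = {}
    for entry in mapformula:
        if entry.reaction_id not in reactions:
            msg = f"mapformula references unknown reaction {entry.reaction_id}"
            logger.warning(msg)
            warnings.append(msg)
            continue
        per_reaction.setdefault(entry.reaction_id, []).append(entry)

    for rid, rec in reactions.items():
        entries = per_reaction.get(rid)
        if not entries:
            rec.main_equation = dict(rec.whole_equation)
            rec.direction = REVERSIBLE
            rec.pathway_ids = frozenset()
            continue
        main_mets = set()
        for e in entries:
            for met in e.stoichiometry:
                if met not in rec.whole_equation:
                    msg = (f"main-equation metabolite {met} of {rid} not in "
                           f"whole equation; ignored")
                    logger.warning(msg)
                    warnings.append(msg)
                else:
                    main_mets.add(met)
        rec.main_equation = {m: rec.whole_equation[m] for m in sorted(main_mets)}
        rec.direction = merge_directions(e.direction for e in entries)
        rec.pathway_ids = frozenset(e.pathway_id for e in entries)

    ko_to_reactions: dict[str, set[str]] = {}
    for ko, rid in ko_links:
        if rid not in reactions:
            msg = f"KO link {ko} -> {rid} skipped: unknown reaction id"
            logger.warning(msg)
            warnings.append(msg)
            continue
        ko_to_reactions.setdefault(ko, set()).add(rid)

    reaction_kos: dict[str, set[str]] = {}
    for ko, rids in ko_to_reactions.items():
        for rid in rids:
            reaction_kos.setdefault(rid, set()).add(ko)

    ec_to_ko: dict[str, set[str]] = {}
    for ec, ko in ec_links:
        ec_to_ko.setdefault(ec, set()).add(ko)

    for rid, rec in reactions.items():
        kos = frozenset(reaction_kos.get(rid, set()))
        rec.ko_set = kos
        rec.ec_set = frozenset(
            ec for ec, ko_ids in ec_to_ko.items() if ko_ids & kos)

    flagged = set()
    for rec in reactions.values():
        for pid in rec.pathway_ids:
            if pid not in pathway_subsystems:
                flagged.add(pid)
    for pid in sorted(flagged):
        msg = f"pathway {pid} has no subsystem entry"
        logger.warning(msg)
        warnings.append(msg)

    return ReferenceDatabase(
        metabolites=dict(metabolites),
        reactions=reactions,
        ko_to_reactions={k: frozenset(v) for k, v in ko_to_reactions.items()},
        ec_to_ko={k: frozenset(v) for k, v in ec_to_ko.items()},
        pathway_to_subsystem=dict(pathway_subsystems),
        flagged_pathways=frozenset(flagged),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# directory round-trip

FILENAMES = {
    "reactions": "reactions.txt",
    "mapformula": "mapformula.txt",
    "metabolites": "metabolites.tsv",
    "ko": "ko_reactions.tsv",
    "ec": "ec_ko.tsv",
    "pathways": "pathway_subsystems.tsv",
}


def _fmt_coef(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(c)


def format_equation(eq: Mapping[str, float], arrow: str = "<=>") -> str:
    lhs = [f"{_fmt_coef(-c)} {m}" if -c != 1 else m
           for m, c in sorted(eq.items()) if c < 0]
    rhs = [f"{_fmt_coef(c)} {m}" if c != 1 else m
           for m, c in sorted(eq.items()) if c > 0]
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}"


def serialize_reference_database(db: ReferenceDatabase, outdir: str | Path) -> None:
    """Write the six flat files; ``load_reference_database`` reads them back."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrow_of = {FORWARD: "=>", BACKWARD: "<=", REVERSIBLE: "<=>"}

    lines = [f"{rid}: {format_equation(rec.whole_equation)}"
             for rid, rec in sorted(db.reactions.items())]
    (outdir / FILENAMES["reactions"]).write_text("\n".join(lines) + "\n")

    mf_lines = []
    for rid, rec in sorted(db.reactions.items()):
        if not rec.pathway_ids:
            continue
        arrow = arrow_of[rec.direction]
        eq = format_equation(rec.main_equation, arrow)
        for pid in sorted(rec.pathway_ids):
            mf_lines.append(f"{rid}: {pid}: {eq}")
    (outdir / FILENAMES["mapformula"]).write_text("\n".join(mf_lines) + "\n")

    met_lines = []
    for cid, m in sorted(db.metabolites.items()):
        mass = "" if m.molar_mass is None else repr(m.molar_mass)
        chir = m.chirality_class or ""
        met_lines.append(f"{cid}\t{m.name}\t{mass}\t{chir}")
    (outdir / FILENAMES["metabolites"]).write_text("\n".join(met_lines) + "\n")

    ko_lines = [f"{ko}\t{rid}"
                for ko, rids in sorted(db.ko_to_reactions.items())
                for rid in sorted(rids)]
    (outdir / FILENAMES["ko"]).write_text("\n".join(ko_lines) + "\n")

    ec_lines = [f"{ec}\t{ko}"
                for ec, kos in sorted(db.ec_to_ko.items())
                for ko in sorted(kos)]
    (outdir / FILENAMES["ec"]).write_text("\n".join(ec_lines) + "\n")

    pw_lines = [f"{pid}\t{sub}"
                for pid, sub in sorted(db.pathway_to_subsystem.items())]
    (outdir / FILENAMES["pathways"]).write_text("\n".join(pw_lines) + "\n")


def load_reference_database(indir: str | Path) -> ReferenceDatabase:
    indir = Path(indir)
    reactions = parse_reaction_list((indir / FILENAMES["reactions"]).read_text())
    mapformula = parse_mapformula((indir / FILENAMES["mapformula"]).read_text())
    metabolites = parse_metabolite_list((indir / FILENAMES["metabolites"]).read_text())
    ko_links = parse_pairs((indir / FILENAMES["ko"]).read_text())
    ec_links = parse_pairs((indir / FILENAMES["ec"]).read_text())
    pathway_subsystems = dict(parse_pairs((indir / FILENAMES["pathways"]).read_text()))
    return build_indexes(metabolites, reactions, mapformula, ko_links,
                         ec_links, pathway_subsystems)
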