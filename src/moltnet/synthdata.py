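"""Synthetic fixtures: a toy reference database with KEGG-like structure,
unigene annotations with planted gaps, two-condition count tables with
planted differential expression, and a mass-closed composition table.

The generated world is small (~60 reactions across five pathways) but keeps
the features every pipeline stage needs: a glycolysis-like backbone with
currency cofactors woven in, a ten-amino-acid block (the non-essential set,
including a sulfide-dependent cysteine synthesis), an elongating fatty-acid
chain, a five-step cholesterol-to-ecdysone hormone route, a small nucleotide
branch, and glucose anomers for the chirality rules.  Every fixture carries
its ground truth (held-out gap reactions, planted DE unigenes) so recovery
tests never guess.

A single global seed fans out to per-fixture seeds through
:func:`derive_seed`, so any stage is regenerable in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import refdb as rdb
from .biomass import CompositionEntry, write_composition
from .gapfill import DEFAULT_CURRENCY
from .refdb import (FORWARD, REVERSIBLE, MetaboliteRecord, ReferenceDatabase,
                    build_indexes)

_STAGES = {"refdb": 0, "annotations": 1, "counts": 2, "composition": 3,
           "network_b": 4, "network_c": 5}


def derive_seed(seed: int, stage: str) -> int:
    """Documented fan-out rule: child = (seed * 1000003 + stage) mod (2^31-1)."""
    return (seed * 1_000_003 + _STAGES[stage]) % 2_147_483_647


@dataclass
class SyntheticTruth:
    held_out_gap_reactions: frozenset[str] = frozenset()
    planted_de: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_modules: dict[str, int] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "held_out_gap_reactions": sorted(self.held_out_gap_reactions),
            "planted_de": {k: list(v) for k, v in sorted(self.planted_de.items())},
            "planted_modules": dict(sorted(self.planted_modules.items())),
            "seeds": self.seeds,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# compound inventory

AA_MASSES = {
    # the ten non-essential amino acids
    "C00041": ("L-alanine", 89.09), "C00152": ("L-asparagine", 132.12),
    "C00049": ("L-aspartate", 133.10), "C00097": ("L-cysteine", 121.16),
    "C00064": ("L-glutamine", 146.15), "C00025": ("L-glutamate", 147.13),
    "C00037": ("glycine", 75.07), "C00148": ("L-proline", 115.13),
    "C00065": ("L-serine", 105.09), "C00082": ("L-tyrosine", 181.19),
    # the ten essential amino acids (feed-supplied)
    "C00062": ("L-arginine", 174.20), "C00135": ("L-histidine", 155.15),
    "C00407": ("L-isoleucine", 131.17), "C00123": ("L-leucine", 131.17),
    "C00047": ("L-lysine", 146.19), "C00073": ("L-methionine", 149.21),
    "C00079": ("L-phenylalanine", 165.19), "C00188": ("L-threonine", 119.12),
    "C00078": ("L-tryptophan", 204.23), "C00183": ("L-valine", 117.15),
}
NONESSENTIAL_AA_IDS = ("C00041", "C00152", "C00049", "C00097", "C00064",
                       "C00025", "C00037", "C00148", "C00065", "C00082")
ESSENTIAL_AA_IDS = ("C00062", "C00135", "C00407", "C00123", "C00047",
                    "C00073", "C00079", "C00188", "C00078", "C00183")

CURRENCY_MASSES = {
    "C00001": ("H2O", 18.02), "C00002": ("ATP", 507.18),
    "C00003": ("NAD+", 663.43), "C00004": ("NADH", 665.44),
    "C00005": ("NADPH", 745.42), "C00006": ("NADP+", 743.41),
    "C00007": ("O2", 32.00), "C00008": ("ADP", 427.20),
    "C00009": ("orthophosphate", 97.98), "C00011": ("CO2", 44.01),
    "C00080": ("H+", 1.008),
}

CORE_MASSES = {
    "C00267": ("alpha-D-glucose", 180.16), "C00221": ("beta-D-glucose", 180.16),
    "C00031": ("D-glucose", 180.16), "C00092": ("D-glucose 6-phosphate", 260.14),
    "C00085": ("D-fructose 6-phosphate", 260.14),
    "C00354": ("D-fructose 1,6-bisphosphate", 340.12),
    "C00022": ("pyruvate", 88.06), "C00024": ("acetyl-CoA", 809.57),
    "C00026": ("2-oxoglutarate", 146.10), "C00036": ("oxaloacetate", 132.07),
    "C00033": ("acetate", 60.05), "C00979": ("O-acetyl-L-serine", 147.13),
    "C00283": ("hydrogen sulfide", 34.08), "C01083": ("trehalose", 342.30),
    "C90501": ("ribose 5-phosphate analog", 230.11),
    "C90502": ("nucleotide N1", 347.22), "C90503": ("nucleotide N2", 363.22),
    "C00187": ("cholesterol", 386.65),
    "C01164": ("7-dehydrocholesterol", 384.64),
    "C90301": ("diketol", 400.55), "C90302": ("ketotriol", 416.55),
    "C90303": ("2-deoxyecdysone", 448.60), "C02633": ("ecdysone", 464.63),
}

CHIRALITY_CLASS = {"C00267": "D-glucose", "C00221": "D-glucose",
                   "C00031": "D-glucose"}

TRACE_IDS = tuple(f"C902{i:02d}" for i in range(1, 11))
CARBOHYDRATE_IDS = ("C00267", "C01083")
NUCLEOTIDE_IDS = ("C90502", "C90503")

GLUCOSE_RULES = {"C00031": "C00267", "C00221": "C00267"}

PATHWAY_SUBSYSTEMS = {
    "00010": "Carbohydrate metabolism",
    "00260": "Amino acid metabolism",
    "01040": "Lipid metabolism",
    "00981": "Metabolism of terpenoids and polyketides",
    "00230": "Nucleotide metabolism",
    "01100": "Global and overview maps",
}
_PATHWAY_ORDER = ("00010", "00260", "01040", "00981", "00230")


def fatty_acid_id(k: int) -> str:
    return f"C901{k:02d}"


def _backbone(n_fatty_acids: int) -> list[tuple[str, str, str, dict, list]]:
    """(rid, pathway, direction, whole equation, main metabolites)."""
    rxns: list[tuple[str, str, str, dict, list]] = [
        # carbohydrate / energy backbone
        ("R90001", "00010", FORWARD,
         {"C00267": -1, "C00002": -1, "C00092": 1, "C00008": 1},
         ["C00267", "C00092"]),
        ("R90002", "00010", FORWARD,
         {"C00031": -1, "C00002": -1, "C00092": 1, "C00008": 1},
         ["C00031", "C00092"]),
        ("R90003", "00010", REVERSIBLE,
         {"C00221": -1, "C00267": 1}, ["C00221", "C00267"]),
        ("R90004", "00010", REVERSIBLE,
         {"C00092": -1, "C00085": 1}, ["C00092", "C00085"]),
        ("R90005", "00010", FORWARD,
         {"C00085": -1, "C00002": -1, "C00354": 1, "C00008": 1},
         ["C00085", "C00354"]),
        ("R90006", "00010", FORWARD,  # lower glycolysis with substrate-level ATP
         {"C00354": -1, "C00003": -2, "C00008": -4, "C00009": -2,
          "C00022": 2, "C00004": 2, "C00002": 4},
         ["C00354", "C00022"]),
        ("R90007", "00010", FORWARD,
         {"C00022": -1, "C00003": -1, "C00024": 1, "C00004": 1, "C00011": 1},
         ["C00022", "C00024"]),
        ("R90008", "00010", FORWARD,  # oxidative phosphorylation (currency only)
         {"C00008": -1, "C00009": -1, "C00004": -1, "C00007": -0.5,
          "C00002": 1, "C00003": 1, "C00001": 1},
         ["C00008", "C00009", "C00004", "C00002", "C00003"]),
        ("R90009", "00010", REVERSIBLE,
         {"C00024": -1, "C00003": -1, "C00026": 1, "C00004": 1},
         ["C00024", "C00026"]),
        ("R90010", "00010", REVERSIBLE,
         {"C00022": -1, "C00011": -1, "C00036": 1}, ["C00022", "C00036"]),
        ("R90011", "00010", REVERSIBLE,  # transhydrogenase (currency only)
         {"C00004": -1, "C00006": -1, "C00003": 1, "C00005": 1},
         ["C00004", "C00006", "C00003", "C00005"]),
        ("R90012", "00010", REVERSIBLE,
         {"C00267": -2, "C01083": 1}, ["C00267", "C01083"]),
        ("R90013", "00010", FORWARD,
         {"C00033": -1, "C00002": -1, "C00024": 1, "C00008": 1, "C00009": 1},
         ["C00033", "C00024"]),
        ("R90014", "00010", FORWARD,  # non-growth ATPase (currency only)
         {"C00002": -1, "C00001": -1, "C00008": 1, "C00009": 1, "C00080": 1},
         ["C00002", "C00008", "C00009"]),
        # amino acid block (the ten non-essential acids)
        ("R90101", "00260", REVERSIBLE,
         {"C00026": -1, "C00004": -1, "C00025": 1, "C00003": 1},
         ["C00026", "C00025"]),
        ("R90102", "00260", REVERSIBLE,
         {"C00025": -1, "C00064": 1}, ["C00025", "C00064"]),
        ("R90103", "00260", REVERSIBLE,
         {"C00022": -1, "C00025": -1, "C00041": 1, "C00026": 1},
         ["C00022", "C00025", "C00041", "C00026"]),
        ("R90104", "00260", REVERSIBLE,
         {"C00036": -1, "C00025": -1, "C00049": 1, "C00026": 1},
         ["C00036", "C00025", "C00049", "C00026"]),
        ("R90105", "00260", REVERSIBLE,
         {"C00049": -1, "C00152": 1}, ["C00049", "C00152"]),
        ("R90106", "00260", REVERSIBLE,
         {"C00022": -1, "C00025": -1, "C00065": 1, "C00026": 1},
         ["C00022", "C00025", "C00065", "C00026"]),
        ("R90107", "00260", REVERSIBLE,
         {"C00065": -1, "C00037": 1}, ["C00065", "C00037"]),
        ("R90108", "00260", FORWARD,
         {"C00065": -1, "C00979": 1}, ["C00065", "C00979"]),
        ("R90109", "00260", REVERSIBLE,  # O-acetyl-L-serine + H2S <=> Cys + acetate
         {"C00979": -1, "C00283": -1, "C00097": 1, "C00033": 1},
         ["C00979", "C00283", "C00097", "C00033"]),
        ("R90110", "00260", FORWARD,
         {"C00025": -1, "C00004": -1, "C00148": 1, "C00003": 1},
         ["C00025", "C00148"]),
        ("R90111", "00260", FORWARD,
         {"C00079": -1, "C00005": -1, "C00007": -1,
          "C00082": 1, "C00006": 1, "C00001": 1},
         ["C00079", "C00082"]),
        # hormone route: cholesterol -> ... -> ecdysone
        ("R90401", "00981", FORWARD,
         {"C00187": -1, "C00007": -1, "C01164": 1, "C00001": 1},
         ["C00187", "C01164"]),
        ("R90402", "00981", FORWARD,
         {"C01164": -1, "C00005": -1, "C00007": -1,
          "C90301": 1, "C00006": 1, "C00001": 1},
         ["C01164", "C90301"]),
        ("R90403", "00981", FORWARD,
         {"C90301": -1, "C00005": -1, "C00007": -1,
          "C90302": 1, "C00006": 1, "C00001": 1},
         ["C90301", "C90302"]),
        ("R90404", "00981", FORWARD,
         {"C90302": -1, "C00005": -1, "C00007": -1,
          "C90303": 1, "C00006": 1, "C00001": 1},
         ["C90302", "C90303"]),
        ("R90405", "00981", FORWARD,
         {"C90303": -1, "C00005": -1, "C00007": -1,
          "C02633": 1, "C00006": 1, "C00001": 1},
         ["C90303", "C02633"]),
        # nucleotide branch
        ("R90501", "00230", REVERSIBLE,
         {"C00092": -1, "C90501": 1}, ["C00092", "C90501"]),
        ("R90502", "00230", REVERSIBLE,
         {"C90501": -1, "C00002": -1, "C90502": 1, "C00008": 1},
         ["C90501", "C90502"]),
        ("R90503", "00230", REVERSIBLE,
         {"C90502": -1, "C90503": 1}, ["C90502", "C90503"]),
    ]
    # elongating fatty-acid chain
    rxns.append(("R90201", "01040", FORWARD,
                 {"C00024": -2, fatty_acid_id(1): 1},
                 ["C00024", fatty_acid_id(1)]))
    for k in range(2, n_fatty_acids + 1):
        prev, cur = fatty_acid_id(k - 1), fatty_acid_id(k)
        rxns.append((f"R902{k:02d}", "01040", FORWARD,
                     {prev: -1, "C00024": -1, "C00005": -2, cur: 1, "C00006": 2},
                     [prev, cur]))
    return rxns


def make_refdb(seed: int = 0, n_pathways: int = 5,
               n_reactions: int = 63,
               write_dir: str | Path | None = None) -> ReferenceDatabase:
    """Build the toy reference database.

    ``n_pathways`` takes a prefix of (00010, 00260, 01040, 00981, 00230);
    ``n_reactions`` tunes the length of the fatty-acid chain (the other
    blocks are fixed).  The result is deterministic for a given seed.
    """
    if not 1 <= n_pathways <= len(_PATHWAY_ORDER):
        raise ValueError("n_pathways must be within 1..5")
    rng = np.random.default_rng(derive_seed(seed, "refdb"))
    n_fixed = 33  # backbone reactions outside the fatty-acid chain
    n_fatty = max(3, n_reactions - n_fixed)
    keep = set(_PATHWAY_ORDER[:n_pathways])
    backbone = [r for r in _backbone(n_fatty) if r[1] in keep]

    reactions: dict[str, rdb.ReactionRecord] = {}
    mapformula: list[rdb.MapformulaEntry] = []
    ko_links: list[tuple[str, str]] = []
    ec_links: list[tuple[str, str]] = []
    for idx, (rid, pathway, direction, whole, main_mets) in enumerate(backbone):
        reactions[rid] = rdb.ReactionRecord(id=rid, whole_equation=dict(whole))
        main = {m: whole[m] for m in main_mets}
        mapformula.append(rdb.MapformulaEntry(rid, pathway, main, direction))
        if pathway == "00010":  # also listed on the global overview map
            mapformula.append(rdb.MapformulaEntry(rid, "01100", main, direction))
        ko = f"K9{idx:04d}"
        ko_links.append((ko, rid))
        ec_links.append((f"{idx % 6 + 1}.{idx % 9 + 1}.{idx % 7 + 1}.{idx + 1}", ko))
    # a second enzyme (KO+EC) for glutamate dehydrogenase: exercises OR rules
    if "R90101" in reactions:
        ko_links.append(("K99999", "R90101"))
        ec_links.append(("1.4.1.3", "K99999"))

    metabolites: dict[str, MetaboliteRecord] = {}
    inventory: dict[str, tuple[str, float]] = {}
    inventory.update(CURRENCY_MASSES)
    inventory.update(CORE_MASSES)
    inventory.update(AA_MASSES)
    for k in range(1, n_fatty + 1):
        mass = 200.0 + 14.0 * k + float(rng.uniform(-2.0, 2.0))
        inventory[fatty_acid_id(k)] = (f"fatty acid FA{k:02d}", round(mass, 2))
    for i, cid in enumerate(TRACE_IDS):
        inventory[cid] = (f"trace element TE{i + 1:02d}",
                          round(40.0 + 4.0 * i + float(rng.uniform(0, 2)), 2))
    for cid, (name, mass) in inventory.items():
        metabolites[cid] = MetaboliteRecord(
            id=cid, name=name, molar_mass=mass,
            chirality_class=CHIRALITY_CLASS.get(cid))

    db = build_indexes(metabolites, reactions, mapformula, ko_links, ec_links,
                       dict(PATHWAY_SUBSYSTEMS))
    if write_dir is not None:
        rdb.serialize_reference_database(db, write_dir)
    return db


# ---------------------------------------------------------------------------
# annotations with planted gaps


def _record_adjacency(db: ReferenceDatabase,
                      exclude: frozenset[str] = frozenset()) -> nx.Graph:
    """Reference-reaction adjacency under the same conventions the pipeline
    analyses the network with: currency metabolites ignored and chiral
    glucose variants canonicalized (a bridge must still be a bridge after
    unification)."""
    graph = nx.Graph()
    by_met: dict[str, list[str]] = {}
    for rid, rec in db.reactions.items():
        if rid in exclude:
            continue
        graph.add_node(rid)
        for met in rec.main_equation:
            met = GLUCOSE_RULES.get(met, met)
            if met not in DEFAULT_CURRENCY:
                by_met.setdefault(met, []).append(rid)
    for members in by_met.values():
        for other in members[1:]:
            graph.add_edge(members[0], other)
    return graph


def _is_valid_gap_set(db: ReferenceDatabase, gaps: set[str]) -> bool:
    """Every held-out reaction, re-added alone, must merge >= 2 components
    of the remaining graph — this guarantees the gap-fill search can see it."""
    remaining = _record_adjacency(db, exclude=frozenset(gaps))
    comp_of: dict[str, int] = {}
    for i, comp in enumerate(nx.connected_components(remaining)):
        for node in comp:
            comp_of[node] = i
    full = _record_adjacency(db)
    for gap in gaps:
        touched = {comp_of[nb] for nb in full.neighbors(gap) if nb in comp_of}
        if len(touched) < 2:
            return False
    return True


def make_annotations(db: ReferenceDatabase, coverage: float = 0.8,
                     n_gaps: int = 3, seed: int = 0,
                     write_path: str | Path | None = None
                     ) -> tuple[dict[str, frozenset[str]], SyntheticTruth]:
    """Unigene-KO table covering a known reaction subset with held-out gaps.

    Gap reactions are chosen among articulation reactions of the reference
    adjacency graph (their removal splits a component) whose KOs are private
    to them, validated jointly so each one re-added alone reconnects the
    network.  Coverage is deterministic-count: exactly
    ``round(coverage * n_available)`` of the remaining reactions are
    annotated.
    """
    rng = np.random.default_rng(derive_seed(seed, "annotations"))
    graph = _record_adjacency(db)

    private_ko = {rid for rid, rec in db.reactions.items()
                  if rec.ko_set and all(db.ko_to_reactions[ko] == {rid}
                                        for ko in rec.ko_set)}

    candidates = sorted(set(nx.articulation_points(graph)) & private_ko)
    rng.shuffle(candidates)
    gaps: set[str] = set()
    for cand in candidates:
        if len(gaps) == n_gaps:
            break
        if _is_valid_gap_set(db, gaps | {cand}):
            gaps.add(cand)
    if len(gaps) < n_gaps:
        raise ValueError(
            f"only {len(gaps)} valid bridge reactions available, "
            f"{n_gaps} requested")

    available = sorted(rid for rid, rec in db.reactions.items()
                       if rid not in gaps and rec.ko_set)
    n_selected = int(round(coverage * len(available)))
    selected = sorted(rng.choice(available, size=n_selected, replace=False))

    assignments: list[tuple[str, int]] = []  # (KO, unigenes carrying it)
    for rid in selected:
        for ko in sorted(db.reactions[rid].ko_set):
            n_unigenes = 2 if rng.random() < 0.3 else 1
            assignments.append((ko, n_unigenes))
    total = sum(n for _, n in assignments)
    numbers = rng.choice(90000, size=total, replace=False) + 10000

    unigenes: dict[str, frozenset[str]] = {}
    cursor = 0
    for ko, n_unigenes in assignments:
        for _ in range(n_unigenes):
            uid = f"Unigene{numbers[cursor]}_A0A"
            cursor += 1
            unigenes[uid] = frozenset({ko})

    truth = SyntheticTruth(held_out_gap_reactions=frozenset(gaps),
                           seeds={"annotations": seed})
    if write_path is not None:
        lines = [f"{uid}\t{';'.join(sorted(kos))}"
                 for uid, kos in sorted(unigenes.items())]
        Path(write_path).write_text("\n".join(lines) + "\n")
    return unigenes, truth


# ---------------------------------------------------------------------------
# two-condition counts with planted differential expression


def make_counts(n: int = 5000, de_fraction: float = 0.05, fold: float = 10.0,
                totals: tuple[float, float] = (1_000_000.0, 1_000_000.0),
                seed: int = 0, sigma: float = 0.5,
                unigene_ids: Sequence[str] = (),
                write_path: str | Path | None = None
                ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Poisson count table for two libraries with planted fold changes.

    Baseline expression is lognormal (``sigma`` on the log scale) around a
    mean count of ``totals[0]/n`` (200 at the defaults).  A ``de_fraction``
    of unigenes gets a ``fold``-times change in C1 (up or down, coin flip);
    the truth records each planted unigene and its direction.  The planted
    mass shows up as extra depth in C1 (its realized total exceeds
    ``totals[1]`` when up-regulation dominates); the screen's totals-based
    normalisation absorbs that.  Supplied ``unigene_ids`` (e.g. the
    network's annotation unigenes) occupy the first rows so planted DE
    overlaps the network.
    """
    rng = np.random.default_rng(derive_seed(seed, "counts"))
    ids = list(dict.fromkeys(unigene_ids))[:n]
    ids += [f"DGE{i:05d}" for i in range(n - len(ids))]

    base = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    lam0 = base / base.sum() * totals[0]
    n_de = int(round(de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    up_mask = rng.random(n_de) < 0.5

    factor = np.ones(n)
    factor[de_idx[up_mask]] = fold
    factor[de_idx[~up_mask]] = 1.0 / fold
    # the planted changes are carried by library depth rather than squeezed
    # back to totals[1]: renormalising would shift every null unigene's
    # sampling fraction (a composition effect) and manufacture false signal
    lam1 = lam0 * factor * (totals[1] / totals[0])

    table = pd.DataFrame({
        "unigene": ids,
        "length": rng.integers(300, 3001, size=n),
        "count_C0": rng.poisson(lam0),
        "count_C1": rng.poisson(lam1),
    })
    planted = {ids[i]: ("up" if up else "down", fold)
               for i, up in zip(de_idx, up_mask)}
    truth = SyntheticTruth(planted_de=planted, seeds={"counts": seed})
    if write_path is not None:
        table.to_csv(write_path, sep="\t", index=False)
    return table, truth


# ---------------------------------------------------------------------------
# mass-closed composition table

_CLASS_TOTALS = {  # g per 100 g wet cells, before closure scaling
    "protein": 7.81, "lipid": 33.7, "carbohydrate": 1.05, "trace": 0.74,
}
_NUCLEOTIDE_MGKG = 43.1  # mg/kg, i.e. 4.31 mg per 100 g


def make_composition(seed: int = 0, db: ReferenceDatabase | None = None,
                     water_content: float = 54.2,
                     write_path: str | Path | None = None
                     ) -> list[CompositionEntry]:
    """Composition table (g/100g wet; trace-level nucleotides in mg/kg).

    Class totals mirror a whole-cell assay (protein, lipid, water,
    carbohydrate, nucleotide, trace element); within-class shares are
    jittered by the seed.  Non-water masses are scaled so they sum exactly
    to the dry weight, making the table mass-closed by construction.
    """
    rng = np.random.default_rng(derive_seed(seed, "composition"))

    def mass_of(cid: str, fallback: float) -> float:
        if db is not None and cid in db.metabolites:
            m = db.metabolites[cid].molar_mass
            if m:
                return m
        return fallback

    if db is not None:
        fatty = sorted(cid for cid in db.metabolites if cid.startswith("C901"))
    else:
        fatty = [fatty_acid_id(k) for k in range(1, 31)]

    groups: list[tuple[str, str, list[str]]] = [
        ("protein", "amino acid", list(AA_MASSES)),
        ("lipid", "fatty acid", fatty),
        ("carbohydrate", "carbohydrate", list(CARBOHYDRATE_IDS)),
        # phosphate rides with the mineral fraction: the phosphorus the cell
        # exports in phosphorylated biomass precursors must enter somewhere
        ("trace", "trace element", list(TRACE_IDS) + ["C00009"]),
    ]
    dry = 100.0 - water_content
    nucleotide_g = _NUCLEOTIDE_MGKG * 1e-4
    scale = (dry - nucleotide_g) / sum(_CLASS_TOTALS.values())

    entries: list[CompositionEntry] = [CompositionEntry(
        name="water", nutrient_class="water", content=water_content,
        unit="g/100g", metabolite_id="C00001", molar_mass=18.02)]
    fallback_masses = {**{k: v[1] for k, v in AA_MASSES.items()},
                       **{k: v[1] for k, v in CORE_MASSES.items()}}
    for class_key, nutrient_class, members in groups:
        weights = rng.uniform(0.5, 1.5, size=len(members))
        shares = weights / weights.sum() * _CLASS_TOTALS[class_key] * scale
        for cid, grams in zip(members, shares):
            default = fallback_masses.get(cid, 250.0)
            entries.append(CompositionEntry(
                name=(db.metabolites[cid].name
                      if db is not None and cid in db.metabolites else cid),
                nutrient_class=nutrient_class, content=float(grams),
                unit="g/100g", metabolite_id=cid,
                molar_mass=mass_of(cid, default)))
    nuc_weights = rng.uniform(0.5, 1.5, size=len(NUCLEOTIDE_IDS))
    nuc_shares = nuc_weights / nuc_weights.sum() * _NUCLEOTIDE_MGKG
    for cid, mgkg in zip(NUCLEOTIDE_IDS, nuc_shares):
        entries.append(CompositionEntry(
            name=cid, nutrient_class="nucleotide", content=float(mgkg),
            unit="mg/kg", metabolite_id=cid,
            molar_mass=mass_of(cid, 350.0)))

    if write_path is not None:
        write_composition(entries, write_path)
    return entries
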