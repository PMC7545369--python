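"""Multi-network comparison: shared/unique reactions and feature tables.

Reaction identity is the reference reaction id (not an equation hash), so
two reconstructions share a reaction exactly when they adopted the same
reference reaction.  Unique sets are reported both with and without
transport/exchange reactions, since boundary reactions reflect the chosen
nutrient set rather than annotated metabolism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import pandas as pd

from .reconstruct import Reconstruction


class ComparisonError(ValueError):
    pass


@dataclass
class ComparisonReport:
    features: pd.DataFrame = None
    common: frozenset[str] = frozenset()
    unique: dict[str, frozenset[str]] = field(default_factory=dict)
    unique_metabolic: dict[str, frozenset[str]] = field(default_factory=dict)
    shared_only: dict[frozenset[str], frozenset[str]] = field(default_factory=dict)
    pathway_presence: pd.DataFrame = None


def compare_networks(networks: Mapping[str, Reconstruction]) -> ComparisonReport:
    """Set algebra over reaction ids plus side-by-side feature counts.

    ``shared_only`` holds, for every proper subset of >= 2 networks, the
    reactions present in exactly those networks, so that
    |common| + sum |shared_only| + sum |unique| = |union|.
    """
    if len(networks) < 2:
        raise ComparisonError("need at least two networks to compare")
    names = list(networks)
    ids = {name: frozenset(r.id for r in networks[name].reactions.values()
                           if r.category != "biomass")
           for name in names}
    union = frozenset().union(*ids.values())
    common = frozenset.intersection(*ids.values())

    membership: dict[str, frozenset[str]] = {}
    for rid in union:
        membership[rid] = frozenset(n for n in names if rid in ids[n])

    unique = {
        name: frozenset(rid for rid in ids[name]
                        if membership[rid] == frozenset({name}))
        for name in names
    }
    boundary = {
        name: frozenset(
            r.id for r in networks[name].reactions.values()
            if r.category in ("transport", "exchange"))
        for name in names
    }
    unique_metabolic = {name: unique[name] - boundary[name] for name in names}

    shared_only: dict[frozenset[str], frozenset[str]] = {}
    for size in range(2, len(names)):
        for group in combinations(names, size):
            key = frozenset(group)
            shared_only[key] = frozenset(
                rid for rid in union if membership[rid] == key)

    features = pd.DataFrame(
        {name: networks[name].feature_counts() for name in names})

    pathways = sorted({r.pathway_id for net in networks.values()
                       for r in net.reactions.values()
                       if r.category == "metabolic"
                       and r.pathway_id != "unassigned"})
    presence = pd.DataFrame(
        {name: [any(r.pathway_id == p for r in networks[name].reactions.values())
                for p in pathways] for name in names},
        index=pathways)

    return ComparisonReport(features=features, common=common, unique=unique,
                            unique_metabolic=unique_metabolic,
                            shared_only=shared_only,
                            pathway_presence=presence)
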