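"""Differential unigene expression: read filters, RPKM, exact test, overlay.

Two single-replicate libraries (control C0, treatment C1) are compared per
unigene.  Expression is quantified as RPKM (reads per kilobase per million
mapped reads); significance uses the exact conditional binomial test on the
count pair given the library totals (the classic Audic-Claverie-style test
for replicate-free digital expression data), corrected per unigene with
Benjamini-Hochberg.  A unigene is differentially expressed when
FDR <= 0.001 and |log2 ratio(C1/C0)| > 1 on RPKM; an infinite ratio (a count
of zero in one library) satisfies the ratio criterion by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netmodules import ModulePartition
from .reconstruct import Reconstruction, gpr_leaves

FDR_THRESHOLD = 0.001
LOG2_RATIO_THRESHOLD = 1.0
PHRED_OFFSET = 33


class ExpressionError(ValueError):
    pass


@dataclass
class ReadRecord:
    sequence: str
    quality: str            # Phred+33 encoded, one symbol per base
    has_adaptor: bool = False


def filter_reads(reads: Sequence[ReadRecord], *, quality_offset: int = PHRED_OFFSET,
                 max_n_fraction: float = 0.10, low_quality_value: int = 5,
                 max_low_quality_fraction: float = 0.50
                 ) -> tuple[list[ReadRecord], dict[str, int]]:
    """Keep clean reads; reject adaptor reads, reads with more than 10%
    unknown bases, and reads where more than 50% of bases have quality <= 5.
    Both fraction rules are strict inequalities."""
    clean: list[ReadRecord] = []
    tally = {"kept": 0, "adaptor": 0, "high_n": 0, "low_quality": 0}
    for read in reads:
        if len(read.quality) != len(read.sequence):
            raise ExpressionError(
                f"quality length {len(read.quality)} != sequence length "
                f"{len(read.sequence)}")
        if read.has_adaptor:
            tally["adaptor"] += 1
            continue
        n = len(read.sequence)
        if read.sequence.upper().count("N") / n > max_n_fraction:
            tally["high_n"] += 1
            continue
        low = sum(1 for q in read.quality
                  if ord(q) - quality_offset <= low_quality_value)
        if low / n > max_low_quality_fraction:
            tally["low_quality"] += 1
            continue
        clean.append(read)
        tally["kept"] += 1
    return clean, tally


def rpkm(count: float, length_bp: float, total_mapped: float) -> float:
    """RPKM = 1e9 * count / (total_mapped * length_bp)."""
    if length_bp <= 0:
        raise ExpressionError("gene length must be positive")
    if total_mapped <= 0:
        raise ExpressionError("total mapped reads must be positive")
    return 1e9 * count / (total_mapped * length_bp)


def _log2_ratio(r0: float, r1: float) -> float:
    if r0 == 0.0 and r1 == 0.0:
        return 0.0
    if r0 == 0.0:
        return float("inf")
    if r1 == 0.0:
        return float("-inf")
    return float(np.log2(r1 / r0))


def deu_screen(counts: pd.DataFrame,
               totals: tuple[float, float] | None = None,
               fdr_threshold: float = FDR_THRESHOLD,
               log2_threshold: float = LOG2_RATIO_THRESHOLD) -> pd.DataFrame:
    """Screen differentially expressed unigenes.

    ``counts`` needs columns unigene, length, count_C0, count_C1; ``totals``
    defaults to the column sums.  Returns one row per unigene with RPKM for
    both libraries, the log2 ratio, the exact-test p value, BH-adjusted FDR
    and a direction flag in {up, down, ns}.
    """
    required = {"unigene", "length", "count_C0", "count_C1"}
    missing = required - set(counts.columns)
    if missing:
        raise ExpressionError(f"missing columns: {sorted(missing)}")
    if totals is None:
        totals = (float(counts["count_C0"].sum()), float(counts["count_C1"].sum()))
    total0, total1 = totals
    expected_c1 = total1 / (total0 + total1)

    rows = []
    for row in counts.itertuples(index=False):
        c0, c1 = int(row.count_C0), int(row.count_C1)
        r0 = rpkm(c0, row.length, total0)
        r1 = rpkm(c1, row.length, total1)
        n = c0 + c1
        if n == 0:
            p = 1.0
        else:
            p = stats.binomtest(c1, n, expected_c1).pvalue
        rows.append((row.unigene, row.length, c0, c1, r0, r1,
                     _log2_ratio(r0, r1), p))

    table = pd.DataFrame(rows, columns=[
        "unigene", "length", "count_C0", "count_C1",
        "rpkm_C0", "rpkm_C1", "log2_ratio", "p_value"])
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    significant = (table["fdr"] <= fdr_threshold) & (
        table["log2_ratio"].abs() > log2_threshold)
    table["direction"] = "ns"
    table.loc[significant & (table["log2_ratio"] > 0), "direction"] = "up"
    table.loc[significant & (table["log2_ratio"] < 0), "direction"] = "down"
    return table


@dataclass
class DeuOverlay:
    differential_reactions: dict[str, str] = field(default_factory=dict)
    deus_in_network: frozenset[str] = frozenset()
    deus_in_network_up: int = 0
    deus_in_network_down: int = 0
    deus_in_biggest_wcc: frozenset[str] = frozenset()
    module_counts: dict[int, dict[str, int]] = field(default_factory=dict)


def map_deus(recon: Reconstruction, partition: ModulePartition | None,
             deu_table: pd.DataFrame) -> DeuOverlay:
    """Overlay DEUs on the network: a reaction is differential iff any GPR
    leaf is a DEU.  Counts are split by direction and rolled up per module
    (partition nodes are reaction ids of the biggest WCC)."""
    direction = {row.unigene: row.direction
                 for row in deu_table.itertuples(index=False)
                 if row.direction != "ns"}
    deu_ids = set(direction)

    overlay = DeuOverlay()
    network_leaves: set[str] = set()
    wcc_leaves: set[str] = set()
    assignment = partition.assignment if partition is not None else {}
    for rid, rxn in recon.reactions.items():
        leaves = gpr_leaves(rxn.gpr)
        network_leaves |= leaves
        hits = leaves & deu_ids
        if rid in assignment:
            wcc_leaves |= leaves
        if not hits:
            continue
        dirs = {direction[u] for u in hits}
        overlay.differential_reactions[rid] = (
            dirs.pop() if len(dirs) == 1 else "mixed")
        mid = assignment.get(rid)
        if mid is not None:
            bucket = overlay.module_counts.setdefault(mid, {"up": 0, "down": 0})
            for u in hits:
                bucket[direction[u]] += 1

    in_network = frozenset(network_leaves & deu_ids)
    overlay.deus_in_network = in_network
    overlay.deus_in_network_up = sum(1 for u in in_network if direction[u] == "up")
    overlay.deus_in_network_down = sum(1 for u in in_network if direction[u] == "down")
    overlay.deus_in_biggest_wcc = frozenset(wcc_leaves & deu_ids)
    return overlay


@dataclass
class QcReport:
    saturation: list[int]
    relative_positions: np.ndarray
    histogram: np.ndarray
    bin_edges: np.ndarray


def sequencing_qc(read_positions: Sequence[tuple[str, float]],
                  gene_lengths: Mapping[str, float],
                  n_bins: int = 20) -> QcReport:
    """Saturation curve (detected genes vs reads, monotone non-decreasing)
    and positional randomness histogram of position/length over [0, 1]."""
    seen: set[str] = set()
    saturation: list[int] = []
    rel: list[float] = []
    for gene, pos in read_positions:
        length = gene_lengths[gene]
        if pos > length or pos < 0:
            raise ExpressionError(
                f"read position {pos} outside gene {gene} (length {length})")
        seen.add(gene)
        saturation.append(len(seen))
        rel.append(pos / length)
    positions = np.asarray(rel)
    histogram, bin_edges = np.histogram(positions, bins=n_bins, range=(0.0, 1.0))
    return QcReport(saturation=saturation, relative_positions=positions,
                    histogram=histogram, bin_edges=bin_edges)


def write_deu_table(table: pd.DataFrame, path) -> None:
    """GEO-style layout: id, RPKM x2, log2 ratio, p, FDR, direction."""
    cols = ["unigene", "rpkm_C0", "rpkm_C1", "log2_ratio",
            "p_value", "fdr", "direction"]
    table[cols].to_csv(path, sep="\t", index=False)
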