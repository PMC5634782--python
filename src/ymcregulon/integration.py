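"""Binding x expression integration: core-target calling, phase composition,
Fisher-exact gene-set enrichment with BH FDR, and phase-vs-condition overlap
matrices.

A "core target" is a gene both bound by the TF pair (ChIP peak overlapping
its 700 bp-extended gene region) and differentially expressed in the
deletion mutant; bound-and-down genes are the activated regulon,
bound-and-up the repressed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import PHASES

logger = logging.getLogger(__name__)


@dataclass
class CoreTargetTable:
    activated: set  # bound and down-regulated in the mutant
    repressed: set  # bound and up-regulated in the mutant
    activated_phases: pd.DataFrame
    repressed_phases: pd.DataFrame


def phase_composition(gene_set: set, phases: dict[str, str]) -> pd.DataFrame:
    """Counts and percentages (rounded to 0.1) per phase; unlabeled -> other."""
    counts = {p: 0 for p in PHASES}
    for g in gene_set:
        counts[phases.get(g, "other")] += 1
    n = len(gene_set)
    if n == 0:
        logger.warning("empty gene set; percentages reported as 0")
    return pd.DataFrame(
        {
            "phase": list(counts),
            "count": list(counts.values()),
            "percent": [round(100.0 * c / n, 1) if n else 0.0 for c in counts.values()],
        }
    )


def core_targets(
    bound: set, up: set, down: set, phases: dict[str, str]
) -> CoreTargetTable:
    """activated = bound n down; repressed = bound n up (either-TF binding)."""
    activated = set(bound) & set(down)
    repressed = set(bound) & set(up)
    return CoreTargetTable(
        activated=activated,
        repressed=repressed,
        activated_phases=phase_composition(activated, phases),
        repressed_phases=phase_composition(repressed, phases),
    )


def fisher_geneset(
    query: set, terms: dict[str, set], universe: set
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per term, BH across terms."""
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & set(universe)
    rows = []
    for term, genes in terms.items():
        term_genes = set(genes) & set(universe)
        overlap = len(term_genes & query)
        a = overlap
        b = len(query) - overlap
        c = len(term_genes) - overlap
        d = len(universe) - len(query) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term, overlap, len(term_genes), len(query), len(universe), odds, p))
    out = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "query_size", "universe", "odds_ratio", "p"]
    )
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def quiescence_overlap(
    phase_sets: dict[str, set], condition_sets: dict[str, set], universe: set
) -> pd.DataFrame:
    """Fisher enrichment of each condition gene set in each phase set;
    BH-adjusted across the whole matrix; long-form output."""
    rows = []
    for phase, pg in phase_sets.items():
        pg = set(pg) & universe
        for cond, cg in condition_sets.items():
            cg = set(cg) & universe
            overlap = len(pg & cg)
            a, b = overlap, len(pg) - overlap
            c, d = len(cg) - overlap, len(universe) - len(pg) - (len(cg) - overlap)
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((phase, cond, overlap, len(pg), len(cg), p))
    out = pd.DataFrame(
        rows, columns=["phase", "condition", "overlap", "phase_size", "condition_size", "p"]
    )
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out
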