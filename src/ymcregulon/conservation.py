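"""Two-stage averaging of per-base conservation scores (e.g. phastCons)
over promoter and ORF regions for gene groups.

Promoters are the 500 bp immediately 5' of the start codon; ORFs run from
start codon through stop codon. Stage 1 averages scores per gene region
(missing bases skipped); stage 2 averages the per-gene means within a group
*unweighted* by gene length. The base-weighted alternative is emitted
alongside for comparison; the two coincide when all regions have equal
length.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation

logger = logging.getLogger(__name__)


def promoter_orf_regions(
    annotation: GeneAnnotation, promoter_len: int = 500
) -> tuple[pd.DataFrame, pd.DataFrame]:
    return annotation.promoters(promoter_len), annotation.orf_regions()


def per_gene_means(
    track: dict[str, np.ndarray], regions: pd.DataFrame
) -> pd.Series:
    """Mean score over each gene's region bases; NaN bases skipped; genes
    with zero covered bases dropped (reported)."""
    means = {}
    dropped = []
    for _, r in regions.iterrows():
        v = track[r["chrom"]][int(r["start"]) : int(r["end"])]
        ok = ~np.isnan(v)
        if not ok.any():
            dropped.append(r["gene_id"])
            continue
        means[r["gene_id"]] = float(v[ok].mean())
    if dropped:
        logger.warning("genes with no covered bases excluded: %s", dropped)
    return pd.Series(means, name="mean_score")


def group_mean_score(
    track: dict[str, np.ndarray],
    regions: pd.DataFrame,
    gene_groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-group mean of per-gene mean scores (two-stage, unweighted), with
    the base-weighted mean alongside."""
    gene_means = per_gene_means(track, regions)
    lengths = (regions["end"] - regions["start"]).to_numpy()
    length_by_gene = pd.Series(lengths, index=regions["gene_id"])
    rows = []
    for group, genes in gene_groups.items():
        present = [g for g in genes if g in gene_means.index]
        if not present:
            rows.append((group, 0, np.nan, np.nan))
            continue
        m = gene_means[present]
        w = length_by_gene[present]
        rows.append((group, len(present), float(m.mean()), float((m * w).sum() / w.sum())))
    return pd.DataFrame(rows, columns=["group", "n_genes", "mean", "base_weighted_mean"])


def conservation_summary(
    track: dict[str, np.ndarray],
    annotation: GeneAnnotation,
    gene_groups: dict[str, list[str]],
    promoter_len: int = 500,
) -> pd.DataFrame:
    """Group x {promoter, ORF} table of two-stage mean conservation."""
    promoters, orfs = promoter_orf_regions(annotation, promoter_len)
    prom = group_mean_score(track, promoters, gene_groups).assign(region="promoter")
    orf = group_mean_score(track, orfs, gene_groups).assign(region="ORF")
    return pd.concat([prom, orf], ignore_index=True)[
        ["group", "region", "n_genes", "mean", "base_weighted_mean"]
    ]
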