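"""Pathway-level motif/binding enrichment against a random-gene-set null,
plus the DNase bin filter used for the human-genome variant of the analysis.

The null draws N (default 100) random gene sets of the pathway's size and
counts features (motif sites or ChIP-overlapping sites) in their extended
gene regions. Two p-values are reported: the add-one empirical p, whose
floor is 1/(N+1), and a normal-approximation upper-tail p from the null's
z-score — the latter can reach far smaller magnitudes than 100 draws allow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneAnnotation
from .intervals import _overlap_mask

logger = logging.getLogger(__name__)


def extended_gene_regions(annotation: GeneAnnotation, upstream: int) -> pd.DataFrame:
    """Gene spans extended ``upstream`` bp 5' of the start codon (strand-aware,
    clipped at chromosome bounds)."""
    return annotation.gene_regions(upstream)


def count_features_in_genes(
    features: pd.DataFrame, regions: pd.DataFrame, mode: str = "total_sites"
) -> int:
    """Number of feature intervals overlapping >= 1 region; each feature
    counted once. ``mode`` is a label for which feature set the caller
    supplied (total / predicted / peak-overlapping sites)."""
    del mode  # counting rule is identical; mode names the feature set
    return int(_overlap_mask(features, regions).sum())


def make_region_counter(
    features: pd.DataFrame, regions: pd.DataFrame
) -> Callable[[Sequence[str]], int]:
    """Counter over gene subsets against a fixed feature set (regions must
    carry a ``gene_id`` column)."""

    def counter(genes: Sequence[str]) -> int:
        sub = regions[regions["gene_id"].isin(set(genes))]
        return count_features_in_genes(features, sub)

    return counter


@dataclass
class PermutationNull:
    observed: int
    null_counts: np.ndarray
    N: int
    seed: int
    p_empirical: float
    z: float
    p_normal: float


def random_geneset_null(
    universe: Sequence[str],
    size: int,
    counter: Callable[[Sequence[str]], int],
    observed: int | None = None,
    observed_genes: Sequence[str] | None = None,
    N: int = 100,
    seed: int = 0,
) -> PermutationNull:
    """Random same-size gene sets drawn N times without replacement; add-one
    empirical p plus z-score / normal-tail p."""
    universe = list(universe)
    if size > len(universe):
        raise ValueError("pathway size exceeds universe")
    if observed is None:
        if observed_genes is None:
            raise ValueError("provide observed count or the observed gene set")
        observed = counter(observed_genes)
    rng = np.random.default_rng(seed)
    null_counts = np.array(
        [counter(rng.choice(universe, size=size, replace=False)) for _ in range(N)]
    )
    p_emp = (1 + int((null_counts >= observed).sum())) / (N + 1)
    mean, sd = float(null_counts.mean()), float(null_counts.std(ddof=1))
    if sd == 0:
        logger.warning("degenerate null (sd = 0); z undefined")
        z = np.nan
        p_norm = 1.0 if observed <= mean else 1.0 / (N + 1)
    else:
        z = (observed - mean) / sd
        p_norm = float(stats.norm.sf(z))
    return PermutationNull(
        observed=int(observed),
        null_counts=null_counts,
        N=N,
        seed=seed,
        p_empirical=float(p_emp),
        z=float(z),
        p_normal=p_norm,
    )


def dnase_bin_filter(
    bin_counts: np.ndarray | pd.DataFrame, high: int = 10_000, low: int = 10
) -> np.ndarray:
    """Retain genomic bins whose max read count across cell types is <= high
    (drop abnormal loci) and >= low in at least one cell type (drop noisy
    loci). Boundary semantics: exactly ``low`` passes; ``high + 1`` fails."""
    mat = np.asarray(bin_counts)
    if mat.size == 0:
        return np.array([], dtype=int)
    mx = mat.max(axis=1)
    return np.flatnonzero((mx <= high) & (mx >= low))
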