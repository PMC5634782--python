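"""ChIP-seq downstream logic: combining peaks across time points, two-TF
overlap (Venn) counts, bound-gene assignment by the 700 bp gene-region rule,
pathway binding summaries and temporal binding profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation
from .intervals import merge_intervals, overlap_pairs, validate_intervals, _overlap_mask
from .simulate import SignalTracks

logger = logging.getLogger(__name__)


def merge_time_peaks(
    peak_sets: Iterable[pd.DataFrame], bookended: bool = True
) -> pd.DataFrame:
    """Combine one TF's peaks across time points into maximal merged runs."""
    frames = [validate_intervals(df, "peak set") for df in peak_sets]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(pd.concat(frames, ignore_index=True), bookended=bookended)


class VennCounts(NamedTuple):
    a_only: int
    a_shared: int
    b_shared: int
    b_only: int

    @property
    def shared_summary(self) -> int:
        """Single overlap number for a two-set Venn figure."""
        return min(self.a_shared, self.b_shared)


def overlap_venn(merged_a: pd.DataFrame, merged_b: pd.DataFrame) -> VennCounts:
    """Per-set counts of peaks overlapping (>=1 bp) the other set.

    Both shared counts are reported because peak-to-peak overlap can be
    many-to-one.
    """
    a_shared = int(_overlap_mask(merged_a, merged_b).sum())
    b_shared = int(_overlap_mask(merged_b, merged_a).sum())
    return VennCounts(len(merged_a) - a_shared, a_shared, b_shared, len(merged_b) - b_shared)


def gene_regions(annotation: GeneAnnotation, upstream: int = 700) -> pd.DataFrame:
    """Strand-aware region from 700 bp upstream of the start codon through
    the stop codon (clipped at chromosome bounds)."""
    return annotation.gene_regions(upstream)


@dataclass
class BoundGeneTable:
    bound: dict[str, set]  # tf_id -> gene ids
    support: pd.DataFrame  # gene_id, tf_id, n_supporting_peaks

    def union(self) -> set:
        out: set = set()
        for s in self.bound.values():
            out |= s
        return out


def bound_genes(
    merged_peaks: dict[str, pd.DataFrame], regions: pd.DataFrame
) -> BoundGeneTable:
    """A gene is bound by a TF iff its region overlaps >= 1 merged peak."""
    bound: dict[str, set] = {}
    support_rows = []
    for tf, peaks in merged_peaks.items():
        pairs = overlap_pairs(regions, peaks)
        hits = regions.loc[pairs["query_idx"].unique(), "gene_id"] if len(pairs) else pd.Series(dtype=object)
        bound[tf] = set(hits)
        if len(pairs):
            n_sup = pairs.groupby("query_idx").size()
            for ridx, n in n_sup.items():
                support_rows.append((regions.loc[ridx, "gene_id"], tf, int(n)))
    support = pd.DataFrame(support_rows, columns=["gene_id", "tf_id", "n_supporting_peaks"])
    return BoundGeneTable(bound=bound, support=support)


def pathway_binding_fraction(
    table: BoundGeneTable,
    pathway_genes: Iterable[str],
    annotation: GeneAnnotation | None = None,
    tf_union: bool = True,
    tf_id: str | None = None,
) -> tuple[int, int]:
    """(bound count, pathway size); with ``tf_union`` a gene counts if bound
    by any TF in the table. Pathway genes absent from the annotation are
    excluded and reported."""
    pathway = list(pathway_genes)
    if annotation is not None:
        known = set(annotation.gene_ids)
        missing = [g for g in pathway if g not in known]
        if missing:
            logger.warning("pathway genes absent from annotation, excluded: %s", missing)
        pathway = [g for g in pathway if g in known]
    if not pathway:
        logger.warning("empty pathway")
        return (0, 0)
    bound = table.union() if tf_union else table.bound.get(tf_id or "", set())
    return (sum(g in bound for g in pathway), len(pathway))


def temporal_binding_summary(
    merged_peaks: pd.DataFrame, tracks: SignalTracks, flank: int = 1000
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean signal per peak per time point over midpoint +/- ``flank``;
    column means give the global temporal binding trend."""
    T = tracks.n_timepoints
    rows = np.empty((len(merged_peaks), T))
    for i, (_, p) in enumerate(merged_peaks.iterrows()):
        if flank > 0:
            mid = (int(p["start"]) + int(p["end"])) // 2
            lo, hi = mid - flank, mid + flank
        else:
            mid = (int(p["start"]) + int(p["end"])) // 2
            lo, hi = mid, mid + 1
        rows[i] = tracks.window_mean(p["chrom"], lo, hi)
    mat = pd.DataFrame(rows, columns=tracks.timepoints)
    return mat, mat.mean(axis=0)
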