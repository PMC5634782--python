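"""Strand-aware gene annotation: the coordinate backbone for every region rule.

A gene is stored as a half-open genomic span ``[start, end)`` plus strand.
In gene orientation, the start codon occupies the first three bases of the
span and the stop codon the last three; on the minus strand the start codon
therefore sits at the genomic *right* edge.  Region rules derived from the
annotation (upstream-extended gene regions, promoters, ORFs) all orient
"upstream" 5' of the start codon:

* extended gene region (``upstream`` bp):  ``[start-u, end)`` on +, ``[start, end+u)`` on −
* promoter (``length`` bp):                ``[start-L, start)`` on +, ``[end, end+L)`` on −
* ORF: the span itself (start codon through stop codon inclusive).

The TSV sidecar records 1-based inclusive positions of the first base of each
codon (in gene orientation); readers convert back to half-open spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import clip_to_chrom

PHASES = ("OX", "RB", "RC", "other")

GENE_COLS = ["gene_id", "chrom", "start", "end", "strand", "phase"]


@dataclass
class GeneAnnotation:
    """Table of gene records with optional chromosome sizes for clipping."""

    genes: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLS[:5] if c not in self.genes.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if "phase" not in self.genes.columns:
            self.genes = self.genes.assign(phase="other")
        bad = self.genes[~self.genes["strand"].isin(["+", "-"])]
        if len(bad):
            raise ValueError(f"gene {bad.iloc[0]['gene_id']}: missing or invalid strand")
        self.genes = self.genes.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()

    def phase_labels(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["phase"]))

    # ---- region rules -------------------------------------------------

    def gene_regions(self, upstream: int = 700) -> pd.DataFrame:
        """Strand-aware region from ``upstream`` bp before the start codon
        through the stop codon, clipped at chromosome bounds."""
        if upstream < 0:
            raise ValueError("upstream must be >= 0")
        g = self.genes
        plus = g["strand"].to_numpy() == "+"
        start = np.where(plus, g["start"] - upstream, g["start"])
        end = np.where(plus, g["end"], g["end"] + upstream)
        df = pd.DataFrame(
            {"chrom": g["chrom"], "start": start, "end": end, "gene_id": g["gene_id"]}
        )
        return clip_to_chrom(df, self.chrom_sizes)

    def promoters(self, length: int = 500) -> pd.DataFrame:
        """Promoter = the ``length`` bases immediately 5' of the start codon."""
        g = self.genes
        plus = g["strand"].to_numpy() == "+"
        start = np.where(plus, g["start"] - length, g["end"])
        end = np.where(plus, g["start"], g["end"] + length)
        df = pd.DataFrame(
            {"chrom": g["chrom"], "start": start, "end": end, "gene_id": g["gene_id"]}
        )
        return clip_to_chrom(df, self.chrom_sizes)

    def orf_regions(self) -> pd.DataFrame:
        g = self.genes
        return pd.DataFrame(
            {"chrom": g["chrom"], "start": g["start"], "end": g["end"], "gene_id": g["gene_id"]}
        )

    # ---- sidecar I/O --------------------------------------------------

    def to_sidecar(self) -> pd.DataFrame:
        """1-based inclusive first-base codon positions, gene orientation."""
        g = self.genes
        plus = g["strand"].to_numpy() == "+"
        start_codon = np.where(plus, g["start"] + 1, g["end"])
        stop_codon = np.where(plus, g["end"] - 2, g["start"] + 3)
        return pd.DataFrame(
            {
                "gene_id": g["gene_id"],
                "chrom": g["chrom"],
                "strand": g["strand"],
                "start_codon": start_codon,
                "stop_codon": stop_codon,
                "phase": g["phase"],
            }
        )

    @classmethod
    def from_sidecar(
        cls, df: pd.DataFrame, chrom_sizes: dict[str, int] | None = None
    ) -> "GeneAnnotation":
        bad = df[~df["phase"].isin(PHASES)] if "phase" in df.columns else df.iloc[0:0]
        if len(bad):
            raise ValueError(f"unknown phase token: {bad.iloc[0]['phase']!r}")
        plus = df["strand"].to_numpy() == "+"
        start = np.where(plus, df["start_codon"] - 1, df["stop_codon"] - 3)
        end = np.where(plus, df["stop_codon"] + 2, df["start_codon"])
        genes = pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "chrom": df["chrom"],
                "start": start.astype(int),
                "end": end.astype(int),
                "strand": df["strand"],
                "phase": df.get("phase", "other"),
            }
        )
        return cls(genes, chrom_sizes or {})

    def to_bed(self) -> pd.DataFrame:
        g = self.genes
        return pd.DataFrame(
            {
                "chrom": g["chrom"],
                "start": g["start"],
                "end": g["end"],
                "name": g["gene_id"],
                "score": 0,
                "strand": g["strand"],
            }
        )
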