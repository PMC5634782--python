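"""Genomic interval primitives: merge, overlap, Venn counting.

All coordinates are 0-based half-open (BED convention). Interval tables are
pandas DataFrames with at least ``chrom``, ``start``, ``end`` columns; extra
columns are carried through where meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def validate_intervals(df: pd.DataFrame, name: str = "interval set") -> pd.DataFrame:
    """Check end > start for every record; raise naming the offender."""
    bad = df[df["end"].to_numpy() <= df["start"].to_numpy()]
    if len(bad):
        rec = bad.iloc[0]
        raise ValueError(
            f"malformed interval in {name}: {rec['chrom']}:{rec['start']}-{rec['end']} (end <= start)"
        )
    return df


def merge_intervals(df: pd.DataFrame, bookended: bool = True) -> pd.DataFrame:
    """Merge overlapping (and, by default, bookended) intervals into maximal runs.

    Idempotent; the union of covered base pairs is preserved.
    """
    validate_intervals(df)
    if df.empty:
        return df[INTERVAL_COLS].copy()
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        ends = sub["end"].to_numpy()[order]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            joins = s <= cur_e if bookended else s < cur_e
            if joins:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLS)


def _overlap_mask(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: overlaps >= 1 bp of any subject interval.

    The subject is merged per chromosome first, so a sorted two-pointer /
    searchsorted test is exact.
    """
    mask = np.zeros(len(query), dtype=bool)
    if query.empty or subject.empty:
        return mask
    merged = merge_intervals(subject, bookended=False)
    by_chrom = {c: g for c, g in merged.groupby("chrom")}
    qs = query["start"].to_numpy()
    qe = query["end"].to_numpy()
    qc = query["chrom"].to_numpy()
    for chrom, sub in by_chrom.items():
        idx = np.flatnonzero(qc == chrom)
        if idx.size == 0:
            continue
        ss = sub["start"].to_numpy()
        se = sub["end"].to_numpy()
        # candidate subject interval: last one starting before the query end
        j = np.searchsorted(ss, qe[idx], side="left") - 1
        ok = j >= 0
        ok[ok] = se[j[ok]] > qs[idx[ok]]
        mask[idx] = ok
    return mask


def count_overlapping(query: pd.DataFrame, subject: pd.DataFrame) -> int:
    """Number of query intervals overlapping >= 1 subject interval (each counted once)."""
    return int(_overlap_mask(query, subject).sum())


def overlap_pairs(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
    """All (query index, subject index) pairs with >= 1 bp overlap."""
    hits = []
    if query.empty or subject.empty:
        return pd.DataFrame(columns=["query_idx", "subject_idx"])
    for chrom, sub in subject.groupby("chrom"):
        q = query[query["chrom"] == chrom]
        if q.empty:
            continue
        ss = sub["start"].to_numpy()
        se = sub["end"].to_numpy()
        order = np.argsort(ss, kind="stable")
        ss, se = ss[order], se[order]
        sidx = sub.index.to_numpy()[order]
        for qi, qs_, qe_ in zip(q.index, q["start"].to_numpy(), q["end"].to_numpy()):
            lo = np.searchsorted(ss, qe_, side="left")
            for k in range(lo):
                if se[k] > qs_:
                    hits.append((qi, sidx[k]))
    return pd.DataFrame(hits, columns=["query_idx", "subject_idx"])


def covered_bases(df: pd.DataFrame) -> int:
    m = merge_intervals(df, bookended=False)
    return int((m["end"] - m["start"]).sum()) if len(m) else 0


def clip_to_chrom(df: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Clip intervals to [0, chrom length); drop records that vanish."""
    out = df.copy()
    out["start"] = out["start"].clip(lower=0)
    if chrom_sizes:
        lens = out["chrom"].map(chrom_sizes)
        out["end"] = np.minimum(out["end"], lens.fillna(out["end"]).astype(int))
    return out[out["end"] > out["start"]].reset_index(drop=True)
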