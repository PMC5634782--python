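"""Dynamic motif-occupancy analysis: temporal profiles at motif sites,
k-means clustering into dynamic classes, per-(TF, cluster) hypergeometric
enrichment, target-gene prediction and target-set similarity.

The idea: a histone-acetylation signal tracks transcriptional activity, so
the temporal signal at a TF's predicted motif sites is a proxy for when the
TF acts. Sites clustering into the same temporal class, over-populated by
one TF's sites, flag that TF as a candidate phase-specific regulator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .annotation import GeneAnnotation
from .intervals import _overlap_mask
from .simulate import SignalTracks

logger = logging.getLogger(__name__)


def standardize_profiles(values: np.ndarray) -> np.ndarray:
    """Row-wise z-scores; constant rows map to all-zeros."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    out = np.zeros_like(values)
    ok = sd[:, 0] > 0
    out[ok] = (values[ok] - mean[ok]) / sd[ok]
    return out


def extract_profiles(
    sites: pd.DataFrame,
    tracks: SignalTracks,
    flank: int = 50,
    standardize: bool = True,
) -> pd.DataFrame:
    """Mean signal per time point over each site's midpoint +/- ``flank``.

    ``flank=0`` reads the site's own span. Windows running off a chromosome
    are truncated (logged). Returns a site x T frame whose index aligns with
    ``sites``.
    """
    T = tracks.n_timepoints
    rows = np.empty((len(sites), T))
    for i, (_, s) in enumerate(sites.iterrows()):
        if flank > 0:
            mid = (int(s["start"]) + int(s["end"])) // 2
            lo, hi = mid - flank, mid + flank
        else:
            lo, hi = int(s["start"]), int(s["end"])
        L = tracks.values[s["chrom"]].shape[1]
        if lo < 0 or hi > L:
            logger.warning("profile window %s:%d-%d truncated to chromosome", s["chrom"], lo, hi)
        rows[i] = tracks.window_mean(s["chrom"], lo, hi)
    if standardize:
        rows = standardize_profiles(rows)
    return pd.DataFrame(rows, index=sites.index, columns=tracks.timepoints)


@dataclass
class SiteClustering:
    k: int
    labels: pd.Series  # site index -> cluster 0..k-1, ordered by peak time
    centroids: np.ndarray  # (k, T)
    seed: int
    inertia: float


def cluster_profiles(
    profiles: pd.DataFrame, k: int = 3, seed: int = 0, n_init: int = 10
) -> SiteClustering:
    """K-means on standardized profiles; clusters relabelled by centroid peak
    time so cluster 0 peaks earliest."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(profiles) < k:
        raise ValueError(f"need >= {k} profiles for k={k}")
    X = profiles.to_numpy()
    if len(np.unique(X, axis=0)) < k:
        logger.warning("degenerate clustering: fewer than k distinct profiles")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-profile convergence warnings
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    peak_time = km.cluster_centers_.argmax(axis=1)
    order = np.lexsort((np.arange(k), peak_time))  # peak time asc, stable
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = pd.Series(relabel[km.labels_], index=profiles.index, name="cluster")
    if not np.all(np.isfinite(km.cluster_centers_)):
        raise RuntimeError("non-finite centroid")
    return SiteClustering(
        k=k,
        labels=labels,
        centroids=km.cluster_centers_[order],
        seed=seed,
        inertia=float(km.inertia_),
    )


def tf_cluster_enrichment(
    clustering: SiteClustering, sites: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each TF's sites in
    each cluster, BH-corrected across all (TF, cluster) pairs."""
    df = sites.copy()
    df["cluster"] = clustering.labels
    universe = len(df)
    tf_totals = df["tf_id"].value_counts()
    cluster_totals = df["cluster"].value_counts()
    rows = []
    for tf, tf_total in tf_totals.items():
        if tf_total == 0:
            logger.warning("TF %s has zero sites; excluded", tf)
            continue
        for cluster in range(clustering.k):
            cl_total = int(cluster_totals.get(cluster, 0))
            in_cluster = int(((df["tf_id"] == tf) & (df["cluster"] == cluster)).sum())
            p = float(stats.hypergeom.sf(in_cluster - 1, universe, tf_total, cl_total))
            rows.append((tf, cluster, in_cluster, int(tf_total), cl_total, universe, p))
    out = pd.DataFrame(
        rows,
        columns=["tf_id", "cluster", "in_cluster", "tf_total", "cluster_total", "universe", "p"],
    )
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out["candidate"] = out["fdr"] < fdr_threshold
    return out


def predict_targets(
    sites: pd.DataFrame, annotation: GeneAnnotation, upstream_window: int = 1000
) -> dict[str, set]:
    """Gene is a target of a TF iff one of the TF's sites overlaps the
    strand-aware region from ``upstream_window`` bp before the start codon
    through the stop codon."""
    regions = annotation.gene_regions(upstream_window)
    targets: dict[str, set] = {}
    for tf, sub in sites.groupby("tf_id"):
        mask = _overlap_mask(regions, sub[["chrom", "start", "end"]])
        targets[tf] = set(regions.loc[mask, "gene_id"])
    return targets


def target_similarity(targets: dict[str, set]) -> pd.DataFrame:
    """Jaccard similarity of target sets: |A n B| / |A u B|."""
    if len(targets) < 2:
        raise ValueError("need >= 2 TFs")
    tfs = sorted(targets)
    mat = np.zeros((len(tfs), len(tfs)))
    for i, a in enumerate(tfs):
        for j, b in enumerate(tfs):
            union = targets[a] | targets[b]
            if not union:
                logger.warning("both target sets empty for (%s, %s); similarity 0", a, b)
                mat[i, j] = 0.0
            else:
                mat[i, j] = len(targets[a] & targets[b]) / len(union)
    return pd.DataFrame(mat, index=tfs, columns=tfs)
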