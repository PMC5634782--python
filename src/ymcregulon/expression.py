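"""Count normalization, FPKM, and the time-matched differential-expression
scheme for a 7-sample wild-type / 11-sample mutant metabolic-cycle design.

The testing machinery follows the classic negative-binomial exact-test
approach for count data without replicates:

* size factors by median-of-ratios;
* for a single-sample-vs-single-sample comparison, the two contrasted
  samples are treated as replicates, a mean-dispersion trend
  ``a0 + a1/mean`` is fitted across genes, and each gene uses the *fitted*
  dispersion (deliberately conservative: genuine signal inflates the trend,
  not individual genes);
* the p-value is a two-sided conditional exact test on the pair's count sum
  ``K_A + K_B``: with NB marginals for each side, every split ``(a, s-a)``
  with probability <= that of the observed split contributes;
* the replicated RC-group comparison (5 WT vs 9 mutant samples) uses
  per-gene method-of-moments dispersions shrunk conservatively to
  ``max(per-gene, trend)`` and the same exact test on group sums, using the
  fact that a sum of n iid NB(mu, alpha) variables is NB(n*mu, alpha/n).

The study design runs eleven sample pairings (absolute-time matches then
relative-RC-time matches) plus the RC group contrast; each comparison is
BH-adjusted on its own and significant genes (padj < 0.01) are unioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_PAIRS = [
    ("WT1", "Mut1"), ("WT2", "Mut2"), ("WT3", "Mut3"), ("WT4", "Mut4"),
    ("WT5", "Mut5"), ("WT6", "Mut6"), ("WT7", "Mut7"),
    ("WT4", "Mut8"), ("WT5", "Mut9"), ("WT6", "Mut10"), ("WT7", "Mut11"),
]
DEFAULT_WT_RC = ["WT3", "WT4", "WT5", "WT6", "WT7"]
DEFAULT_MUT_RC = ["Mut3", "Mut4", "Mut5", "Mut6", "Mut7", "Mut8", "Mut9", "Mut10", "Mut11"]


@dataclass
class ComparisonScheme:
    pairs: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_PAIRS))
    group_comparison: tuple[list[str], list[str]] = field(
        default_factory=lambda: (list(DEFAULT_WT_RC), list(DEFAULT_MUT_RC))
    )

    def validate(self, samples: list[str]) -> None:
        have = set(samples)
        used = {s for p in self.pairs for s in p} | set(self.group_comparison[0]) | set(
            self.group_comparison[1]
        )
        missing = used - have
        if missing:
            raise ValueError(f"comparison scheme references missing samples: {sorted(missing)}")


# ---------------------------------------------------------------------
# normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (genes with any zero excluded
    from the geometric-mean reference)."""
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample; cannot normalize")
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million library fragments (raw library size)."""
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    return counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


def max_fpkm(
    fpkm_matrix: pd.DataFrame,
    genes: list[str] | None = None,
    samples: list[str] | None = None,
) -> pd.Series:
    """Row-wise max FPKM over the selected samples."""
    sub = fpkm_matrix
    if genes is not None:
        sub = sub.loc[[g for g in genes if g in sub.index]]
    if samples is not None:
        if len(samples) == 0:
            raise ValueError("empty sample set")
        sub = sub[samples]
    if sub.shape[1] == 0:
        raise ValueError("empty sample set")
    return sub.max(axis=1)


# ---------------------------------------------------------------------
# dispersion trend


def _fit_dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Non-negative least-squares fit of disp ~ a0 + a1/mean over informative
    genes, with one outlier-trimming refit (genes far above the first fit are
    usually genuine signal, not dispersion, and must not inflate the trend)."""
    from scipy.optimize import nnls

    ok = (mean > 1.0) & np.isfinite(disp)
    if ok.sum() < 10:
        med = float(np.median(disp[np.isfinite(disp)])) if np.isfinite(disp).any() else 0.01
        return max(med, 1e-8), 0.0
    m, d = mean[ok], disp[ok]
    a0, a1 = 0.0, 0.0
    keep = np.ones(m.size, dtype=bool)
    for _ in range(2):
        X = np.column_stack([np.ones(keep.sum()), 1.0 / m[keep]])
        coef, _ = nnls(X, d[keep])
        a0, a1 = float(coef[0]), float(coef[1])
        fitted = np.maximum(a0 + a1 / m, 1e-8)
        keep = d <= 10.0 * fitted + 1e-3
        if keep.sum() < 10:
            break
    if a0 == 0.0 and a1 == 0.0:
        a0 = 1e-8
    return a0, a1


def _trend_dispersion(mean: np.ndarray, a0: float, a1: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        d = a0 + a1 / np.maximum(mean, 1e-8)
    return np.clip(d, 1e-8, 20.0)


# ---------------------------------------------------------------------
# exact NB test


def _exact_nb_p(k_a: int, k_b: int, mu_a: float, mu_b: float, alpha_a: float, alpha_b: float) -> float:
    """Two-sided conditional exact NB p-value for the split of s = k_a + k_b."""
    s = k_a + k_b
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    na, nb = 1.0 / alpha_a, 1.0 / alpha_b
    logp = stats.nbinom.logpmf(a, na, na / (na + mu_a)) + stats.nbinom.logpmf(
        s - a, nb, nb / (nb + mu_b)
    )
    logp -= logp.max()
    p = np.exp(logp)
    total = p.sum()
    obs = p[k_a]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-8)].sum() / total))


def nb_test_pair(
    counts: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """No-replicate exact NB test between two single samples.

    Returns a per-gene frame with ``log2fc`` (b relative to a, pseudocount on
    normalized counts) and two-sided ``p``.
    """
    if factors is None:
        factors = size_factors(counts[[sample_a, sample_b]])
    sf_a, sf_b = float(factors[sample_a]), float(factors[sample_b])
    k_a = counts[sample_a].to_numpy(dtype=int)
    k_b = counts[sample_b].to_numpy(dtype=int)
    na, nb = k_a / sf_a, k_b / sf_b
    q = (na + nb) / 2.0
    # blind dispersion: the two contrasted samples treated as replicates
    raw_disp = np.where(q > 0, ((na - nb) ** 2 / 2.0 - q) / np.maximum(q, 1e-8) ** 2, np.nan)
    raw_disp = np.clip(raw_disp, 0.0, None)
    a0, a1 = _fit_dispersion_trend(q, raw_disp)
    disp = _trend_dispersion(q, a0, a1)
    log2fc = np.log2((nb + pseudocount) / (na + pseudocount))
    p = np.ones(len(q))
    for i in range(len(q)):
        if k_a[i] + k_b[i] == 0:
            p[i], log2fc[i] = 1.0, 0.0
            continue
        p[i] = _exact_nb_p(
            int(k_a[i]), int(k_b[i]), q[i] * sf_a, q[i] * sf_b, disp[i], disp[i]
        )
    return pd.DataFrame({"gene_id": counts.index, "log2fc": log2fc, "p": p}).set_index("gene_id")


def nb_test_group(
    counts: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Replicated-group exact NB test (group sums; dispersion shrunk to
    max(per-gene MoM, fitted trend))."""
    cols = list(samples_a) + list(samples_b)
    if factors is None:
        factors = size_factors(counts[cols])
    sf = factors[cols].to_numpy(dtype=float)
    mat = counts[cols].to_numpy(dtype=float)
    norm = mat / sf[None, :]
    n_a, n_b = len(samples_a), len(samples_b)
    norm_a, norm_b = norm[:, :n_a], norm[:, n_a:]
    m_a, m_b = norm_a.mean(axis=1), norm_b.mean(axis=1)
    q = norm.mean(axis=1)
    resid = np.concatenate([norm_a - m_a[:, None], norm_b - m_b[:, None]], axis=1)
    var_pooled = (resid**2).sum(axis=1) / max(n_a + n_b - 2, 1)
    raw_disp = np.clip((var_pooled - q) / np.maximum(q, 1e-8) ** 2, 0.0, None)
    a0, a1 = _fit_dispersion_trend(q, raw_disp)
    disp = np.maximum(raw_disp, _trend_dispersion(q, a0, a1))
    disp = np.clip(disp, 1e-8, 20.0)
    k_a = mat[:, :n_a].sum(axis=1).astype(int)
    k_b = mat[:, n_a:].sum(axis=1).astype(int)
    mu_a = q * sf[:n_a].sum()
    mu_b = q * sf[n_a:].sum()
    log2fc = np.log2((m_b + pseudocount) / (m_a + pseudocount))
    p = np.ones(len(q))
    for i in range(len(q)):
        if k_a[i] + k_b[i] == 0:
            p[i], log2fc[i] = 1.0, 0.0
            continue
        p[i] = _exact_nb_p(
            int(k_a[i]), int(k_b[i]), mu_a[i], mu_b[i], disp[i] / n_a, disp[i] / n_b
        )
    return pd.DataFrame({"gene_id": counts.index, "log2fc": log2fc, "p": p}).set_index("gene_id")


# ---------------------------------------------------------------------
# full design


@dataclass
class DEResults:
    table: pd.DataFrame  # gene_id, comparison, log2fc, p, padj, significant
    up: set
    down: set
    conflicted: set


def run_design(
    wt_counts: pd.DataFrame,
    mut_counts: pd.DataFrame,
    scheme: ComparisonScheme | None = None,
    padj_threshold: float = 0.01,
) -> DEResults:
    """Run the 11 pairings plus the RC-group comparison; BH within each
    comparison; union significant genes and call direction by majority sign."""
    scheme = scheme or ComparisonScheme()
    counts = pd.concat([wt_counts, mut_counts], axis=1)
    scheme.validate(list(counts.columns))
    factors = size_factors(counts)
    tables = []
    for wt_s, mut_s in scheme.pairs:
        res = nb_test_pair(counts, wt_s, mut_s, factors=factors)
        res["comparison"] = f"{wt_s}-{mut_s}"
        tables.append(res.reset_index())
    ga, gb = scheme.group_comparison
    res = nb_test_group(counts, ga, gb, factors=factors)
    res["comparison"] = "RCgroup"
    tables.append(res.reset_index())
    table = pd.concat(tables, ignore_index=True)
    table["padj"] = np.nan
    for comp, idx in table.groupby("comparison").groups.items():
        table.loc[idx, "padj"] = multipletests(table.loc[idx, "p"], method="fdr_bh")[1]
    table["significant"] = table["padj"] < padj_threshold
    up, down, conflicted = set(), set(), set()
    sig = table[table["significant"]]
    for gene, sub in sig.groupby("gene_id"):
        direction = classify_direction(sub)
        if direction == "up":
            up.add(gene)
        elif direction == "down":
            down.add(gene)
        else:
            conflicted.add(gene)
    if conflicted:
        logger.info("%d genes with conflicting directions excluded from up/down", len(conflicted))
    return DEResults(table=table, up=up, down=down, conflicted=conflicted)


def classify_direction(significant_rows: pd.DataFrame) -> str:
    """Majority sign among a gene's significant comparisons; tie -> conflicted."""
    n_up = int((significant_rows["log2fc"] > 0).sum())
    n_down = int((significant_rows["log2fc"] < 0).sum())
    if n_up > n_down:
        return "up"
    if n_down > n_up:
        return "down"
    return "conflicted"


# ---------------------------------------------------------------------
# phase assignment


def assign_phase(
    labels: dict[str, str] | None = None,
    wt_matrix: pd.DataFrame | None = None,
    sample_phases: list[str] | None = None,
    min_correlation: float = 0.5,
) -> dict[str, str]:
    """Phase labels per gene: pass a label mapping through, or classify each
    gene's standardized WT profile by maximal Pearson correlation with
    phase-indicator templates over the sample axis ('other' below
    ``min_correlation`` or for flat profiles)."""
    if labels is not None:
        from .annotation import PHASES

        bad = set(labels.values()) - set(PHASES)
        if bad:
            raise ValueError(f"unknown label token(s): {sorted(bad)}")
        return dict(labels)
    if wt_matrix is None or sample_phases is None:
        raise ValueError("provide labels, or a WT matrix with per-sample phases")
    templates = {}
    ph_arr = np.array(sample_phases)
    for ph in ("OX", "RB", "RC"):
        t = (ph_arr == ph).astype(float)
        if t.std() > 0:
            templates[ph] = (t - t.mean()) / t.std()
    out = {}
    X = wt_matrix.to_numpy(dtype=float)
    for i, gene in enumerate(wt_matrix.index):
        v = X[i]
        if v.std() == 0:
            out[gene] = "other"
            continue
        z = (v - v.mean()) / v.std()
        best, best_r = "other", -np.inf
        for ph, t in templates.items():
            r = float(np.mean(z * t))
            if r > best_r:
                best, best_r = ph, r
        out[gene] = best if best_r >= min_correlation else "other"
    return out
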