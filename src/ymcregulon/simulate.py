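"""Ground-truth simulator for the yeast-metabolic-cycle regulatory pipeline.

Generates a miniature genome with phase-labelled genes, plants transcription
factor motif instances in promoters of their assigned phase, and emits the
data modalities the real study measured: per-time-point histone-acetylation
signal tracks following three phase templates (OX / RB / RC), per-time-point
ChIP peak sets for two partially overlapping quiescence-phase TFs,
negative-binomial RNA-seq count matrices for a 7-sample wild-type and an
11-sample deletion-mutant time course with a down-regulated "glycolysis-like"
pathway, and a per-base conservation track elevated over ORFs.

Everything is driven by one :class:`SimConfig` and one seed; outputs are
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import PHASES, GeneAnnotation
from .motifs import PWM, random_pwm, reverse_complement
from . import io as _io

logger = logging.getLogger(__name__)

# three-phase partition of the 16-point histone-signal axis
PHASE_WINDOWS = {"OX": (0, 5), "RB": (5, 10), "RC": (10, 16)}
TEMPLATE_BASELINE = 1.0
TEMPLATE_PEAK = 10.0

# six ChIP time points spanning the cycle's phases
CHIP_TIMEPOINT_PHASES = ("OX", "RB", "RB", "RC", "RC", "RC")


@dataclass
class SimConfig:
    """Experiment-design constants for the synthetic study."""

    n_chroms: int = 2
    chrom_len: int = 200_000
    n_genes: int = 200
    n_timepoints_signal: int = 16
    n_tf_motifs: int = 6
    phase_fractions: dict[str, float] = field(
        default_factory=lambda: {"OX": 0.25, "RB": 0.25, "RC": 0.3, "other": 0.2}
    )
    planted_tf_phase: dict[str, str] = field(default_factory=lambda: {"TF1": "RC"})
    motif_width: int = 8
    signal_noise_sd: float = 1.0  # 10% of template peak
    nb_mean: float = 200.0
    nb_dispersion: float = 0.05
    de_log2fc: float = 3.0
    phase_amp: float = 4.0  # expression fold-up in a gene's own phase
    pathway_size: int = 33  # glycolysis-like regulon
    n_wt_samples: int = 7
    n_mut_samples: int = 11
    gene_len: int = 900
    promoter_len: int = 1000  # upstream margin reserved per gene
    background_site_prob: float = 0.03  # off-phase planting rate per promoter
    tf_peak_share: float = 0.6
    peak_rc_prob: float = 0.95
    peak_bg_prob: float = 0.05
    peak_halfwidth: int = 100
    seed: int = 42

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.phase_fractions.values()), 1.0):
            raise ValueError("phase_fractions must sum to 1")
        if self.motif_width < 4:
            raise ValueError("motif_width must be >= 4")
        for name in ("n_chroms", "chrom_len", "n_genes", "n_timepoints_signal", "n_tf_motifs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.planted_tf_phase.values()) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown planted phase(s): {unknown}")

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1}" for i in range(self.n_tf_motifs)]

    @property
    def wt_sample_phases(self) -> list[str]:
        # WT1=OX, WT2=RB, then the RC stretch (5 WT samples in RC)
        return ["OX", "RB"] + ["RC"] * (self.n_wt_samples - 2)

    @property
    def mut_sample_phases(self) -> list[str]:
        # same layout; the mutant's RC phase is lengthened (9 RC samples)
        return ["OX", "RB"] + ["RC"] * (self.n_mut_samples - 2)


@dataclass
class TruthTable:
    planted_sites: pd.DataFrame  # tf_id, chrom, start, end, strand, phase
    de_genes: pd.DataFrame  # gene_id, direction, log2fc
    phase_labels: dict[str, str]
    bound_genes_truth: dict[str, set]


def phase_templates(n_timepoints: int = 16) -> dict[str, np.ndarray]:
    """Raised-cosine bump per phase over its window; flat baseline elsewhere."""
    templates = {}
    t = np.arange(n_timepoints)
    for phase, (lo, hi) in PHASE_WINDOWS.items():
        lo_s, hi_s = lo * n_timepoints / 16, hi * n_timepoints / 16
        v = np.full(n_timepoints, TEMPLATE_BASELINE)
        inside = (t >= lo_s) & (t < hi_s)
        x = (t[inside] - lo_s + 0.5) / (hi_s - lo_s)
        v[inside] = TEMPLATE_BASELINE + (TEMPLATE_PEAK - TEMPLATE_BASELINE) * 0.5 * (
            1 - np.cos(2 * np.pi * x)
        )
        templates[phase] = v
    templates["other"] = np.full(n_timepoints, TEMPLATE_BASELINE)
    return templates


# ---------------------------------------------------------------------
# genome and annotation


def generate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], GeneAnnotation]:
    """Random genome with non-overlapping, phase-labelled genes on both strands.

    Genes are laid out on a grid of equal slots, each slot reserving
    ``promoter_len`` bp upstream of the start codon, so promoters never
    invade neighbouring genes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    slot = config.chrom_len // per_chrom
    if slot < config.gene_len + config.promoter_len + 10:
        raise ValueError(
            f"genome too small: slot {slot} bp cannot hold a {config.gene_len} bp gene "
            f"plus {config.promoter_len} bp promoter margin for {config.n_genes} genes"
        )
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sequences = {
        c: "".join(rng.choice(list("ACGT"), size=config.chrom_len)) for c in chrom_names
    }
    phases = list(config.phase_fractions)
    probs = np.array([config.phase_fractions[p] for p in phases])
    records = []
    gi = 0
    for ci, chrom in enumerate(chrom_names):
        for si in range(per_chrom):
            if gi >= config.n_genes:
                break
            strand = "+" if gi % 2 == 0 else "-"  # both strands guaranteed
            # promoter (upstream of the start codon) stays inside the slot,
            # so gene regions of neighbouring genes never overlap
            if strand == "+":
                start = si * slot + config.promoter_len
            else:
                start = si * slot + slot - config.promoter_len - config.gene_len
            end = start + config.gene_len
            phase = str(rng.choice(phases, p=probs))
            records.append((f"gene{gi + 1:04d}", chrom, start, end, strand, phase))
            gi += 1
    genes = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand", "phase"]
    )
    annotation = GeneAnnotation(genes, {c: config.chrom_len for c in chrom_names})
    return sequences, annotation


def make_pwms(config: SimConfig, rng: np.random.Generator | None = None) -> list[PWM]:
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    return [random_pwm(tf, config.motif_width, rng) for tf in config.tf_ids]


# ---------------------------------------------------------------------
# motif planting


def plant_motifs(
    sequences: dict[str, str],
    annotation: GeneAnnotation,
    pwms: list[PWM],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], TruthTable]:
    """Write consensus motif instances into promoters.

    A TF with a planted phase hits every promoter of that phase's genes (plus
    a small off-phase background rate); an unassigned TF hits random
    promoters at the background rate regardless of phase. The truth table
    records exactly the instances written (later plants may clobber earlier
    overlapping ones only by chance; offsets are drawn over the whole
    plantable window to keep collisions rare).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    seqs = {c: list(s) for c, s in sequences.items()}
    promoters = annotation.promoters(config.promoter_len).set_index("gene_id")
    gene_info = annotation.genes.set_index("gene_id")
    truth_rows = []
    bound: dict[str, set] = {tf: set() for tf in (p.tf_id for p in pwms)}
    for pwm in pwms:
        planted_phase = config.planted_tf_phase.get(pwm.tf_id)
        consensus = pwm.consensus
        w = pwm.width
        for gene_id, prom in promoters.iterrows():
            phase = gene_info.loc[gene_id, "phase"]
            if planted_phase is not None and phase == planted_phase:
                plant = True
            else:
                plant = rng.random() < config.background_site_prob
            if not plant:
                continue
            lo, hi = int(prom["start"]), int(prom["end"])
            if hi - lo < w:
                logger.warning("promoter of %s too short for motif %s", gene_id, pwm.tf_id)
                continue
            pos = int(rng.integers(lo, hi - w + 1))
            strand = gene_info.loc[gene_id, "strand"]
            inst = consensus if strand == "+" else reverse_complement(consensus)
            seqs[prom["chrom"]][pos : pos + w] = list(inst)
            truth_rows.append((pwm.tf_id, prom["chrom"], pos, pos + w, strand, phase))
            bound[pwm.tf_id].add(gene_id)
    planted = pd.DataFrame(
        truth_rows, columns=["tf_id", "chrom", "start", "end", "strand", "phase"]
    )
    truth = TruthTable(
        planted_sites=planted,
        de_genes=pd.DataFrame(columns=["gene_id", "direction", "log2fc"]),
        phase_labels=annotation.phase_labels(),
        bound_genes_truth=bound,
    )
    return {c: "".join(s) for c, s in seqs.items()}, truth


# ---------------------------------------------------------------------
# signal tracks


class SignalTracks:
    """Per-base signal per time point: ``values[chrom]`` has shape (T, L)."""

    def __init__(self, values: dict[str, np.ndarray], timepoints: list[str]):
        self.values = values
        self.timepoints = timepoints

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def window_mean(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self.values[chrom]
        start, end = max(0, start), min(arr.shape[1], end)
        if end <= start:
            return np.full(self.n_timepoints, np.nan)
        return arr[:, start:end].mean(axis=1)


def simulate_signal_tracks(
    truth: TruthTable,
    chrom_sizes: dict[str, int],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    site_halfwidth: int = 50,
) -> SignalTracks:
    """Histone-signal tracks: each planted site carries its phase's temporal
    template (plus Gaussian noise, truncated at 0); background is baseline."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    T = config.n_timepoints_signal
    templates = phase_templates(T)
    values = {}
    for chrom, L in chrom_sizes.items():
        base = np.full((T, L), TEMPLATE_BASELINE, dtype=np.float32)
        if config.signal_noise_sd > 0:
            base += rng.normal(0.0, config.signal_noise_sd, size=(T, L)).astype(np.float32)
        values[chrom] = np.maximum(base, 0.0)
    for _, site in truth.planted_sites.iterrows():
        tmpl = templates[site["phase"]]
        lo = max(0, int(site["start"]) - site_halfwidth)
        hi = min(chrom_sizes[site["chrom"]], int(site["end"]) + site_halfwidth)
        width = hi - lo
        block = tmpl[:, None] + (
            rng.normal(0.0, config.signal_noise_sd, size=(len(tmpl), width))
            if config.signal_noise_sd > 0
            else 0.0
        )
        values[site["chrom"]][:, lo:hi] = np.maximum(block, 0.0)
    return SignalTracks(values, [f"t{i + 1}" for i in range(T)])


# ---------------------------------------------------------------------
# ChIP peaks


def signal_peak_regions(
    truth: TruthTable,
    chrom_sizes: dict[str, int],
    halfwidth: int = 50,
    pad: int = 20,
) -> pd.DataFrame:
    """Histone-signal peak intervals: the (merged) windows around planted
    sites where the simulator wrote phase templates, padded by ``pad`` bp.
    These are the regions motif scanning operates within."""
    from .intervals import merge_intervals, clip_to_chrom

    sites = truth.planted_sites
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["start"] - halfwidth - pad,
            "end": sites["end"] + halfwidth + pad,
        }
    )
    return merge_intervals(clip_to_chrom(df, chrom_sizes))


def split_shared_sites(
    sites: pd.DataFrame, share: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each site to both TFs with probability ``share``, otherwise to
    exactly one of them (fair coin)."""
    u = rng.random(len(sites))
    both = u < share
    to_a = both | (rng.random(len(sites)) < 0.5)
    to_b = both | ~to_a
    return sites[to_a].reset_index(drop=True), sites[to_b].reset_index(drop=True)


def simulate_tf_peaks(
    sites: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    tf_phase: str = "RC",
) -> dict[str, pd.DataFrame]:
    """Per-time-point peak intervals centred on a TF's sites: present with
    high probability at time points of the TF's phase, low elsewhere."""
    rng = rng if rng is not None else np.random.default_rng(0)
    out = {}
    for ti, tp_phase in enumerate(CHIP_TIMEPOINT_PHASES):
        prob = config.peak_rc_prob if tp_phase == tf_phase else config.peak_bg_prob
        present = rng.random(len(sites)) < prob
        sub = sites[present]
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        out[f"tp{ti + 1}"] = pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "start": np.maximum(mid - config.peak_halfwidth, 0),
                "end": mid + config.peak_halfwidth,
            }
        )
    return out


# ---------------------------------------------------------------------
# count matrices


def _sample_meta(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i, ph in enumerate(config.wt_sample_phases):
        rows.append((f"WT{i + 1}", "WT", i + 1, ph))
    for i, ph in enumerate(config.mut_sample_phases):
        rows.append((f"Mut{i + 1}", "mutant", i + 1, ph))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "time_index", "phase"])


def simulate_count_matrices(
    annotation: GeneAnnotation,
    truth: TruthTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Phase-structured NB counts for the WT and mutant time courses.

    A gene's mean is ``nb_mean``, multiplied by ``phase_amp`` in samples of
    its own phase. The designated pathway (``pathway_size`` genes drawn from
    the planted TF's bound RC genes, padded from other RC genes) is shifted
    by ``-de_log2fc`` in mutant RC samples. Per-sample library-size factors
    are log-uniform in [0.7, 1.4].
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    meta = _sample_meta(config)
    genes = annotation.genes
    gene_ids = genes["gene_id"].to_numpy()
    phases = genes["phase"].to_numpy()

    rc_genes = [g for g, p in zip(gene_ids, phases) if p == "RC"]
    planted_tfs = [tf for tf, ph in config.planted_tf_phase.items() if ph == "RC"]
    bound_rc = sorted(
        set().union(*(truth.bound_genes_truth.get(tf, set()) for tf in planted_tfs))
        & set(rc_genes)
    ) if planted_tfs else []
    pathway = list(bound_rc[: config.pathway_size])
    for g in rc_genes:
        if len(pathway) >= config.pathway_size:
            break
        if g not in pathway:
            pathway.append(g)
    if config.de_log2fc != 0:
        de = pd.DataFrame(
            {"gene_id": pathway, "direction": "down", "log2fc": -config.de_log2fc}
        )
    else:
        de = pd.DataFrame(columns=["gene_id", "direction", "log2fc"])
    truth.de_genes = de
    de_set = set(de["gene_id"])

    sf = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=len(meta)))
    counts = np.zeros((len(gene_ids), len(meta)), dtype=int)
    n_disp = 1.0 / config.nb_dispersion
    for si, (sample, genotype, _, s_phase) in enumerate(meta.itertuples(index=False)):
        mu = np.where(phases == s_phase, config.nb_mean * config.phase_amp, config.nb_mean)
        if genotype == "mutant" and s_phase == "RC" and de_set:
            is_de = np.isin(gene_ids, list(de_set))
            mu = np.where(is_de, mu * 2.0 ** (-config.de_log2fc), mu)
        mu = mu * sf[si]
        counts[:, si] = rng.negative_binomial(n_disp, n_disp / (n_disp + mu))
    mat = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=meta["sample_id"])
    wt = mat[[s for s in meta["sample_id"] if s.startswith("WT")]]
    mut = mat[[s for s in meta["sample_id"] if s.startswith("Mut")]]
    return wt, mut, meta, truth


# ---------------------------------------------------------------------
# conservation


def simulate_conservation_track(
    annotation: GeneAnnotation,
    orf_mean: float = 0.8,
    promoter_mean: float = 0.5,
    noise: float = 0.05,
    background_mean: float = 0.3,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Per-base conservation scores: clipped Gaussians around region means."""
    for m in (orf_mean, promoter_mean, background_mean):
        if not 0.0 <= m <= 1.0:
            raise ValueError("region means must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)
    track = {}
    for chrom, L in annotation.chrom_sizes.items():
        v = np.full(L, background_mean) + (rng.normal(0, noise, L) if noise > 0 else 0.0)
        track[chrom] = v
    for regions, mean in (
        (annotation.promoters(500), promoter_mean),
        (annotation.orf_regions(), orf_mean),
    ):
        for _, r in regions.iterrows():
            n = int(r["end"]) - int(r["start"])
            block = np.full(n, mean) + (rng.normal(0, noise, n) if noise > 0 else 0.0)
            track[r["chrom"]][int(r["start"]) : int(r["end"])] = block
    return {c: np.clip(v, 0.0, 1.0) for c, v in track.items()}


# ---------------------------------------------------------------------
# one-call bundle + on-disk emission


@dataclass
class SimResult:
    config: SimConfig
    sequences: dict[str, str]
    annotation: GeneAnnotation
    pwms: list[PWM]
    truth: TruthTable
    tracks: SignalTracks
    peaks: dict[str, dict[str, pd.DataFrame]]  # tf -> time point -> intervals
    wt_counts: pd.DataFrame
    mut_counts: pd.DataFrame
    sample_meta: pd.DataFrame
    conservation: dict[str, np.ndarray]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.annotation.chrom_sizes


def simulate_all(config: SimConfig | None = None) -> SimResult:
    """Run the whole generator off one seed; deterministic end to end."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    sequences, annotation = generate_genome(config, rng)
    pwms = make_pwms(config, rng)
    sequences, truth = plant_motifs(sequences, annotation, pwms, config, rng)
    tracks = simulate_signal_tracks(truth, annotation.chrom_sizes, config, rng)
    planted_tfs = [tf for tf in config.planted_tf_phase]
    peaks: dict[str, dict[str, pd.DataFrame]] = {}
    if planted_tfs:
        # two partially overlapping ChIP'd TFs built over the first planted
        # TF's true sites (the Msn2/Msn4-style homolog pair)
        anchor = planted_tfs[0]
        anchor_phase = config.planted_tf_phase[anchor]
        sites = truth.planted_sites.query("tf_id == @anchor and phase == @anchor_phase")
        a, b = split_shared_sites(sites, config.tf_peak_share, rng)
        peaks[f"{anchor}a"] = simulate_tf_peaks(a, config, rng, tf_phase=anchor_phase)
        peaks[f"{anchor}b"] = simulate_tf_peaks(b, config, rng, tf_phase=anchor_phase)
    wt, mut, meta, truth = simulate_count_matrices(annotation, truth, config, rng)
    conservation = simulate_conservation_track(annotation, rng=rng)
    return SimResult(
        config=config,
        sequences=sequences,
        annotation=annotation,
        pwms=pwms,
        truth=truth,
        tracks=tracks,
        peaks=peaks,
        wt_counts=wt,
        mut_counts=mut,
        sample_meta=meta,
        conservation=conservation,
    )


def write_simulation(result: SimResult, outdir: str | Path) -> None:
    """Emit every modality as plain-text files (FASTA/BED/TSV/MEME/bedGraph/wig)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_fasta(out / "genome.fa", result.sequences)
    _io.write_bed(out / "genes.bed", result.annotation.to_bed())
    _io.write_tsv(out / "genes.tsv", result.annotation.to_sidecar())
    _io.write_meme(out / "motifs.meme", result.pwms)
    for ti, tp in enumerate(result.tracks.timepoints):
        _io.write_bedgraph(
            out / f"signal_{tp}.bedgraph",
            {c: v[ti] for c, v in result.tracks.values.items()},
        )
    for tf, by_tp in result.peaks.items():
        for tp, df in by_tp.items():
            _io.write_bed(out / f"peaks_{tf}_{tp}.bed", df)
    _io.write_counts(out / "counts_wt.tsv", result.wt_counts)
    _io.write_counts(out / "counts_mut.tsv", result.mut_counts)
    _io.write_tsv(out / "samples.tsv", result.sample_meta)
    _io.write_tsv(out / "truth_sites.tsv", result.truth.planted_sites)
    _io.write_tsv(out / "truth_de.tsv", result.truth.de_genes)
    _io.write_wig(out / "conservation.wig", result.conservation)
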