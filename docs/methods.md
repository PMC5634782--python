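# Methods

This note documents the models, conventions and numerical choices behind
`ymcregulon`, and what the synthetic study does and does not establish.

## Coordinate conventions

All interval files and in-memory interval tables are 0-based half-open (BED
convention). A gene is a half-open genomic span `[start, end)` plus strand;
in gene orientation the start codon occupies the first three bases and the
stop codon the last three. Every region rule orients "upstream" 5′ of the
start codon:

| region | + strand | − strand |
|---|---|---|
| extended gene region (u bp) | `[start−u, end)` | `[start, end+u)` |
| promoter (L bp) | `[start−L, start)` | `[end, end+L)` |
| ORF | `[start, end)` | `[start, end)` |

Regions are clipped at chromosome bounds. The annotation TSV sidecar stores
1-based inclusive positions of the first base of each codon (in gene
orientation); readers convert back to spans. Overlap always means ≥ 1 bp;
bookended intervals (`[a,b)` + `[b,c)`) are merged by default when peaks are
combined across time points (configurable off), because combining peak calls
is a union operation, not an adjacency test.

## Motif model and scanning

A PWM is a `w × 4` matrix of per-position base probabilities. Before
scoring, a pseudocount (default 0.01 per base) is added and rows
renormalised, avoiding −∞ log-odds; windows are scored on both strands as
`Σᵢ log₂ p′ᵢ(bᵢ)/bg(bᵢ)` bits, with non-ACGT bases contributing 0 (scored
at background). The default site threshold is **60% of the PWM's maximum
achievable score**: a relative threshold keeps sensitivity comparable
across motif widths, where a fixed bit cutoff would not. Overlapping
same-strand hits of one PWM are collapsed greedily, best score first and
leftmost on ties. Scanning operates inside histone-signal peak regions:
the premise of the method is that regulatory sites live under dynamic
acetylation peaks, and restricting the search space is also what keeps the
temporal clustering from being dominated by background-noise profiles.

## Temporal profiles and clustering

The profile of a site is the mean signal over its midpoint ± flank
(default 50 bp; flank 0 reads the site's own span) at each of the T = 16
time points, standardized per profile to mean 0, sd 1 (constant profiles
map to all-zeros). Standardization is on by default because the object of
interest is the *shape* of the temporal pattern, not its amplitude.
Clustering is k-means (scikit-learn, `n_init` restarts, fixed
`random_state`), k = 3 by default to match the three metabolic phases;
clusters are relabelled by centroid peak time so cluster 0 always peaks
earliest — this makes labels stable across initialisations for
well-separated patterns. Degenerate inputs (fewer distinct profiles than k)
return with a logged warning rather than failing.

TF-per-cluster enrichment is a one-sided hypergeometric upper tail with the
site universe as background, BH-corrected over all (TF, cluster) pairs;
candidates are pairs below FDR 0.05. With ~24 tests and one strong true
positive, BH at 0.05 admits a second, borderline pair in a minority of
random instances — that is the designed behaviour of FDR control, not a
defect, and it is why the enrichment table reports effect sizes
(`in_cluster / tf_total`) alongside the FDR.

## Differential expression

Size factors are median-of-ratios: per-gene geometric means across samples
(genes containing any zero excluded) form the reference; a sample's factor
is the median ratio to it. Factors are defined only up to a global
constant, so the meaningful invariance is that scaling one sample's counts
by c scales its factor *relative to any other sample* by exactly c.

**Pairwise (no-replicate) test.** Each of the eleven WT–mutant pairings has
one sample per side. The two contrasted samples are treated as replicates:
a per-gene method-of-moments dispersion is computed from their normalized
difference, a trend `α(μ) = a₀ + a₁/μ` is fitted across genes by
non-negative least squares with one outlier-trimming refit (points > 10×
the first fit are dropped — genuinely differential genes must inflate
neither the intercept nor the slope), and each gene uses the *fitted*
value. This is deliberately conservative: real signal between the two
samples can only push the trend up. The p-value is a two-sided conditional
exact test: given the pair's count sum `s = k_A + k_B` and NB marginals
`NB(μ_A, α)`, `NB(μ_B, α)`, every split `(a, s−a)` whose probability is ≤
that of the observed split contributes. Log2 fold changes use normalized
counts with pseudocount 0.5.

**Group test.** The RC-phase contrast (5 WT vs 9 mutant samples) has real
replicates: per-gene pooled method-of-moments dispersions are shrunk
conservatively to `max(per-gene, trend)`, and the same exact test is
applied to group sums using the identity that a sum of n iid `NB(μ, α)`
variables is `NB(nμ, α/n)` (exact under equal size factors, an
approximation otherwise).

Each comparison is BH-adjusted on its own and thresholded at padj < 0.01;
the union over the 12 comparisons defines the differential set. Direction
is the majority sign among a gene's significant comparisons; exact ties are
reported as conflicted and excluded from the up/down sets.

Phase labels pass through from an external file when given; otherwise a
gene is assigned the phase whose sample-indicator template best correlates
(Pearson, on the standardized WT profile), with "other" below r = 0.5 or
for flat profiles.

## Permutation pathway enrichment

Features (motif sites, or sites overlapping ChIP peaks) are counted once
each when they overlap any 1000 bp-extended gene region of a gene set. The
null redraws same-size gene sets N times (default 100) without replacement.
Two p-values are reported: the add-one empirical p
`(1 + #{null ≥ obs})/(N + 1)`, whose floor at N = 100 is 1/101 ≈ 0.0099,
and the upper-tail normal p from the null's z-score. Magnitudes far below
the empirical floor (10⁻⁵ and beyond) are only reachable through the
normal approximation or by raising `--n-perm`; both routes are exposed and
the output labels which is which. A degenerate null (sd = 0) leaves z
undefined and reports p_normal = 1 (or the N-based floor when the observed
count exceeds the null) with a warning.

## Conservation averaging

Stage 1 averages scores over each gene's region bases, skipping missing
bases (never zero-filling); genes with no covered base are excluded and
reported. Stage 2 averages per-gene means within a group *unweighted* by
gene length; the base-weighted alternative is emitted alongside, and the
two coincide exactly when all regions share one length. Unweighted
averaging was chosen so a single long gene cannot dominate a group mean.

## The synthetic study

The generator emulates the structure of the real experiment at desk scale:

* **Genome**: 2 chromosomes × 200 kb, 200 non-overlapping genes laid out on
  equal slots, alternating strands, each slot reserving 1000 bp of promoter
  on the gene's 5′ side so neighbouring gene regions never collide. Phase
  labels are drawn from fractions OX 0.25 / RB 0.25 / RC 0.30 / other 0.20.
* **Signal**: three raised-cosine temporal templates over the 16-point
  axis (OX = points 1–5, RB = 6–10, RC = 11–16), baseline 1.0, peak 10.0;
  each planted site carries its phase's template ± Gaussian noise
  (default sd 1.0 = 10% of peak), truncated at 0; background is baseline
  noise.
* **Motifs**: 6 TFs, width 8, consensus base probability 0.85. TF1 is
  planted in every RC-gene promoter; every TF additionally hits off-phase
  promoters at rate 0.03 — enough to exercise the background paths without
  letting noise profiles dominate the clusters.
* **ChIP**: TF1's RC sites are split between two "homolog" TFs sharing 60%
  of sites; peaks (± 100 bp of the site midpoint) appear with probability
  0.95 at RC time points of a 6-point axis and 0.05 elsewhere.
* **Counts**: negative binomial with shared dispersion 0.05; a gene's mean
  is 200, ×4 in samples of its own phase; WT samples are OX, RB, then five
  RC; mutant samples OX, RB, then nine RC (the lengthened quiescent phase);
  the 33-gene pathway (RC genes bound by the planted TF) is shifted by
  −3 log₂ units in mutant RC samples; per-sample library factors are
  log-uniform in [0.7, 1.4] to exercise normalization.
* **Conservation**: ORF bases around mean 0.8, promoters 0.5, background
  0.3, Gaussian noise 0.05, clipped to [0, 1].

What passing on this study shows: the coordinate arithmetic, statistics and
plumbing are correct, calibrated on NB counts, and recover planted signal
of realistic effect size. What it does not show: robustness to real-data
features the generator omits — mappability artefacts, copy-number and GC
biases, overlapping/nested genes, motif self-similarity between TFs,
non-NB overdispersion structure, and peak-calling noise (peaks here are
inputs by design).

## Problem sizes

Defaults were chosen so the whole suite runs in about a minute and the
acceptance script in well under one: 200-gene genomes for end-to-end runs,
a 2000-gene genome for DE null calibration, 100-permutation nulls, and
exhaustive-enumeration oracles on universes of ≤ 25 genes. All stochastic
stages flow from a single seed through `numpy.random.default_rng`; equal
configurations produce byte-identical output files.

## Known limitations

* The pairwise exact test enumerates all splits of a pair's count sum;
  runtime grows linearly with counts and becomes noticeable above means of
  a few thousand.
* The group exact test treats unequal size factors approximately (sums of
  NB variables with unequal means are not exactly NB).
* The Venn overlap counts are reported from both sides because peak-to-peak
  overlap is many-to-one; the single "shared" number shown in two-set
  diagrams is the minimum of the two.
* `target_similarity` reads "total targets" as the union (Jaccard); the
  average-size denominator is a defensible alternative and would scale all
  similarities monotonically.
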