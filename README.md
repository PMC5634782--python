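# ymcregulon

Tools for discovering **phase-specific transcription-factor regulators of the
yeast metabolic cycle (YMC)** and characterizing the regulon of the
quiescence-phase stress factors Msn2/Msn4, together with a ground-truth
synthetic-data generator that makes every stage testable without any
external downloads.

In a glucose-limited chemostat, budding yeast synchronize into a respiratory
oscillation with three transcriptional phases: **OX** (oxidative / growth),
**RB** (reductive building / proliferation) and **RC** (reductive charging /
quiescence). The package implements the computational chain used to ask
*which TFs drive each phase* and *what the RC-phase regulators actually
regulate*:

1. **Dynamic motif analysis** — scan position weight matrices (PWMs) over
   histone-acetylation (H3K9ac) peak regions on both strands
   (log-odds score `Σᵢ log₂ p′ᵢ(bᵢ)/bg(bᵢ)` ≥ a fixed fraction of the PWM
   maximum), read out the temporal H3K9ac signal at each site across 16 time
   points, k-means-cluster the standardized profiles into dynamic classes
   (relabelled by peak time), and test each TF for over-representation of
   its sites in each class with a one-sided hypergeometric test,
   BH-corrected. Targets are genes whose strand-aware
   `[start codon − 1000 bp, stop codon]` region overlaps a site; TF–TF
   similarity is the Jaccard index of target sets.
2. **ChIP-seq target assignment** — merge a TF's peaks across time points,
   count two-TF Venn overlaps, and call a gene *bound* when its
   `[start codon − 700 bp, stop codon]` region overlaps ≥ 1 bp of a merged
   peak.
3. **Time-matched differential expression** — a 7-time-point wild type vs an
   11-time-point *msn2Δ msn4Δ* mutant; eleven single-sample pairings
   (absolute-time then relative-RC-time matches) tested with a conditional
   exact negative-binomial test under a fitted mean–dispersion trend
   (no-replicate convention), plus a replicated 5-WT vs 9-mutant RC-group
   contrast; per-comparison BH at padj < 0.01; the union over all 12
   comparisons gives up-/down-regulated sets with majority-sign direction
   calls.
4. **Integration** — *core targets* = bound ∧ differentially expressed
   (bound ∧ down = activated regulon); phase composition of gene sets;
   Fisher-exact gene-set/GO enrichment with BH FDR; phase × condition
   overlap matrices.
5. **Permutation pathway enrichment** — count motif sites falling in the
   1000 bp-extended regions of a pathway's genes and compare against N
   (default 100) random same-size gene sets; reports the add-one empirical
   p `(1 + #{null ≥ obs})/(N + 1)` and a normal-approximation tail p from
   the null z-score. Includes the 200 bp DNase bin filter used for the
   human-genome variant of the analysis.
6. **Conservation** — two-stage averaging of per-base conservation scores
   (phastCons-style) over promoters (0–500 bp upstream) and ORFs.

The `simulate` module generates a miniature genome with phase-labelled
genes, plants TF consensus sites in the promoters of their assigned phase,
emits per-time-point signal tracks following three raised-cosine phase
templates, builds two partially overlapping RC-biased ChIP peak sets,
draws negative-binomial count matrices with a down-regulated 33-gene
"glycolysis-like" pathway, and writes a conservation track elevated over
ORFs — all byte-reproducible from one seed, with a truth table recording
every planted site, bound gene and differential gene.

## Worked example

```python
import pandas as pd
import ymcregulon as y
from ymcregulon.simulate import signal_peak_regions

sim = y.simulate_all(y.SimConfig())            # default study, seed 42

# 1. dynamic motif stage
regions = signal_peak_regions(sim.truth, sim.chrom_sizes)
sites = pd.concat([y.scan_motifs(sim.sequences, p, regions) for p in sim.pwms],
                  ignore_index=True)
profiles = y.extract_profiles(sites, sim.tracks, flank=50)
clustering = y.cluster_profiles(profiles, k=3, seed=0)
enr = y.tf_cluster_enrichment(clustering, sites)
print(enr[enr.candidate][["tf_id", "cluster", "in_cluster", "tf_total", "fdr"]])
#   tf_id  cluster  in_cluster  tf_total           fdr
# 2   TF1        2         105       110  6.174105e-07

# 2-4. ChIP binding, differential expression, core targets
merged = {tf: y.merge_time_peaks(list(d.values())) for tf, d in sim.peaks.items()}
bound = y.bound_genes(merged, sim.annotation.gene_regions(700))
de = y.run_design(sim.wt_counts, sim.mut_counts)
core = y.core_targets(bound.union(), de.up, de.down, sim.truth.phase_labels)
print(len(de.down), len(core.activated))
# 33 22
```

The enrichment table says: of TF1's 110 scanned motif sites, 105 fall in
cluster 2 — the latest-peaking (RC/quiescence) temporal class — and no other
TF is enriched anywhere: the planted RC regulator is recovered. The DE stage
finds exactly the 33 planted pathway genes down-regulated in the mutant, and
22 of them are also ChIP-bound, forming the activated core regulon (the
remainder carry their planted site more than 700 bp upstream, outside the
bound-gene window — mirroring how binding and expression evidence overlap
only partially in practice).

The same pipeline is exposed as a CLI (`ymcregulon simulate | scan |
profile | cluster | enrich-tf | merge-peaks | venn | bind-genes |
pathway-binding | de | core-targets | enrich-go | phase-comp | quiescence |
perm-enrich | conserve`), reading and writing FASTA, BED, bedGraph,
fixedStep wiggle, MEME-minimal and TSV files.

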