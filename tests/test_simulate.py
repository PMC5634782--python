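"""Generator contracts: construction guarantees, determinism, truth bookkeeping,
and the noise-free limits every downstream stage relies on."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ymcregulon as y
from ymcregulon.simulate import (
    CHIP_TIMEPOINT_PHASES,
    TEMPLATE_BASELINE,
    TEMPLATE_PEAK,
    phase_templates,
    generate_genome,
    make_pwms,
    plant_motifs,
    simulate_signal_tracks,
    simulate_tf_peaks,
    split_shared_sites,
    simulate_conservation_track,
    signal_peak_regions,
)


class TestGenerateGenome:
    def test_gene_count_and_both_strands(self, tiny_config):
        _, anno = generate_genome(tiny_config)
        assert len(anno) == tiny_config.n_genes
        assert set(anno.genes["strand"]) == {"+", "-"}

    def test_sequences_have_stated_length_and_alphabet(self, tiny_config):
        seqs, _ = generate_genome(tiny_config)
        assert all(len(s) == tiny_config.chrom_len for s in seqs.values())
        assert set("".join(seqs.values())) <= set("ACGT")

    def test_genes_non_overlapping(self, tiny_config):
        _, anno = generate_genome(tiny_config)
        g = anno.genes.sort_values(["chrom", "start"])
        for _, sub in g.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_degenerate_phase_fractions(self):
        cfg = y.SimConfig(
            n_chroms=1, chrom_len=120_000, n_genes=50,
            phase_fractions={"OX": 0.0, "RB": 0.0, "RC": 1.0, "other": 0.0},
        )
        _, anno = generate_genome(cfg)
        assert (anno.genes["phase"] == "RC").all()

    def test_sizing_error(self):
        cfg = y.SimConfig(n_chroms=1, chrom_len=10_000, n_genes=50)
        with pytest.raises(ValueError, match="too small"):
            generate_genome(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            y.SimConfig(phase_fractions={"OX": 0.5, "RB": 0.1, "RC": 0.1, "other": 0.1})
        with pytest.raises(ValueError):
            y.SimConfig(motif_width=3)


class TestDeterminism:
    def test_seeded_runs_byte_identical(self, tmp_path, tiny_config):
        for d in ("a", "b"):
            y.write_simulation(y.simulate_all(tiny_config), tmp_path / d)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seed_differs(self, tiny_config):
        r1 = y.simulate_all(tiny_config)
        cfg2 = y.SimConfig(**{**tiny_config.__dict__, "seed": 12})
        r2 = y.simulate_all(cfg2)
        assert r1.sequences != r2.sequences


class TestPlantMotifs:
    def test_truth_rows_match_written_instances(self, default_sim):
        truth = default_sim.truth.planted_sites
        for _, s in truth.sample(50, random_state=0).iterrows():
            written = default_sim.sequences[s["chrom"]][s["start"] : s["end"]]
            pwm = next(p for p in default_sim.pwms if p.tf_id == s["tf_id"])
            expected = pwm.consensus
            if s["strand"] == "-":
                from ymcregulon.motifs import reverse_complement

                expected = reverse_complement(expected)
            assert written == expected

    def test_planted_phase_sites_in_matching_promoters(self, tiny_config):
        seqs, anno = generate_genome(tiny_config)
        pwms = make_pwms(tiny_config)
        cfg = y.SimConfig(**{**tiny_config.__dict__, "background_site_prob": 0.0})
        _, truth = plant_motifs(seqs, anno, pwms, cfg)
        planted = truth.planted_sites.query("tf_id == 'TF1'")
        assert len(planted) > 0
        assert (planted["phase"] == "RC").all()

    def test_scan_recovers_planted_sites(self, default_sim, scanned_sites):
        truth = default_sim.truth.planted_sites
        key = ["tf_id", "chrom", "start", "strand"]
        hit = truth.merge(scanned_sites[key].drop_duplicates(), on=key)
        assert len(hit) / len(truth) >= 0.95


class TestSignalTracks:
    def test_zero_noise_site_equals_template(self, tiny_config):
        cfg = y.SimConfig(**{**tiny_config.__dict__, "signal_noise_sd": 0.0})
        res = y.simulate_all(cfg)
        templates = phase_templates(cfg.n_timepoints_signal)
        site = res.truth.planted_sites.iloc[0]
        vec = res.tracks.values[site["chrom"]][:, site["start"]]
        np.testing.assert_allclose(vec, templates[site["phase"]], rtol=1e-6)

    def test_template_argmax_in_phase_window(self):
        templates = phase_templates(16)
        for phase, (lo, hi) in {"OX": (0, 5), "RB": (5, 10), "RC": (10, 16)}.items():
            assert lo <= int(np.argmax(templates[phase])) < hi
        assert templates["OX"].max() == pytest.approx(TEMPLATE_PEAK, abs=1.5)
        assert templates["other"].min() == TEMPLATE_BASELINE

    def test_noisy_profiles_correlate_with_own_template(self, rng):
        cfg = y.SimConfig(n_chroms=1, chrom_len=120_000, n_genes=50,
                          signal_noise_sd=0.1 * TEMPLATE_PEAK, seed=5,
                          phase_fractions={"OX": 0.3, "RB": 0.3, "RC": 0.4, "other": 0.0})
        res = y.simulate_all(cfg)
        templates = phase_templates(cfg.n_timepoints_signal)
        prof = y.extract_profiles(res.truth.planted_sites, res.tracks, flank=50,
                                  standardize=False)
        n_ok = 0
        sites = res.truth.planted_sites
        for i in range(len(sites)):
            r = np.corrcoef(prof.iloc[i], templates[sites.iloc[i]["phase"]])[0, 1]
            n_ok += r > 0.9
        assert n_ok / len(sites) >= 0.99


class TestTfPeaks:
    def test_full_share_identical_sets(self, rng):
        sites = pd.DataFrame({"chrom": "chr1", "start": np.arange(0, 1000, 10),
                              "end": np.arange(8, 1008, 10)})
        a, b = split_shared_sites(sites, 1.0, rng)
        pd.testing.assert_frame_equal(a, b)

    def test_share_fraction_binomial(self, rng):
        sites = pd.DataFrame({"chrom": "chr1", "start": np.arange(0, 10000, 100),
                              "end": np.arange(8, 10008, 100)})
        a, b = split_shared_sites(sites, 0.6, rng)
        shared = len(set(a["start"]) & set(b["start"]))
        lo, hi = stats.binom.ppf([0.025, 0.975], 100, 0.6)
        assert lo <= shared <= hi

    def test_degenerate_presence_probabilities(self, rng):
        sites = pd.DataFrame({"chrom": "chr1", "start": [100, 300], "end": [108, 308]})
        cfg = y.SimConfig(peak_rc_prob=1.0, peak_bg_prob=0.0)
        peaks = simulate_tf_peaks(sites, cfg, rng)
        for tp, phase in zip(peaks, CHIP_TIMEPOINT_PHASES):
            assert len(peaks[tp]) == (len(sites) if phase == "RC" else 0)


class TestCountMatrices:
    def test_null_config_empty_truth(self, tiny_config):
        cfg = y.SimConfig(**{**tiny_config.__dict__, "de_log2fc": 0.0})
        res = y.simulate_all(cfg)
        assert len(res.truth.de_genes) == 0

    def test_non_de_gene_means_agree_across_genotypes(self):
        # CLT oracle: pooled over ~1000 (gene, genotype) normalized draws, a
        # non-DE gene's mean is shared between genotypes
        cfg = y.SimConfig(n_chroms=2, chrom_len=1_000_000, n_genes=1000, nb_mean=500,
                          seed=3)
        res = y.simulate_all(cfg)
        sf = y.size_factors(pd.concat([res.wt_counts, res.mut_counts], axis=1))
        norm_wt = res.wt_counts / sf[res.wt_counts.columns]
        norm_mut = res.mut_counts / sf[res.mut_counts.columns]
        other = res.annotation.genes.query("phase == 'other'")["gene_id"]
        diffs = (norm_wt.loc[other].mean(axis=1) - norm_mut.loc[other].mean(axis=1)).to_numpy()
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se

    def test_planted_fold_change_recovered(self):
        cfg = y.SimConfig(n_chroms=1, chrom_len=400_000, n_genes=200, nb_mean=500,
                          de_log2fc=2.0, seed=9)
        res = y.simulate_all(cfg)
        sf_wt = y.size_factors(res.wt_counts)
        sf_mut = y.size_factors(res.mut_counts)
        de_gene = res.truth.de_genes["gene_id"].iloc[0]
        wt_rc = [s for s, p in zip(res.wt_counts.columns, cfg.wt_sample_phases) if p == "RC"]
        mut_rc = [s for s, p in zip(res.mut_counts.columns, cfg.mut_sample_phases) if p == "RC"]
        wt_mean = (res.wt_counts.loc[de_gene, wt_rc] / sf_wt[wt_rc]).mean()
        mut_mean = (res.mut_counts.loc[de_gene, mut_rc] / sf_mut[mut_rc]).mean()
        assert mut_mean / wt_mean == pytest.approx(2 ** (-cfg.de_log2fc), rel=0.35)


class TestConservationTrack:
    def test_zero_noise_exact_means(self, tiny_config):
        _, anno = generate_genome(tiny_config)
        track = simulate_conservation_track(anno, orf_mean=0.8, promoter_mean=0.5, noise=0.0)
        orf = anno.orf_regions().iloc[0]
        assert np.allclose(track[orf["chrom"]][orf["start"] : orf["end"]], 0.8)

    def test_scores_clipped_to_unit_interval(self, default_sim):
        for v in default_sim.conservation.values():
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_invalid_mean_rejected(self, tiny_config):
        _, anno = generate_genome(tiny_config)
        with pytest.raises(ValueError):
            simulate_conservation_track(anno, orf_mean=1.5)


def test_signal_peak_regions_cover_all_planted_sites(default_sim):
    regions = signal_peak_regions(default_sim.truth, default_sim.chrom_sizes)
    from ymcregulon.intervals import _overlap_mask

    sites = default_sim.truth.planted_sites[["chrom", "start", "end"]]
    assert _overlap_mask(sites, regions).all()
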