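"""Normalization, FPKM, the no-replicate exact NB test (calibration, symmetry,
power), the 12-comparison design union, direction calls and phase assignment.

The replicated RC-group comparison is additionally cross-checked against an
independent NB differential-expression engine (pydeseq2) on simulated data.
"""

import numpy as np
import pandas as pd
import pytest

import ymcregulon as y
from ymcregulon.expression import DEFAULT_PAIRS


@pytest.fixture(scope="module")
def null_sim():
    cfg = y.SimConfig(n_chroms=2, chrom_len=2_000_000, n_genes=2000,
                      de_log2fc=0.0, seed=7)
    return y.simulate_all(cfg)


class TestSizeFactors:
    def test_doubled_sample_ratio(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(100, 500)
        counts = pd.DataFrame({"s1": a, "s2": 2 * a})
        f = y.size_factors(counts)
        assert f["s2"] / f["s1"] == pytest.approx(2.0, rel=1e-9)

    def test_single_sample_unity(self):
        f = y.size_factors(pd.DataFrame({"s": [5, 10, 20]}))
        assert f["s"] == 1.0

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, (100, 3)), columns=list("abc"))
        perm = counts.sample(frac=1, random_state=2)
        pd.testing.assert_series_equal(y.size_factors(counts), y.size_factors(perm))

    def test_scaling_equivariance(self):
        # scaling one sample's counts by c scales its factor relative to
        # every other sample by exactly c (factors are defined up to a
        # global constant, so the ratio is the well-defined quantity)
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(80, (200, 3)) + 1, columns=list("abc"))
        f0 = y.size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = counts["b"] * 3
        f1 = y.size_factors(scaled)
        assert (f1["b"] / f1["a"]) / (f0["b"] / f0["a"]) == pytest.approx(3.0, rel=1e-9)
        assert f1["c"] / f1["a"] == pytest.approx(f0["c"] / f0["a"], rel=1e-9)

    def test_all_zero_gene_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="normalize"):
            y.size_factors(counts)


class TestFpkm:
    def test_unit_definition(self):
        counts = pd.DataFrame({"s": [100, 10**6 - 100]}, index=["g", "rest"])
        lengths = pd.Series([1000, 10**6], index=["g", "rest"])
        out = y.fpkm(counts, lengths)
        assert out.loc["g", "s"] == pytest.approx(100.0)

    def test_scale_invariance_within_sample(self):
        counts = pd.DataFrame({"s": [50, 150]}, index=["g1", "g2"])
        lengths = pd.Series([500, 1500], index=["g1", "g2"])
        doubled = y.fpkm(counts * 2, lengths)
        pd.testing.assert_frame_equal(doubled, y.fpkm(counts, lengths))

    def test_arithmetic(self):
        counts = pd.DataFrame({"s": [50, 2 * 10**6 - 50]}, index=["g", "rest"])
        lengths = pd.Series([500, 10**6], index=["g", "rest"])
        assert y.fpkm(counts, lengths).loc["g", "s"] == pytest.approx(50.0)

    def test_zero_library_error(self):
        with pytest.raises(ValueError):
            y.fpkm(pd.DataFrame({"s": [0]}, index=["g"]), pd.Series([100], index=["g"]))


class TestMaxFpkm:
    def test_row_max_and_permutation_invariance(self):
        mat = pd.DataFrame({"a": [1, 7], "b": [9, 7], "c": [3, 7]}, index=["g1", "g2"])
        out = y.max_fpkm(mat)
        assert out["g1"] == 9 and out["g2"] == 7
        out2 = y.max_fpkm(mat[["c", "a", "b"]])
        pd.testing.assert_series_equal(out.sort_index(), out2.sort_index())

    def test_empty_sample_set_error(self):
        with pytest.raises(ValueError):
            y.max_fpkm(pd.DataFrame({"a": [1]}, index=["g"]), samples=[])


class TestNbTestPair:
    def test_identical_columns_null(self):
        rng = np.random.default_rng(5)
        c = rng.poisson(200, 300)
        counts = pd.DataFrame({"a": c, "b": c}, index=[f"g{i}" for i in range(300)])
        res = y.nb_test_pair(counts, "a", "b")
        assert (res["p"] == 1.0).all()
        assert (res["log2fc"] == 0.0).all()

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            {"a": rng.poisson(150, 200), "b": rng.poisson(180, 200)},
            index=[f"g{i}" for i in range(200)],
        )
        ab = y.nb_test_pair(counts, "a", "b")
        ba = y.nb_test_pair(counts, "b", "a")
        np.testing.assert_allclose(ab["p"], ba["p"], rtol=1e-9)
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], rtol=1e-9)

    def test_all_zero_gene_convention(self):
        counts = pd.DataFrame({"a": [0, 100], "b": [0, 90]}, index=["z", "g"])
        res = y.nb_test_pair(counts, "a", "b")
        assert res.loc["z", "p"] == 1.0 and res.loc["z", "log2fc"] == 0.0

    def test_null_calibration(self, null_sim):
        counts = null_sim.wt_counts.join(null_sim.mut_counts)
        res = y.nb_test_pair(counts, "WT4", "Mut4")
        frac = float((res["p"] < 0.05).mean())
        assert 0.0 <= frac <= 0.08

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            {"a": rng.poisson(100, 50), "b": rng.poisson(120, 50)},
            index=[f"g{i}" for i in range(50)],
        )
        res = y.nb_test_pair(counts, "a", "b")
        perm = counts.sample(frac=1, random_state=1)
        res_p = y.nb_test_pair(perm, "a", "b").loc[res.index]
        np.testing.assert_allclose(res["p"], res_p["p"], rtol=1e-9)


class TestRunDesign:
    def test_null_union_small(self, null_sim):
        res = y.run_design(null_sim.wt_counts, null_sim.mut_counts)
        union = res.up | res.down | res.conflicted
        assert len(union) / len(null_sim.wt_counts) <= 0.02

    def test_power_and_direction_recovery(self, default_sim):
        res = y.run_design(default_sim.wt_counts, default_sim.mut_counts)
        truth_down = set(default_sim.truth.de_genes["gene_id"])
        recovered = truth_down & res.down
        assert len(recovered) / len(truth_down) >= 0.8

    def test_bh_monotone_within_comparison(self, default_sim):
        res = y.run_design(default_sim.wt_counts, default_sim.mut_counts)
        for _, sub in res.table.groupby("comparison"):
            s = sub.sort_values("p")
            assert (s["padj"].cummax() == s["padj"]).all()
            assert (s["padj"] >= s["p"] - 1e-12).all()

    def test_missing_sample_config_error(self, default_sim):
        scheme = y.ComparisonScheme(pairs=[("WT1", "MutX")])
        with pytest.raises(ValueError, match="MutX"):
            y.run_design(default_sim.wt_counts, default_sim.mut_counts, scheme)

    def test_union_semantics_single_pairing(self):
        """A gene shifted in exactly one pairing still enters the union."""
        rng = np.random.default_rng(9)
        n = 400
        idx = [f"g{i}" for i in range(n)]
        base = rng.poisson(300, n)
        cols = {}
        for i in range(7):
            cols[f"WT{i + 1}"] = rng.poisson(base)
        for i in range(11):
            cols[f"Mut{i + 1}"] = rng.poisson(base)
        counts = pd.DataFrame(cols, index=idx)
        counts.loc["g0", "Mut9"] = base[0] * 20  # only pairing WT5-Mut9 differs
        res = y.run_design(counts[[f"WT{i+1}" for i in range(7)]],
                           counts[[f"Mut{i+1}" for i in range(11)]])
        assert "g0" in (res.up | res.conflicted)

    def test_group_comparison_concordant_with_independent_engine(self, default_sim):
        """RC-group contrast agrees with pydeseq2 on who the planted genes are."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts = default_sim.wt_counts.join(default_sim.mut_counts)
        wt_rc = ["WT3", "WT4", "WT5", "WT6", "WT7"]
        mut_rc = [f"Mut{i}" for i in range(3, 12)]
        sub = counts[wt_rc + mut_rc]
        meta = pd.DataFrame(
            {"condition": ["WT"] * 5 + ["mut"] * 9}, index=sub.columns
        )
        dds = DeseqDataSet(counts=sub.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "mut", "WT"], quiet=True)
        stats.summary()
        ref_sig = set(stats.results_df.query("padj < 0.01 and log2FoldChange < 0").index)
        ours = y.nb_test_group(counts, wt_rc, mut_rc)
        from statsmodels.stats.multitest import multipletests

        ours["padj"] = multipletests(ours["p"], method="fdr_bh")[1]
        our_sig = set(ours.query("padj < 0.01 and log2fc < 0").index)
        truth = set(default_sim.truth.de_genes["gene_id"])
        # both engines should recover essentially the planted set
        assert len(truth & ref_sig) / len(truth) >= 0.9
        assert len(truth & our_sig) / len(truth) >= 0.9


class TestClassifyDirection:
    def _rows(self, fcs):
        return pd.DataFrame({"log2fc": fcs})

    def test_majority_down(self):
        assert y.classify_direction(self._rows([-2, -1, -3])) == "down"

    def test_tie_conflicted(self):
        assert y.classify_direction(self._rows([2, -2])) == "conflicted"


class TestAssignPhase:
    def test_label_passthrough(self):
        labels = {"g1": "RC", "g2": "other"}
        assert y.assign_phase(labels=labels) == labels

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError, match="label token"):
            y.assign_phase(labels={"g1": "XX"})

    def test_template_profile_classified(self):
        phases = ["OX", "RB", "RC", "RC", "RC", "RC", "RC"]
        mat = pd.DataFrame(
            {
                "g_rc": [1, 1, 4, 4, 4, 4, 4],
                "g_ox": [4, 1, 1, 1, 1, 1, 1],
                "g_flat": [2, 2, 2, 2, 2, 2, 2],
            }
        ).T
        out = y.assign_phase(wt_matrix=mat, sample_phases=phases)
        assert out == {"g_rc": "RC", "g_ox": "OX", "g_flat": "other"}
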