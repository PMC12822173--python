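"""Normalisation formulas, ratio statistics, gametologue sums and slopes."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosagecomp import expression as ex
from conftest import pairs_from_genes, small_config
import dosagecomp as dc


def feat(gene, start, end, kind="CDS"):
    return {"gene_id": gene, "feature": kind, "start": start, "end": end}


class TestGeneLengths:
    def test_single_cds(self):
        f = pd.DataFrame([feat("g", 0, 1000)])
        assert ex.gene_lengths(f)["g"] == 1000

    def test_overlapping_features_take_union_not_sum(self):
        f = pd.DataFrame([feat("g", 0, 600),
                          feat("g", 400, 1000, "five_prime_utr")])
        assert ex.gene_lengths(f)["g"] == 1000

    def test_disjoint_features_sum(self):
        f = pd.DataFrame([feat("g", 0, 200), feat("g", 300, 500),
                          feat("g", 900, 1100)])
        assert ex.gene_lengths(f)["g"] == 600

    def test_contained_feature_adds_nothing(self):
        f = pd.DataFrame([feat("g", 0, 1000), feat("g", 200, 300)])
        assert ex.gene_lengths(f)["g"] == 1000

    def test_zero_length_gene_rejected(self):
        f = pd.DataFrame([feat("g", 100, 100)])
        with pytest.raises(ValueError):
            ex.gene_lengths(f)


class TestNormalisation:
    def test_cpm_rpkm_formula_identity(self):
        counts = pd.DataFrame({"s": [100, 10 ** 6 - 100]},
                              index=["g1", "g2"])
        lengths = pd.Series([1000, 5000], index=["g1", "g2"])
        assert ex.cpm(counts).loc["g1", "s"] == pytest.approx(100.0)
        assert ex.rpkm(counts, lengths).loc["g1", "s"] == pytest.approx(100.0)

    def test_rpkm_arithmetic(self):
        counts = pd.DataFrame({"s": [50, 2 * 10 ** 6 - 50]}, index=["g", "h"])
        lengths = pd.Series([500, 1000], index=["g", "h"])
        assert ex.rpkm(counts, lengths).loc["g", "s"] == pytest.approx(50.0)

    @given(c=st.integers(min_value=2, max_value=50))
    @settings(deadline=None, max_examples=20)
    def test_cpm_invariant_to_count_scaling(self, c):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, (30, 3)) + 1,
                              columns=list("abc"))
        np.testing.assert_allclose(ex.cpm(counts), ex.cpm(counts * c),
                                   rtol=1e-12)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s": [0, 0]})
        with pytest.raises(ValueError):
            ex.cpm(counts)

    def test_tmm_unity_for_identical_samples(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(100, 200)
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        np.testing.assert_allclose(ex.tmm_factors(counts), 1.0, atol=1e-9)

    def test_tmm_matches_edger(self, tmp_path):
        """Cross-check the composition factors against the reference
        implementation in edgeR on a matrix with a composition shift."""
        rng = np.random.default_rng(3)
        base = rng.lognormal(3, 1, 400)
        counts = pd.DataFrame({
            "a": rng.poisson(base),
            "b": rng.poisson(base * 2),
            "c": rng.poisson(np.r_[base[:50] * 20, base[50:]]),
        }).astype(int)
        counts += 1
        mat = tmp_path / "m.tsv"
        counts.to_csv(mat, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            m <- as.matrix(read.delim("{mat}"))
            cat(calcNormFactors(m, method="TMM"), sep="\\n")
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        ref = np.array([float(v) for v in r.stdout.split()])
        ours = ex.tmm_factors(counts).to_numpy()
        np.testing.assert_allclose(ours, ref, rtol=0.03)


class TestGroupMeans:
    def make(self):
        counts = pd.DataFrame({"XXf_1": [10.0], "XXf_2": [20.0],
                               "XXf_3": [30.0], "XYm_1": [5.0]}, index=["g"])
        samples = pd.DataFrame({
            "sample": ["XXf_1", "XXf_2", "XXf_3", "XYm_1"],
            "group": ["XXf", "XXf", "XXf", "XYm"],
        })
        return counts, samples

    def test_mean_and_single_sample_group(self):
        counts, samples = self.make()
        means = ex.group_mean_rpkm(counts, samples)
        assert means.loc["g", "XXf"] == 20.0
        assert means.loc["g", "XYm"] == 5.0

    def test_sample_order_irrelevant(self):
        counts, samples = self.make()
        shuffled = samples.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(ex.group_mean_rpkm(counts, samples),
                                      ex.group_mean_rpkm(counts, shuffled))

    def test_unknown_group_rejected(self):
        counts, samples = self.make()
        samples.loc[0, "group"] = "XYf"
        with pytest.raises(ValueError):
            ex.group_mean_rpkm(counts, samples)


class TestFilterAndRatios:
    def test_zero_gene_excluded(self):
        means = pd.DataFrame({"A": [0.0, 1.0], "B": [2.0, 2.0]},
                             index=["g0", "g1"])
        assert list(ex.filter_expressed(means, ("A", "B"))) == ["g1"]

    def test_all_positive_is_identity(self):
        means = pd.DataFrame({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        assert len(ex.filter_expressed(means, ("A", "B"))) == 2

    def test_silent_pairs_leave_42_of_47(self, default_run):
        """Five zero-baseline pairs are filtered out, leaving the 42
        analysable gametologue pairs of the modelled data set."""
        means, genes = default_run["means"], default_run["genes"]
        shared = genes.index[genes["region"] == "XY_shared_X"]
        kept = ex.filter_expressed(means.loc[shared], ("XYm", "XXf"))
        assert len(kept) == 42

    def test_identical_groups_give_zero_ratios(self):
        means = pd.DataFrame({"A": [1.0, 5.0], "B": [1.0, 5.0]},
                             index=["g", "h"])
        classes = pd.Series(["autosome", "X_specific"], index=["g", "h"])
        rt = ex.per_gene_ratio(means, "A", "B", classes)
        assert (rt["log2_ratio"] == 0).all()
        med = ex.median_ratio_by_class(rt)
        assert (med["median_log2_ratio"] == 0).all()

    def test_halved_class_gives_minus_one(self):
        means = pd.DataFrame({"A": [2.0, 1.0, 3.0], "B": [4.0, 2.0, 6.0]},
                             index=list("ghk"))
        classes = pd.Series(["X_specific"] * 3, index=list("ghk"))
        rt = ex.per_gene_ratio(means, "A", "B", classes)
        med = ex.median_ratio_by_class(rt).set_index("class")
        assert med.loc["X_specific", "median_log2_ratio"] == -1.0
        assert med.loc["X_total", "median_ratio"] == 0.5

    def test_antisymmetry_under_group_swap(self, default_run):
        means, genes = default_run["means"], default_run["genes"]
        ab = ex.median_ratio_by_class(
            ex.per_gene_ratio(means, "XYm", "XXf", genes["region"]))
        ba = ex.median_ratio_by_class(
            ex.per_gene_ratio(means, "XXf", "XYm", genes["region"]))
        np.testing.assert_allclose(ab["median_log2_ratio"],
                                   -ba["median_log2_ratio"], atol=1e-12)

    def test_x_total_pools_specific_and_shared(self, default_run):
        means, genes = default_run["means"], default_run["genes"]
        med = ex.median_ratio_by_class(
            ex.per_gene_ratio(means, "XYm", "XXf", genes["region"])
        ).set_index("class")
        assert med.loc["X_total", "n"] == 667 + 42
        assert med.loc["XY_shared_X", "n"] == 42

    def test_recovers_rho(self, default_run):
        means, genes = default_run["means"], default_run["genes"]
        med = ex.median_ratio_by_class(
            ex.per_gene_ratio(means, "XYm", "XXf", genes["region"])
        ).set_index("class")
        assert med.loc["X_specific", "median_ratio"] == pytest.approx(
            0.7, abs=0.05)
        assert med.loc["autosome", "median_ratio"] == pytest.approx(
            1.0, abs=0.03)


class TestRatioToAutosomalMedian:
    def test_autosome_median_is_one_in_every_group(self, default_run):
        _, med = ex.ratio_to_autosomal_median(default_run["means"],
                                              default_run["genes"]["region"])
        auto = med[med["class"] == "autosome"]
        np.testing.assert_allclose(auto["median_ratio_to_autosomal"], 1.0)

    def test_xym_x_down_xx_groups_at_parity(self, default_run):
        _, med = ex.ratio_to_autosomal_median(default_run["means"],
                                              default_run["genes"]["region"])
        m = med.set_index(["group", "class"])["median_ratio_to_autosomal"]
        # the X:autosome ratio is depressed only in XY males
        assert m["XYm", "X_specific"] / m["XXf", "X_specific"] \
            == pytest.approx(0.7, abs=0.06)
        assert m["XXm", "X_specific"] / m["XXf", "X_specific"] \
            == pytest.approx(1.0, abs=0.08)

    def test_par_parity_with_low_baseline_spread(self):
        # tight baselines so the small PAR class median is estimable
        cfg = small_config(seed=4, baseline_log_sd=0.2, n_par=40,
                           par_length=1_500_000)
        genes, features, _ = dc.generate_annotation(cfg)
        counts, samples = dc.generate_counts(genes, cfg)
        means = ex.group_mean_rpkm(
            ex.rpkm(counts, ex.gene_lengths(features)), samples)
        _, med = ex.ratio_to_autosomal_median(means, genes["region"])
        par = med[med["class"] == "PAR"]
        assert np.allclose(par["median_ratio_to_autosomal"], 1.0, atol=0.12)


class TestGametologueSum:
    def test_hand_worked_pair(self):
        means = pd.DataFrame({"XYm": [30.0, 30.0], "XXf": [60.0, 0.0]},
                             index=["gx", "gy"])
        pairs = pd.DataFrame({"x_gene": ["gx"], "y_gene": ["gy"]})
        samples = pd.DataFrame({"sample": ["m", "f"],
                                "group": ["XYm", "XXf"],
                                "genotype": ["XY", "XX"]})
        per_pair, med = ex.gametologue_sum(means, pairs, samples)
        assert per_pair["XYm_sum"].iloc[0] == 60.0
        assert per_pair["XXf_sum"].iloc[0] == 60.0
        m = med.set_index(["group", "component"])["median_rpkm"]
        assert m["XYm", "sum"] / m["XXf", "x_copy"] == 1.0

    def test_kappa_one_silences_y_copies(self, small_cfg):
        cfg = small_cfg.replace(kappa=1.0)
        genes, features, _ = dc.generate_annotation(cfg)
        counts, samples = dc.generate_counts(genes, cfg)
        means = ex.group_mean_rpkm(
            ex.rpkm(counts, ex.gene_lengths(features)), samples)
        _, med = ex.gametologue_sum(means, pairs_from_genes(genes), samples)
        m = med.set_index(["group", "component"])["median_rpkm"]
        assert m["XYm", "y_copy"] == 0.0

    def test_sum_dominates_components(self, default_run):
        per_pair, _ = ex.gametologue_sum(default_run["means"],
                                         pairs_from_genes(default_run["genes"]),
                                         default_run["samples"])
        for g in ("XXf", "XYm", "XXm"):
            assert (per_pair[f"{g}_sum"]
                    >= per_pair[[f"{g}_x", f"{g}_y"]].max(axis=1)).all()

    def test_unknown_pair_gene_rejected(self, default_run):
        pairs = pd.DataFrame({"x_gene": ["nope"], "y_gene": ["nada"]})
        with pytest.raises(ValueError):
            ex.gametologue_sum(default_run["means"], pairs,
                               default_run["samples"])


class TestClassSlope:
    def classes(self, n):
        return pd.Series(["autosome"] * (n // 2) + ["X_specific"] * (n - n // 2),
                         index=[f"g{i}" for i in range(n)])

    def test_identical_groups_slope_one(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.lognormal(2, 1, 40),
                      index=[f"g{i}" for i in range(40)])
        out = ex.class_slope(a, a, self.classes(40)).set_index("class")
        np.testing.assert_allclose(out["slope"], 1.0)
        np.testing.assert_allclose(out["r2"], 1.0)

    def test_exact_half_slope(self):
        rng = np.random.default_rng(1)
        b = pd.Series(rng.lognormal(2, 1, 40),
                      index=[f"g{i}" for i in range(40)])
        out = ex.class_slope(0.5 * b, b, self.classes(40)).set_index("class")
        np.testing.assert_allclose(out["slope"], 0.5)
        np.testing.assert_allclose(out["r2"], 1.0)

    def test_low_noise_simulation_recovers_rho_slope(self, small_cfg):
        cfg = small_cfg.replace(dispersion=0.0, library_size=50_000_000)
        genes, features, _ = dc.generate_annotation(cfg)
        counts, samples = dc.generate_counts(genes, cfg)
        cpm_means = ex.group_mean_rpkm(ex.cpm(counts), samples)
        out = ex.class_slope(cpm_means["XYm"], cpm_means["XXf"],
                             genes["region"]).set_index("class")
        assert out.loc["X_total", "slope"] == pytest.approx(0.7, abs=0.03)
        assert out.loc["autosome", "slope"] == pytest.approx(1.0, abs=0.03)

    def test_all_zero_predictor_rejected(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
        b = pd.Series([0.0, 0.0, 0.0, 0.0], index=list("wxyz"))
        classes = pd.Series(["autosome", "autosome", "X_specific",
                             "X_specific"], index=list("wxyz"))
        with pytest.raises(ValueError):
            ex.class_slope(a, b, classes)
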