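"""Size factors, NB testing, BH adjustment and the significance filter."""

import numpy as np
import pandas as pd
import pytest

from isomirseq.diffexp import (
    SignificanceThresholds,
    benjamini_hochberg,
    build_default_contrasts,
    estimate_size_factors,
    filter_significant,
    nb_differential,
    run_contrast,
)


def nb_counts(rng, mu, dispersion, n_samples):
    lam = rng.gamma(1 / dispersion, np.asarray(mu) * dispersion, size=(n_samples, len(mu)))
    return rng.poisson(lam).T


class TestSizeFactors:
    def test_closed_form_two_sample_example(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        sf = estimate_size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({f"s{i}": [5, 9, 14] for i in range(4)})
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0)

    def test_single_sample_convention(self):
        counts = pd.DataFrame({"only": [1, 2, 3]})
        assert estimate_size_factors(counts).tolist() == [1.0]

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(30, 4)), columns=list("abcd")
        ) + 1
        sf = estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["b"] *= 3
        sf2 = estimate_size_factors(scaled)
        # factors are defined up to the geometric-mean reference, so the
        # equivariance holds for factor ratios
        np.testing.assert_allclose(
            (sf2["b"] / sf2["a"]) / (sf["b"] / sf["a"]), 3.0, rtol=1e-9
        )

    def test_no_common_nonzero_feature_is_an_error(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
        with pytest.raises(ValueError, match="nonzero"):
            estimate_size_factors(counts)

    def test_agrees_with_pydeseq2_on_random_matrix(self):
        # independent implementation of the same median-of-ratios rule
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(42)
        counts = pd.DataFrame(
            rng.poisson(rng.lognormal(3, 1, size=(60, 1)), size=(60, 6)) + 1,
            columns=[f"s{i}" for i in range(6)],
        )
        ours = estimate_size_factors(counts)
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        np.testing.assert_allclose(ours, dds.obs["size_factors"], rtol=1e-8)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up_example(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.5]
        np.testing.assert_allclose(
            benjamini_hochberg(p), [0.05, 0.05, 0.05, 0.05, 0.5], rtol=1e-12
        )

    def test_nan_inputs_are_ignored_not_counted(self):
        padj = benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(padj[1])
        np.testing.assert_allclose(padj[[0, 2]], [0.02, 0.04])


class TestNbDifferential:
    def test_identical_counts_give_null_result(self):
        counts = pd.DataFrame({c: [10, 20, 5] for c in "abcdef"}, index=list("xyz"))
        res = nb_differential(counts, ["A"] * 3 + ["B"] * 3)
        np.testing.assert_allclose(res["log2FoldChange"], 0.0, atol=1e-9)
        np.testing.assert_allclose(res["pvalue"], 1.0, atol=1e-6)

    def test_all_zero_feature_reported_with_missing_p(self):
        counts = pd.DataFrame(
            {c: [0, 20, 30] for c in "abcdef"}, index=["zero", "f1", "f2"]
        )
        res = nb_differential(counts, ["A"] * 3 + ["B"] * 3)
        assert np.isnan(res.loc["zero", "pvalue"]) and np.isnan(res.loc["zero", "padj"])
        assert res.loc["zero", "baseMean"] == 0

    def test_non_two_level_grouping_is_an_error(self):
        counts = pd.DataFrame({c: [1, 2] for c in "abc"})
        with pytest.raises(ValueError, match="two group levels"):
            nb_differential(counts, ["A", "B", "C"])

    def test_single_replicate_groups_get_descriptive_lfc_only(self):
        counts = pd.DataFrame({"a": [100], "b": [400]}, index=["f"])
        res = nb_differential(counts, ["A", "B"])
        assert np.isnan(res.loc["f", "pvalue"])
        assert np.isfinite(res.loc["f", "log2FoldChange"])

    def test_recovers_planted_fourfold_change(self):
        # null background features anchor the median-of-ratios normalization
        rng = np.random.default_rng(11)
        mu = np.full(60, 500.0)
        a = nb_counts(rng, mu, 0.05, 3)
        b = nb_counts(rng, mu * 4, 0.05, 3)
        mu_bg = rng.lognormal(4, 1, 500)
        bg = np.hstack([nb_counts(rng, mu_bg, 0.1, 3), nb_counts(rng, mu_bg, 0.1, 3)])
        counts = pd.DataFrame(
            np.vstack([np.hstack([a, b]), bg]), columns=list("abcdef"),
            index=[f"f{i}" for i in range(60)] + [f"bg{i}" for i in range(500)],
        )
        res = nb_differential(counts, ["A"] * 3 + ["B"] * 3).iloc[:60]
        assert 1.7 <= res["log2FoldChange"].median() <= 2.3
        assert (res["padj"] < 0.05).mean() >= 0.9

    def test_direction_follows_reference_level(self):
        rng = np.random.default_rng(12)
        mu = np.full(20, 300.0)
        a = nb_counts(rng, mu, 0.05, 3)
        b = nb_counts(rng, mu * 4, 0.05, 3)
        mu_bg = rng.lognormal(4, 1, 300)
        bg = np.hstack([nb_counts(rng, mu_bg, 0.1, 3), nb_counts(rng, mu_bg, 0.1, 3)])
        counts = pd.DataFrame(np.vstack([np.hstack([a, b]), bg]), columns=list("abcdef"))
        up = nb_differential(counts, ["A"] * 3 + ["B"] * 3, reference_level="A").iloc[:20]
        down = nb_differential(counts, ["A"] * 3 + ["B"] * 3, reference_level="B").iloc[:20]
        assert (up["log2FoldChange"] > 0).all()
        np.testing.assert_allclose(
            up["log2FoldChange"], -down["log2FoldChange"], rtol=1e-6
        )

    def test_one_group_all_zero_yields_strong_signal(self):
        counts = pd.DataFrame(
            [[0, 0, 0, 200, 250, 220], [100, 90, 110, 105, 95, 100]],
            columns=list("abcdef"), index=["f", "stable"],
        )
        res = nb_differential(counts, ["A"] * 3 + ["B"] * 3)
        assert res.loc["f", "log2FoldChange"] > 4


class TestSignificanceFilter:
    @pytest.mark.parametrize(
        "padj,lfc,base,expected,direction",
        [
            (0.04, 1.2, 60, True, "up"),
            (0.04, 0.9, 500, False, ""),
            (0.05, 1.0, 50, True, "up"),  # thresholds are inclusive
            (0.04, -1.5, 60, True, "down"),
            (0.04, 1.5, 49.9, False, ""),
            (0.051, 1.5, 60, False, ""),
            (np.nan, 3.0, 500, False, ""),
        ],
    )
    def test_filter_rules(self, padj, lfc, base, expected, direction):
        records = pd.DataFrame(
            {"baseMean": [base], "log2FoldChange": [lfc], "pvalue": [padj], "padj": [padj]}
        )
        out = filter_significant(records, SignificanceThresholds())
        assert bool(out["significant"].iloc[0]) is expected
        assert out["direction"].iloc[0] == direction


class TestContrasts:
    def test_default_manifest_covers_groups_and_time_points(self):
        sheet = pd.DataFrame(
            [
                (f"{g}_{t}_r{r}", g, t)
                for g in ("colostrum_EV", "calf_EV")
                for t in ("0h", "1h", "6h")
                for r in (1, 2)
            ],
            columns=["sample_id", "group", "time_point"],
        )
        contrasts = {c.name for c in build_default_contrasts(sheet)}
        assert contrasts == {
            "colostrum_EV_vs_calf_EV",
            "calf_EV_1h_vs_0h",
            "calf_EV_6h_vs_0h",
            "colostrum_EV_1h_vs_0h",
            "colostrum_EV_6h_vs_0h",
        }

    def test_run_contrast_uses_only_its_samples(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(100, size=(10, 6)) + 1, columns=[f"s{i}" for i in range(6)]
        )
        sheet = pd.DataFrame(
            {
                "sample_id": counts.columns,
                "group": ["g"] * 6,
                "time_point": ["0h"] * 2 + ["1h"] * 2 + ["6h"] * 2,
            }
        )
        (c1h, _) = [c for c in build_default_contrasts(sheet)]
        res = run_contrast(counts, c1h)
        expected_base = (
            counts[["s0", "s1", "s2", "s3"]]
            .div(estimate_size_factors(counts[["s0", "s1", "s2", "s3"]]), axis=1)
            .mean(axis=1)
        )
        np.testing.assert_allclose(res["baseMean"], expected_base, rtol=1e-9)
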