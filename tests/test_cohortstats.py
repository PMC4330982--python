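"""Gaussian fits, normality tests, group comparison, outlier taxonomy."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

from fociscreen.cohortstats import (
    CohortDistribution,
    classify_outliers,
    compare_groups,
    exceedance_table,
    fit_all,
    fit_distribution,
    outlier_taxonomy,
    relative_increase_pct,
    summarize,
)
from fociscreen.cohortstats import test_normality as normality_test
from fociscreen.synthgen import generate_cohort

from conftest import small_cohort_params


def summaries_frame(values, group="RC", condition="remaining"):
    return pd.DataFrame(
        {
            "individual_id": [f"{group}-{i:03d}" for i in range(len(values))],
            "group": group,
            "condition": condition,
            "mean_foci": values,
            "n_cells": 1000,
        }
    )


class TestSummarize:
    def test_arithmetic_mean_and_cell_count(self):
        records = pd.DataFrame(
            {
                "individual_id": ["a"] * 3,
                "group": ["HI"] * 3,
                "condition": ["preexisting"] * 3,
                "cell_index": [1, 2, 3],
                "foci_count": [0, 1, 2],
            }
        )
        out = summarize(records, min_cells=600)
        assert out["mean_foci"].iloc[0] == 1.0
        assert out["n_cells"].iloc[0] == 3
        assert not out["sufficient"].iloc[0]

    def test_insufficient_flag_threshold(self):
        records = pd.DataFrame(
            {
                "individual_id": ["a"] * 400 + ["b"] * 600,
                "group": "HI",
                "condition": "preexisting",
                "cell_index": list(range(1, 401)) + list(range(1, 601)),
                "foci_count": 1,
            }
        )
        out = summarize(records, min_cells=600).set_index("individual_id")
        assert not out.loc["a", "sufficient"]
        assert out.loc["b", "sufficient"]

    def test_summary_means_match_planted_rates(self, small_cohort):
        params, records, truth = small_cohort
        out = summarize(records, min_cells=400)
        merged = out.merge(truth, on=["individual_id", "group", "condition"])
        lam = merged["true_rate"]
        se = np.sqrt(lam * (1 + params.phi * lam) / merged["n_cells"])
        assert (np.abs(merged["mean_foci"] - lam) < 3 * se).mean() > 0.98

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["individual_id", "group",
                                            "condition", "foci_count"]))


class TestFitDistribution:
    def test_moment_fit_hand_arithmetic(self):
        fit = fit_distribution([1.0, 2.0, 3.0], method="moment")
        assert fit.mu == 2.0
        assert fit.sigma == 1.0
        assert fit.n == 3

    def test_binned_fit_parameter_recovery(self):
        x = np.random.default_rng(7).normal(0.59, 0.1, 10_000)
        fit = fit_distribution(x, method="binned-least-squares")
        assert abs(fit.mu - 0.59) < 0.01
        assert abs(fit.sigma - 0.1) < 0.01
        assert fit.bin_width is not None

    def test_moment_and_binned_fits_agree_on_gaussian_cohorts(self):
        """The two estimators agree within each other's sampling error:
        tightly at large n, loosely (median over seeds) at cohort size."""
        diffs = []
        for s in range(20):
            x = np.random.default_rng(300 + s).normal(2.97, 0.6, 136)
            fm = fit_distribution(x, method="moment")
            fb = fit_distribution(x, method="binned-least-squares")
            diffs.append(abs(fm.mu - fb.mu) / fm.sigma)
        assert np.median(diffs) < 0.1
        x = np.random.default_rng(301).normal(2.97, 0.6, 2000)
        fm = fit_distribution(x, method="moment")
        fb = fit_distribution(x, method="binned-least-squares")
        assert abs(fm.mu - fb.mu) < 0.05 * fm.sigma

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_distribution([1.0, 2.0])
        with pytest.raises(ValueError):
            fit_distribution([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            fit_distribution([1, 2, 3, 4], method="nonsense")


class TestNormality:
    def test_gaussian_samples_pass_both_tests(self):
        ok = 0
        for s in range(20):
            x = np.random.default_rng(500 + s).normal(0, 1, 500)
            r = normality_test(x, seed=s, n_mc=2000)
            ok += int(r["ks_p"] > 0.05 and r["lilliefors_p"] > 0.05)
        assert ok >= 18  # >= 90% of seeds

    def test_exponential_samples_fail_lilliefors(self):
        rejected = 0
        for s in range(20):
            x = np.random.default_rng(600 + s).exponential(1.0, 500)
            r = normality_test(x, seed=s, n_mc=2000)
            rejected += int(r["lilliefors_p"] < 0.05)
        assert rejected == 20  # >= 95% of seeds

    def test_monte_carlo_p_agrees_with_statsmodels_lilliefors(self):
        """Independent cross-check: the seeded Monte-Carlo p-value tracks
        statsmodels' table-based Lilliefors p on moderate samples."""
        for s in (1, 2, 3):
            x = np.random.default_rng(700 + s).normal(2.0, 0.5, 80)
            ours = normality_test(x, seed=s, n_mc=5000)["lilliefors_p"]
            theirs = sm_lilliefors(x, dist="norm")[1]
            assert abs(min(ours, 0.99) - min(theirs, 0.99)) < 0.08

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])


class TestCompareGroups:
    def test_reported_group_means_relative_increase(self):
        assert relative_increase_pct(0.49, 0.59) == 20.4
        assert relative_increase_pct(2.63, 2.97) == 12.9
        assert round(relative_increase_pct(2.63, 2.97)) == 13

    def test_identical_groups(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["t"] == 0.0
        assert r["relative_increase_pct"] == 0.0

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(8)
        hi = rng.normal(0.49, 0.15, 59)
        rc = rng.normal(0.59, 0.15, 136) + 0.1
        r = compare_groups(hi, rc)
        assert r["p"] < 0.001 and r["t"] > 0

    def test_zero_reference_mean_flagged(self):
        r = compare_groups([0.0, 0.0], [1.0, 2.0])
        assert np.isnan(r["relative_increase_pct"])
        assert not r["relative_increase_defined"]


class TestOutlierClassification:
    @pytest.fixture()
    def ref(self):
        return CohortDistribution("RC", "remaining", mu=2.97, sigma=0.6, n=136,
                                  method="moment")

    @pytest.mark.parametrize(
        "value,expected_k",
        [(2.97, 0), (2.97 + 0.61, 1), (2.97 + 2.5 * 0.6, 2),
         (2.97 + 3.01 * 0.6, 3), (0.5, 0)],
    )
    def test_k_rule(self, ref, value, expected_k):
        calls = classify_outliers(summaries_frame([value]), ref)
        assert calls[0].k == expected_k
        assert calls[0].direction == "above"

    def test_analytic_one_sided_tails(self, ref):
        """Self-referenced exceedance of a large Gaussian cohort matches
        the one-sided normal tails 15.87% / 2.28% / 0.13%."""
        values = np.random.default_rng(9).normal(2.97, 0.6, 100_000)
        fit = fit_distribution(values, "RC", "remaining")
        calls = classify_outliers(summaries_frame(values), fit)
        ks = np.array([c.k for c in calls])
        for j, expected, tol in ((1, 15.87, 0.3), (2, 2.28, 0.15), (3, 0.13, 0.05)):
            assert abs(100 * np.mean(ks >= j) - expected) < tol

    def test_reference_monotonicity(self):
        """k against a smaller-mu reference (same sigma) is never smaller."""
        values = np.random.default_rng(10).normal(3.0, 0.5, 200)
        lo = CohortDistribution("HI", "remaining", 2.63, 0.5, 59, "moment")
        hi = CohortDistribution("RC", "remaining", 2.97, 0.5, 136, "moment")
        k_lo = [c.k for c in classify_outliers(summaries_frame(values), lo)]
        k_hi = [c.k for c in classify_outliers(summaries_frame(values), hi)]
        assert all(a >= b for a, b in zip(k_lo, k_hi))

    def test_exceedance_table_layout_and_empty_intersection(self):
        rng = np.random.default_rng(11)
        sums = pd.concat(
            [
                summaries_frame(rng.normal(0.49, 0.15, 59), "HI", "preexisting"),
                summaries_frame(rng.normal(0.59, 0.15, 136), "RC", "preexisting"),
                summaries_frame(rng.normal(2.63, 0.6, 59), "HI", "remaining"),
                summaries_frame(rng.normal(2.97, 0.6, 136), "RC", "remaining"),
            ],
            ignore_index=True,
        )
        fits = fit_all(sums)
        table = exceedance_table(sums, fits)
        # three column blocks x two conditions x k in {1,2,3}
        assert len(table) == 18
        # patients against the healthy reference show more exceedance
        rc_self = table.query("group=='RC' and reference=='RC' and k==2")["pct"]
        rc_vs_hi = table.query("group=='RC' and reference=='HI' and k==2")["pct"]
        assert (rc_vs_hi.to_numpy() >= rc_self.to_numpy()).all()
        # empty intersection: no HI rows -> NaN percentages, no error
        empty = exceedance_table(
            sums[sums["group"] == "RC"], fits, groups_and_refs=[("HI", "RC")]
        )
        assert empty["pct"].isna().all()


class TestTaxonomy:
    def make_calls(self, ks, condition):
        ref = CohortDistribution("RC", condition, 1.0, 0.1, 10, "moment")
        frame = summaries_frame(
            [1.0 + (k + 0.5) * 0.1 if k else 1.0 for k in ks], "RC", condition
        )
        return classify_outliers(frame, ref)

    @pytest.mark.parametrize(
        "k_pre,k_rem,expected",
        [(3, 0, "preexisting_only"), (2, 2, "both"), (0, 2, "remaining_only"),
         (1, 1, "none"), (0, 0, "none")],
    )
    def test_class_rules(self, k_pre, k_rem, expected):
        tax = outlier_taxonomy(
            self.make_calls([k_pre], "preexisting"),
            self.make_calls([k_rem], "remaining"),
        )
        assert tax["outlier_class"].iloc[0] == expected

    def test_partition_property(self):
        rng = np.random.default_rng(12)
        ks_pre = rng.integers(0, 4, 50)
        ks_rem = rng.integers(0, 4, 50)
        tax = outlier_taxonomy(
            self.make_calls(ks_pre, "preexisting"),
            self.make_calls(ks_rem, "remaining"),
        )
        counts = tax["outlier_class"].value_counts()
        assert counts.sum() == 50
        assert set(counts.index) <= {
            "preexisting_only", "both", "remaining_only", "none"
        }

    def test_mismatched_ids_rejected(self):
        pre = self.make_calls([2, 0], "preexisting")
        rem = self.make_calls([2], "remaining")
        with pytest.raises(ValueError):
            outlier_taxonomy(pre, rem)

    def test_planted_classes_recovered(self):
        """A cohort with large planted effects yields high per-class recall
        when classified against the binned patient reference."""
        params = small_cohort_params(
            n_individuals={"HI": 0, "RC": 136},
            outlier_fraction={"HI": 0.0, "RC": 0.12},
            outlier_effect=3.0,
            cells_per_individual=500,
            seed=21,
        )
        records, truth = generate_cohort(params)
        sums = summarize(records, min_cells=500)
        calls = {}
        for cond in ("preexisting", "remaining"):
            sub = sums[sums["condition"] == cond]
            fit = fit_distribution(sub["mean_foci"].to_numpy(), "RC", cond,
                                   method="binned-least-squares")
            calls[cond] = classify_outliers(sub, fit, cond)
        tax = outlier_taxonomy(calls["preexisting"], calls["remaining"])
        merged = tax.merge(
            truth.drop_duplicates("individual_id")[
                ["individual_id", "outlier_class"]
            ],
            on="individual_id", suffixes=("_called", "_planted"),
        )
        planted = merged[merged["outlier_class_planted"] != "none"]
        recall = (
            planted["outlier_class_called"] == planted["outlier_class_planted"]
        ).mean()
        assert recall >= 0.8
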