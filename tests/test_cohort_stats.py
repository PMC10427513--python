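import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from airwayfat import (
    PairedCohortTable,
    cohens_d_repeated,
    paired_change_table,
    paired_t_test,
    summarize_comparisons,
)
from airwayfat.cohort_stats import classify_magnitude
from airwayfat.errors import DegenerateStatisticError, UndefinedPercentChangeError


def make_cohort(values: dict[str, tuple[np.ndarray, np.ndarray]]) -> PairedCohortTable:
    rows = []
    for metric, (pre, post) in values.items():
        for i, (b, f) in enumerate(zip(pre, post)):
            rows.append({"subject": f"S{i}", "session": "baseline", "metric": metric, "value": b})
            rows.append({"subject": f"S{i}", "session": "followup", "metric": metric, "value": f})
    return PairedCohortTable(pd.DataFrame(rows))


class TestPairedTTest:
    def test_closed_form_microexample(self):
        # diffs (1, 2, 0): mean 1, SD 1 -> t = sqrt(3), df = 2
        pre = np.array([0.0, 0.0, 0.0])
        post = np.array([1.0, 2.0, 0.0])
        res = paired_t_test(pre, post)
        assert res.t == pytest.approx(np.sqrt(3.0))
        assert res.df == 2
        # two-sided p frozen from the t-distribution CDF: 2*(1-F_2(sqrt(3)))
        assert res.p == pytest.approx(0.22540, abs=1e-4)

    def test_matches_independent_closed_form(self, rng):
        pre = rng.normal(10, 2, 15)
        post = rng.normal(9, 2, 15)
        res = paired_t_test(pre, post)
        diff = post - pre
        t_oracle = diff.mean() / (diff.std(ddof=1) / np.sqrt(diff.size))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), diff.size - 1)
        assert res.t == pytest.approx(t_oracle)
        assert res.p == pytest.approx(p_oracle)

    def test_identical_sessions_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateStatisticError):
            paired_t_test(x, x)

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            paired_t_test(np.array([1.0]), np.array([2.0]))


class TestEffectSizes:
    def test_d_z_microexample(self):
        pre = np.zeros(3)
        post = np.array([1.0, 2.0, 0.0])
        res = cohens_d_repeated(pre, post, variant="d_z")
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_d_rm_equals_formula(self, rng):
        pre = rng.normal(50, 10, 18)
        post = pre * 0.9 + rng.normal(0, 3, 18)
        res = cohens_d_repeated(pre, post, variant="d_rm")
        diff = post - pre
        s1, s2 = pre.std(ddof=1), post.std(ddof=1)
        r = np.corrcoef(pre, post)[0, 1]
        d_oracle = diff.mean() / np.sqrt(s1**2 + s2**2 - 2 * r * s1 * s2) * np.sqrt(2 * (1 - r))
        assert res.estimate == pytest.approx(d_oracle)

    def test_d_av_equals_formula(self, rng):
        pre = rng.normal(50, 10, 12)
        post = rng.normal(45, 8, 12)
        res = cohens_d_repeated(pre, post, variant="d_av")
        d_oracle = (post - pre).mean() / ((pre.std(ddof=1) + post.std(ddof=1)) / 2)
        assert res.estimate == pytest.approx(d_oracle)

    @pytest.mark.parametrize("scale,shift", [(2.5, 10.0), (0.1, -3.0)])
    def test_d_z_invariant_under_affine_rescaling(self, rng, scale, shift):
        pre = rng.normal(100, 15, 18)
        post = pre + rng.normal(-5, 4, 18)
        d0 = cohens_d_repeated(pre, post, variant="d_z").estimate
        d1 = cohens_d_repeated(pre * scale + shift, post * scale + shift, variant="d_z").estimate
        assert d1 == pytest.approx(d0, abs=1e-10)

    def test_perfect_correlation_degenerate_for_d_rm(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(DegenerateStatisticError):
            cohens_d_repeated(pre, pre + 1.0 + 1e-12 * np.arange(4), variant="d_rm")

    def test_magnitude_thresholds(self):
        assert classify_magnitude(0.1) == "negligible"
        assert classify_magnitude(-0.3) == "small"
        assert classify_magnitude(0.6) == "medium"
        assert classify_magnitude(-1.5) == "large"

    def test_null_simulation_mean_d_z_near_zero(self):
        rng = np.random.default_rng(11)
        n, reps = 18, 1000
        ds = []
        for _ in range(reps):
            pre = rng.standard_normal(n)
            post = rng.standard_normal(n)
            ds.append(cohens_d_repeated(pre, post, variant="d_z").estimate)
        # null d_z has SD ~ 1/sqrt(n); 3 standard errors of the replicate mean
        margin = 3.0 / np.sqrt(n) / np.sqrt(reps)
        assert abs(np.mean(ds)) < 4 * margin

    def test_known_effect_recovery_matches_small_sample_expectation(self):
        # E[d_z] = delta * sqrt(df/2) * Gamma((df-1)/2) / Gamma(df/2)
        rng = np.random.default_rng(13)
        n, delta, reps = 18, -1.5, 1000
        df = n - 1
        expectation = delta * np.sqrt(df / 2) * special.gamma((df - 1) / 2) / special.gamma(df / 2)
        ds = [
            cohens_d_repeated(np.zeros(n), rng.normal(delta, 1.0, n), variant="d_z").estimate
            for _ in range(reps)
        ]
        se = np.std(ds) / np.sqrt(reps)
        assert np.mean(ds) == pytest.approx(expectation, abs=4 * se)

    def test_percentile_bootstrap_is_seeded_and_reproducible(self, rng):
        pre = rng.normal(100, 15, 18)
        post = pre + rng.normal(-5, 4, 18)
        a = cohens_d_repeated(pre, post, ci_method="percentile", n_boot=2000, seed=5)
        b = cohens_d_repeated(pre, post, ci_method="percentile", n_boot=2000, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = cohens_d_repeated(pre, post, ci_method="percentile", n_boot=2000, seed=6)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)


class TestChangeTable:
    def test_quarter_loss(self):
        cohort = make_cohort({"weight": (np.array([100.0, 100.0]), np.array([75.0, 80.0]))})
        table = paired_change_table(cohort)
        row = table[table["subject"] == "S0"].iloc[0]
        assert row["absolute_change"] == -25.0
        assert row["percent_change"] == -25.0

    def test_no_change(self):
        cohort = make_cohort({"m": (np.array([5.0, 6.0]), np.array([5.0, 6.0]))})
        table = paired_change_table(cohort)
        assert (table["absolute_change"] == 0).all()
        assert (table["percent_change"] == 0).all()

    def test_zero_baseline_rejected(self):
        cohort = make_cohort({"m": (np.array([0.0, 1.0]), np.array([1.0, 2.0]))})
        with pytest.raises(UndefinedPercentChangeError):
            paired_change_table(cohort)

    def test_multiplicative_change_recovers_factor(self):
        rng = np.random.default_rng(3)
        c = 0.85
        pre = rng.normal(100, 10, 5000)
        cohort = make_cohort({"m": (pre, pre * c)})
        table = paired_change_table(cohort)
        assert table["percent_change"].mean() == pytest.approx(100 * (c - 1), abs=1e-9)


class TestSummary:
    def test_identical_sessions_flagged_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        summary = summarize_comparisons(make_cohort({"m": (x, x)}))
        row = summary.iloc[0]
        assert row["change_mean"] == 0.0
        assert row["change_sd"] == 0.0
        assert row["status"].startswith("degenerate")

    def test_metric_order_preserved(self, rng):
        pre = rng.normal(10, 1, 6)
        post = pre + rng.normal(1, 0.5, 6)
        summary = summarize_comparisons(make_cohort({"zeta": (pre, post), "alpha": (pre, post)}))
        assert list(summary["metric"]) == ["zeta", "alpha"]

    def test_incomplete_pairs_dropped_listwise(self, rng):
        cohort = make_cohort({"m": (rng.normal(10, 1, 6), rng.normal(9, 1, 6))})
        data = cohort.data.drop(cohort.data[(cohort.data["subject"] == "S0") & (cohort.data["session"] == "followup")].index)
        summary = summarize_comparisons(PairedCohortTable(data))
        assert summary.iloc[0]["n"] == 5

    def test_absolute_change_consistency(self, rng):
        pre = rng.normal(10, 2, 10)
        post = pre + rng.normal(-1, 1, 10)
        row = summarize_comparisons(make_cohort({"m": (pre, post)})).iloc[0]
        assert row["change_mean"] == pytest.approx(row["followup_mean"] - row["baseline_mean"])
        assert bool(row["significant"]) == (row["p"] < 0.05)

    def test_csv_round_trip(self, tmp_path, rng):
        cohort = make_cohort({"m": (rng.normal(10, 1, 4), rng.normal(9, 1, 4))})
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = PairedCohortTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, cohort.data)
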