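"""Normal-database statistics: summaries, regressions, splits, full report."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

import mibgquant as mq
from mibgquant.errors import ValidationError


class TestSummarizeMeasure:
    def test_tiny_vector(self):
        s = mq.summarize_measure([1.0, 2.0, 3.0], "toy")
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)  # n-1 denominator
        assert 1.0 <= s.q025 <= s.mean <= s.q975 <= 3.0

    def test_normal_quantile_oracle(self):
        """Empirical 2.5% quantile of a large Normal(3.29, 0.48) sample
        matches the analytic mu - 1.95996*sigma = 2.3492."""
        rng = np.random.default_rng(11)
        x = rng.normal(3.29, 0.48, 100_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # Shapiro on n > 5000 warns
            s = mq.summarize_measure(x, "hmr_late_std")
        assert s.q025 == pytest.approx(2.3492172874207737, abs=0.01)
        assert s.q975 == pytest.approx(3.29 + 1.9599639845400545 * 0.48, abs=0.01)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            s = mq.summarize_measure([2.0, 2.0, 2.0], "flat")
        assert np.isnan(s.shapiro_p)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            mq.summarize_measure([1.0, 2.0], "toy")

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            mq.summarize_measure([1.0, np.nan, 3.0], "toy")

    def test_quantile_coverage(self):
        """Fraction of values strictly below q025 never exceeds
        2.5% + 1/n for the interpolation estimator."""
        rng = np.random.default_rng(5)
        for n in (20, 62, 500):
            x = rng.standard_normal(n)
            s = mq.summarize_measure(x, "x")
            assert (x < s.q025).mean() <= 0.025 + 1.0 / n

    def test_shapiro_type_one_error(self):
        """On Normal draws the Shapiro-Wilk test rejects at ~alpha."""
        rng = np.random.default_rng(19)
        rejections = sum(
            mq.summarize_measure(rng.normal(3.29, 0.48, 62), "x").shapiro_p < 0.05
            for _ in range(400)
        )
        assert rejections / 400 == pytest.approx(0.05, abs=0.025)


class TestFitAgeRegression:
    def test_exact_recovery_on_collinear_points(self):
        age = np.linspace(20, 84, 30)
        y = -0.0071 * age + 3.69
        r = mq.fit_age_regression(age, y, "hmr_late_std")
        assert r.slope == pytest.approx(-0.0071, abs=1e-12)
        assert r.intercept == pytest.approx(3.69, abs=1e-10)
        assert r.r_squared == pytest.approx(1.0)
        assert r.show_line

    def test_matches_normal_equations_oracle(self):
        """OLS agrees with the closed-form normal equations on random
        small instances."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(5, 30)
            x = rng.uniform(20, 84, n)
            y = rng.normal(3.0, 0.5, n)
            r = mq.fit_age_regression(x, y)
            sxx = np.sum((x - x.mean()) ** 2)
            slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            intercept = y.mean() - slope * x.mean()
            assert r.slope == pytest.approx(slope, abs=1e-10)
            assert r.intercept == pytest.approx(intercept, abs=1e-10)
            assert r.slope_ci[0] <= r.slope <= r.slope_ci[1]
            assert 0.0 <= r.r_squared <= 1.0

    def test_null_rejection_rate(self):
        """Values independent of age reject at ~5% (alpha = 0.05)."""
        rng = np.random.default_rng(8)
        age = rng.uniform(20, 84, 62)
        rej = sum(
            mq.fit_age_regression(age, rng.standard_normal(62)).p_value < 0.05
            for _ in range(600)
        )
        assert rej / 600 == pytest.approx(0.05, abs=0.02)

    def test_zero_age_variance_rejected(self):
        with pytest.raises(ValidationError):
            mq.fit_age_regression([50, 50, 50], [1.0, 2.0, 3.0])


class TestYearsPerDecline:
    def test_abstract_arithmetic(self):
        assert round(mq.years_per_decline(-0.0071, 0.1)) == 14
        assert mq.years_per_decline(-0.0071, 0.1) == pytest.approx(14.08, abs=0.01)

    def test_decade_decline(self):
        assert mq.years_per_decline(-0.0071, 0.071) == pytest.approx(10.0)

    def test_unit_slope(self):
        assert mq.years_per_decline(-0.1, 0.1) == pytest.approx(1.0)

    def test_non_declining_slope_rejected(self):
        with pytest.raises(ValidationError):
            mq.years_per_decline(0.0071, 0.1)


class TestSplitAndCompare:
    def test_identical_groups(self):
        young = pd.DataFrame({"age_years": np.full(31, 40.0), "x": np.tile([3.0, 3.2, 3.4], 11)[:31]})
        old = young.assign(age_years=70.0)
        g = mq.split_and_compare(pd.concat([young, old], ignore_index=True), "x")
        assert g.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert g.p_value == pytest.approx(1.0)

    def test_welch_hand_example(self):
        """3-vs-3 Welch oracle: means 2 and 4, variances 1 and 4 give
        t = -1.5492 with 2.941 df, p = 0.2209."""
        df = pd.DataFrame(
            {"age_years": [30, 35, 40, 70, 75, 80], "x": [1.0, 2.0, 3.0, 2.0, 4.0, 6.0]}
        )
        g = mq.split_and_compare(df, "x", threshold_age=63)
        assert g.t_statistic == pytest.approx(-1.5491933384829668, abs=1e-10)
        assert g.p_value == pytest.approx(0.22088084049409593, abs=1e-10)

    def test_ties_go_to_older_group(self):
        df = pd.DataFrame({"age_years": [62.0, 63.0, 64.0, 30.0], "x": [1.0, 2.0, 3.0, 4.0]})
        g = mq.split_and_compare(df, "x", threshold_age=63)
        assert (g.n_younger, g.n_older) == (2, 2)
        g2 = mq.split_and_compare(df, "x", threshold_age=63, ties_to_older=False)
        assert (g2.n_younger, g2.n_older) == (3, 1)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"age_years": [30.0, 40.0, 50.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError, match="empty"):
            mq.split_and_compare(df, "x", threshold_age=90)

    def test_power_against_known_shift(self):
        """Two Normal(., 0.45) groups 0.2 apart at n = 31 each: the t-test
        detects the shift with the moderate power such a ~0.44-SD effect
        carries (roughly 40% at alpha = 0.05), far above the null rate."""
        rng = np.random.default_rng(10)
        hits = 0
        reps = 400
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "age_years": np.r_[np.full(31, 40.0), np.full(31, 75.0)],
                    "x": np.r_[rng.normal(3.4, 0.45, 31), rng.normal(3.2, 0.45, 31)],
                }
            )
            hits += mq.split_and_compare(df, "x").p_value < 0.05
        assert 0.25 <= hits / reps <= 0.60

    def test_older_group_lower_limit_drops(self, analysis_cohort):
        g = mq.split_and_compare(analysis_cohort, "hmr_late_std")
        assert g.q025_older < g.q025_younger


class TestRunFullAnalysis:
    def test_report_structure_and_display_rule(self, analysis_cohort, tmp_path):
        report = mq.run_full_analysis(analysis_cohort, out_dir=tmp_path, make_figures=False)
        assert set(report["summaries"]) == set(mq.stats.MEASURES)
        for m, reg in report["age_regressions"].items():
            assert reg["show_line"] == (reg["p_value"] < 0.10)
        for fname in ("summary.csv", "regressions.csv", "groups.csv", "report.json"):
            assert (tmp_path / fname).exists()
        loaded = json.loads((tmp_path / "report.json").read_text())
        assert loaded["n"] == 62

    def test_byte_identical_reports(self, analysis_cohort, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        mq.run_full_analysis(analysis_cohort, out_dir=a, make_figures=False)
        mq.run_full_analysis(analysis_cohort, out_dir=b, make_figures=False)
        for fname in ("summary.csv", "regressions.csv", "groups.csv", "report.json"):
            assert (a / fname).read_bytes() == (b / fname).read_bytes()

    def test_figures_written(self, analysis_cohort, tmp_path):
        mq.run_full_analysis(analysis_cohort, out_dir=tmp_path, make_figures=True)
        for m in mq.stats.MEASURES:
            assert (tmp_path / f"fig_{m}_age.png").exists()
        assert (tmp_path / "fig_group_hmr.png").exists()

    def test_missing_measures_rejected(self, cohort):
        with pytest.raises(ValidationError, match="missing"):
            mq.run_full_analysis(cohort)

    def test_null_generator_line_rate(self):
        """With a zero-slope generator each measure's regression line is
        displayed at about the nominal 10% rate of the p < 0.10 rule."""
        shown = {m: 0 for m in mq.stats.MEASURES}
        reps = 80
        for s in range(reps):
            c = mq.simulate_cohort(mq.CohortModel(hmr_age_slope=0.0), seed=80_000 + s)
            c = mq.add_washout_columns(mq.standardize_cohort(c))
            for m in mq.stats.MEASURES:
                r = mq.fit_age_regression(c["age_years"], c[m], m)
                shown[m] += r.show_line
        for m, k in shown.items():
            assert k / reps <= 0.25, m

    def test_default_generator_late_line_majority(self):
        """Under the default age model the late-HMR regression line is
        displayed in the majority of replicate cohorts, while washout
        lines stay mostly absent."""
        late_shown = wr_shown = 0
        reps = 60
        for s in range(reps):
            c = mq.simulate_cohort(seed=85_000 + s)
            c = mq.add_washout_columns(mq.standardize_cohort(c))
            late_shown += mq.fit_age_regression(c["age_years"], c["hmr_late_std"]).show_line
            wr_shown += mq.fit_age_regression(c["age_years"], c["wr_bdc"]).show_line
        assert late_shown / reps > 0.5
        assert wr_shown / reps < 0.3
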