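"""Comparison statistics: summaries, ANOVA/Dunnett, correlations, ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cdltools import stats as cst
from cdltools.estimators import ElectrodeSpec


def long_table(values_by_method, rater="R1"):
    rows = []
    for method, vals in values_by_method.items():
        for i, v in enumerate(vals):
            rows.append({"specimen_id": f"S{i:02d}", "method": method,
                         "rater_id": rater, "cdl_mm": v})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_mean_sd(self):
        rows = cst.summarize(long_table({"m": [40.0, 42.0, 44.0]}))
        assert rows[0].mean_cdl_mm == pytest.approx(42.0)
        assert rows[0].sd_cdl_mm == pytest.approx(2.0)

    def test_full_coverage(self):
        rows = cst.summarize(long_table({"m": [31.5, 31.5]}))
        assert rows[0].mean_cc_percent == pytest.approx(100.0)
        assert rows[0].mean_ia_deg == pytest.approx(900.0)

    def test_ia_cc_linearity_exact(self):
        rng = np.random.default_rng(0)
        table = long_table({"a": rng.uniform(30, 50, 12),
                            "b": rng.uniform(30, 50, 12)})
        for row in cst.summarize(table):
            assert row.mean_ia_deg == pytest.approx(9.0 * row.mean_cc_percent,
                                                    rel=1e-12)
            assert row.sd_ia_deg == pytest.approx(9.0 * row.sd_cc_percent,
                                                  rel=1e-12)

    def test_mean_of_ratios_not_ratio_of_means(self):
        rows = cst.summarize(long_table({"m": [30.0, 60.0]}))
        cc = rows[0].mean_cc_percent
        assert cc == pytest.approx((31.5 / 30 + 31.5 / 60) / 2 * 100)
        assert cc != pytest.approx(31.5 / 45.0 * 100)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        table = long_table({"a": rng.uniform(30, 50, 9),
                            "b": rng.uniform(30, 50, 9)})
        shuffled = table.sample(frac=1.0, random_state=3)
        a = sorted(cst.summarize(table), key=lambda r: r.method)
        b = sorted(cst.summarize(shuffled), key=lambda r: r.method)
        for ra, rb in zip(a, b):
            assert ra.method == rb.method
            assert ra.mean_cdl_mm == pytest.approx(rb.mean_cdl_mm, rel=1e-12)
            assert ra.sd_cdl_mm == pytest.approx(rb.sd_cdl_mm, rel=1e-12)
            assert ra.mean_ia_deg == pytest.approx(rb.mean_ia_deg, rel=1e-12)

    def test_requires_single_rater(self):
        t1 = long_table({"m": [40.0, 41.0]}, rater="R1")
        t2 = long_table({"m": [40.5, 41.5]}, rater="R2")
        with pytest.raises(cst.StatsError):
            cst.summarize(pd.concat([t1, t2]))


class TestAnova:
    def test_identical_groups_f_zero(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        res = cst.anova_oneway(g)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_seven_groups_of_twenty_df(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(size=20) for i in range(7)}
        res = cst.anova_oneway(groups)
        assert (res.df_between, res.df_within) == (6, 133)

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1, 12)
        res = cst.anova_oneway({"a": a, "b": b})
        t = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t.statistic ** 2, abs=1e-9)
        assert res.p == pytest.approx(t.pvalue, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(i * 0.2, 1, 20) for i in range(4)}
        res = cst.anova_oneway(groups)
        ref = sps.f_oneway(*groups.values())
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestDunnett:
    def test_single_comparison_reduces_to_t_test(self):
        rng = np.random.default_rng(4)
        ctrl, grp = rng.normal(0, 1, 20), rng.normal(0.6, 1, 20)
        res = cst.dunnett_vs_control({"c": ctrl, "g": grp}, "c")[0]
        expected = sps.ttest_ind(ctrl, grp).pvalue
        assert res.p_adjusted == pytest.approx(expected, abs=1e-6)

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 15) for i in range(5)}
        groups["c"] = rng.normal(0, 1, 15)
        df = sum(map(len, groups.values())) - len(groups)
        s2 = sum(((v - np.mean(v)) ** 2).sum()
                 for v in map(np.asarray, groups.values())) / df
        for d in cst.dunnett_vs_control(groups, "c"):
            p_raw = 2 * sps.t.sf(abs(d.statistic), df)
            assert d.p_adjusted >= p_raw - 1e-12

    def test_against_scipy_dunnett(self):
        rng = np.random.default_rng(6)
        groups = {f"g{i}": rng.normal(i * 0.25, 1, 20) for i in range(6)}
        ctrl = rng.normal(0, 1, 20)
        mine = cst.dunnett_vs_control({**groups, "ctrl": ctrl}, "ctrl")
        ref = sps.dunnett(*groups.values(), control=ctrl)
        ci = ref.confidence_interval(0.95)
        for i, d in enumerate(mine):
            # scipy integrates by randomised QMC; agree to its noise level
            assert d.p_adjusted == pytest.approx(ref.pvalue[i], abs=2e-3)
            assert d.mean_difference_mm == pytest.approx(
                np.mean(ctrl) - np.mean(groups[f"g{i}"]), abs=1e-12)
            assert d.ci95_mm[0] == pytest.approx(-ci.high[i], abs=5e-3)
            assert d.ci95_mm[1] == pytest.approx(-ci.low[i], abs=5e-3)

    def test_sign_convention_underestimation_positive(self):
        ctrl = np.full(10, 43.0) + np.linspace(-1, 1, 10)
        low = ctrl - 7.7
        d = cst.dunnett_vs_control({"ref": ctrl, "m": low}, "ref")[0]
        assert d.mean_difference_mm == pytest.approx(7.7, abs=1e-12)
        assert d.ci95_mm[0] < d.mean_difference_mm < d.ci95_mm[1]

    def test_familywise_error_calibration(self):
        """All-null simulation, 7 groups x 20: FWE within 5% +/- 1.5."""
        rng = np.random.default_rng(7)
        reps, k, n = 5000, 7, 20
        lambdas = np.sqrt(n / (n + n)) * np.ones(k - 1)
        df = k * n - k
        qcrit = cst.dunnett_critical_value(df, lambdas, 0.05)
        data = rng.normal(size=(reps, k, n))
        means = data.mean(axis=2)
        ss = ((data - means[..., None]) ** 2).sum(axis=(1, 2))
        s = np.sqrt(ss / df)
        tstats = (means[:, 1:] - means[:, [0]]) / (
            s[:, None] * np.sqrt(2.0 / n))
        fwe = (np.abs(tstats).max(axis=1) > qcrit).mean()
        assert 0.035 <= fwe <= 0.065

    def test_errors(self):
        with pytest.raises(cst.StatsError):
            cst.dunnett_vs_control({"a": [1.0, 2.0]}, "a")
        with pytest.raises(cst.StatsError):
            cst.dunnett_vs_control({"a": [1.0, 2.0], "b": [1.0, 2.0]}, "zz")


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(1.0, 8.0)
        assert cst.pearson(x, 2 * x).r == pytest.approx(1.0)
        assert cst.pearson(x, -2 * x + 3).r == pytest.approx(-1.0)

    def test_hand_computed(self):
        res = cst.pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)
        assert res.n == 4

    def test_zero_variance(self):
        with pytest.raises(cst.StatsError):
            cst.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(cst.StatsError):
            cst.pearson([1.0, 2.0], [1.0, 2.0])


class TestDependentCorrelations:
    def test_equal_correlations_null(self):
        t, p = cst.compare_dependent_correlations(0.5, 0.5, 0.3, 20)
        assert t == 0.0
        assert p == 1.0

    def test_p_decreases_with_gap(self):
        gaps = [0.05, 0.15, 0.25, 0.35]
        ps = [cst.compare_dependent_correlations(0.5 + g, 0.5 - g, 0.3, 20)[1]
              for g in gaps]
        assert np.all(np.diff(ps) < 0)

    def test_degenerate_inputs(self):
        with pytest.raises(cst.StatsError):
            cst.compare_dependent_correlations(1.0, 0.5, 0.3, 20)
        with pytest.raises(cst.StatsError):
            cst.compare_dependent_correlations(0.5, 0.4, 0.3, 3)

    def test_type_one_error_monte_carlo(self):
        """Trivariate-normal null: rejection rate ~ 5% at n = 20."""
        rng = np.random.default_rng(11)
        n, reps = 20, 10_000
        cov = np.array([[1.0, 0.5, 0.5],
                        [0.5, 1.0, 0.3],
                        [0.5, 0.3, 1.0]])
        L = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=(n, 3)) @ L.T
            r = np.corrcoef(x, rowvar=False)
            _, p = cst.compare_dependent_correlations(r[0, 1], r[0, 2],
                                                      r[1, 2], n)
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.035 <= rate <= 0.065


class TestICC:
    def test_perfect_agreement(self):
        r1 = np.array([3.0, 5.0, 7.0, 9.0, 11.0])
        res = cst.icc_agreement(np.column_stack([r1, r1]))
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_offset_raters_hand_computed(self):
        """rater2 = rater1 + 1 on 1..5: MSR=5, MSC=2.5, MSE=0 -> 5/6."""
        r1 = np.arange(1.0, 6.0)
        res = cst.icc_agreement(np.column_stack([r1, r1 + 1]))
        assert res.icc == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        truth = rng.normal(40, 4, 30)
        ratings = truth[:, None] + rng.normal(0, 1.5, (30, 2))
        mine = cst.icc_agreement(ratings).icc
        df = pd.DataFrame({
            "s": np.repeat(np.arange(30), 2),
            "r": np.tile(["R1", "R2"], 30),
            "y": ratings.ravel()})
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        # absolute-agreement single-rater row (ICC(2,1) in Shrout-Fleiss)
        ref_icc = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert mine == pytest.approx(ref_icc, abs=1e-9)

    def test_zero_variance(self):
        with pytest.raises(cst.StatsError):
            cst.icc_agreement(np.full((6, 2), 4.2))

    def test_too_few_specimens(self):
        with pytest.raises(cst.StatsError):
            cst.icc_agreement(np.random.default_rng(0).normal(size=(4, 2)))


class TestICCCategory:
    @pytest.mark.parametrize("icc, label", [
        (0.29, "poor"), (0.43, "fair"), (0.71, "good"), (0.87, "excellent"),
        (0.39, "poor"), (0.40, "fair"), (0.59, "fair"), (0.60, "good"),
        (0.74, "good"), (0.75, "excellent"), (1.0, "excellent"),
        (-0.2, "poor"),
    ])
    def test_bands(self, icc, label):
        assert cst.icc_category(icc) == label

    def test_above_one_rejected(self):
        with pytest.raises(cst.StatsError):
            cst.icc_category(1.2)


class TestReport:
    def _inputs(self):
        rng = np.random.default_rng(13)
        table = long_table({"reference": rng.uniform(38, 48, 10),
                            "SW-HRCT": rng.uniform(33, 42, 10)})
        summary = cst.summarize(table)
        groups = {m: table.loc[table.method == m, "cdl_mm"].to_numpy()
                  for m in ("reference", "SW-HRCT")}
        anova = cst.anova_oneway(groups)
        dunnett = cst.dunnett_vs_control(groups, "reference")
        return summary, anova, dunnett

    def test_missing_stage_listed(self):
        with pytest.raises(cst.StatsError, match="anova"):
            cst.build_report(summary=[], anova=None, dunnett=[])

    def test_deterministic_and_renders(self):
        summary, anova, dunnett = self._inputs()
        r1 = cst.build_report(summary, anova, dunnett)
        r2 = cst.build_report(summary, anova, dunnett)
        assert r1 == r2
        md = cst.report_to_markdown(r1)
        assert "Dunnett" in md and "ANOVA" in md

    def test_small_p_formatting(self):
        summary, anova, dunnett = self._inputs()
        report = cst.build_report(summary, anova, dunnett)
        for d in report["dunnett"]:
            if d["p_adjusted"] < 0.001:
                assert d["p_formatted"] == "< 0.001"
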