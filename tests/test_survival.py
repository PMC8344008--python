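"""Cox regression, Kaplan–Meier, maxstat cutoffs, Martingale residuals."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from psmavol import (
    CohortSimSpec,
    DegenerateModelError,
    InputError,
    correlate_and_compare,
    cox_fit,
    cox_score_test,
    km_logrank,
    km_median,
    logrank_z,
    martingale_residuals,
    maxstat_cutoff,
    median_binarize,
    run_paper_analysis,
    simulate_cohort,
)

from oracles import exhaustive_maxstat


class TestCoxFit:
    def test_recovers_injected_log_tv_hazard(self):
        spec = CohortSimSpec(
            n_patients=500, beta_log_tv=np.log(1.618), beta_response=0.0,
            beta_low_expression=0.0, frac_low_expression=0.0,
            censoring_rate=0.2, seed=17,
        )
        res = cox_fit(simulate_cohort(spec), ["tv_baseline_ml"])
        eff = res.effect("tv_baseline_ml")
        assert 1.45 <= eff.hazard_ratio <= 1.80
        assert eff.ci_lower <= eff.hazard_ratio <= eff.ci_upper

    def test_constant_covariate_degenerate(self, null_cohort):
        df = null_cohort.copy()
        df["const"] = 3.0
        with pytest.raises(DegenerateModelError):
            cox_fit(df, ["const"])

    def test_too_few_events_rejected(self, null_cohort):
        df = null_cohort.copy()
        df["event"] = False
        with pytest.raises(DegenerateModelError):
            cox_fit(df, ["tv_baseline_ml"])

    def test_nonpositive_covariate_under_log_rejected(self, null_cohort):
        df = null_cohort.copy()
        df.loc[df.index[0], "tv_baseline_ml"] = 0.0
        with pytest.raises(InputError, match="tv_baseline_ml"):
            cox_fit(df, ["tv_baseline_ml"])

    def test_missing_rows_dropped_and_counted(self, null_cohort):
        df = null_cohort.copy()
        df.loc[df.index[:4], "ldh"] = np.nan
        res = cox_fit(df, ["tv_baseline_ml", "ldh"])
        assert res.n_dropped == 4
        assert res.n_used == len(df) - 4

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_r_coxph_on_fixture(self, tmp_path):
        """Independent oracle: R survival::coxph (Efron ties) on the same data."""
        cohort = simulate_cohort(CohortSimSpec(n_patients=60, seed=23))
        res = cox_fit(cohort, ["tv_baseline_ml"])
        csv = tmp_path / "cohort.csv"
        cohort[["os_months", "event", "tv_baseline_ml"]].to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            library(survival)
            d <- read.csv("{csv}")
            f <- coxph(Surv(os_months, event == "True" | event == "TRUE" | event == TRUE)
                       ~ log(tv_baseline_ml), data = d, ties = "efron")
            cat(sprintf("%.10f", coef(f)))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_coef = float(out.stdout.strip().split()[-1])
        assert res.effect("tv_baseline_ml").coef == pytest.approx(r_coef, abs=1e-4)


class TestKaplanMeier:
    def test_hand_worked_medians(self, km_fixture):
        res = km_logrank(km_fixture, "group")
        low, high = res.groups
        assert low.median_months == pytest.approx(4.0)
        assert high.median_months == pytest.approx(12.0)

    def test_identical_groups_give_null_logrank(self):
        half = pd.DataFrame({"os_months": [3.0, 5.0, 8.0], "event": [True, True, False]})
        df = pd.concat([half, half], ignore_index=True)
        df["group"] = [False] * 3 + [True] * 3
        res = km_logrank(df, "group")
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_km_curve_properties(self, null_cohort):
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(null_cohort["os_months"], null_cohort["event"])
        sf = kmf.survival_function_.iloc[:, 0].to_numpy()
        assert sf[0] == pytest.approx(1.0)
        assert np.all(np.diff(sf) <= 1e-12)  # non-increasing

    def test_median_never_reached_is_nan(self):
        assert np.isnan(km_median(np.array([5.0, 6.0, 7.0]), np.array([False, False, False])))

    def test_one_empty_group_rejected(self, km_fixture):
        df = km_fixture.assign(group=True)
        with pytest.raises(InputError):
            km_logrank(df, "group")


class TestMedianBinarize:
    def test_even_n_midpoint(self):
        flag = median_binarize(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(flag) == [False, False, True, True]

    def test_odd_n_tie_goes_low(self):
        flag = median_binarize(pd.Series([1.0, 2.0, 3.0]))
        assert list(flag) == [False, False, True]

    def test_all_equal_degenerate(self):
        with pytest.raises(DegenerateModelError):
            median_binarize(pd.Series([5.0, 5.0, 5.0]))


class TestScoreLogrankEquivalence:
    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(31)
        t = rng.exponential(10, size=40)
        e = rng.random(40) < 0.7
        g = rng.random(40) < 0.5
        z_lr = logrank_z(t, e, g)
        z_score, chi2 = cox_score_test(t, e, g.astype(float))
        assert abs(z_lr) == pytest.approx(abs(z_score), abs=1e-6)
        assert chi2 == pytest.approx(z_lr**2, abs=1e-6)


class TestMaxstat:
    def test_separated_subpopulations(self):
        rng = np.random.default_rng(3)
        n = 20
        x = np.concatenate([rng.normal(1, 0.05, n), rng.normal(10, 0.05, n)])
        t = np.concatenate([rng.uniform(1, 5, n), rng.uniform(20, 30, n)])
        e = np.ones(2 * n, bool)
        df = pd.DataFrame({"x": x, "os_months": t, "event": e})
        res = maxstat_cutoff(df, "x")
        gap_lo, gap_hi = x[x < 5].max(), x[x > 5].min()
        assert res.cutoff == pytest.approx(0.5 * (gap_lo + gap_hi))
        assert res.n_low == n and res.n_high == n

    def test_two_distinct_values_forced_midpoint(self):
        df = pd.DataFrame(
            {
                "x": [1.0, 1.0, 2.0, 2.0, 1.0, 2.0],
                "os_months": [2.0, 3.0, 9.0, 8.0, 2.5, 7.0],
                "event": [True] * 6,
            }
        )
        res = maxstat_cutoff(df, "x")
        assert res.cutoff == pytest.approx(1.5)

    def test_degenerate_covariate_rejected(self):
        df = pd.DataFrame(
            {"x": [1.0] * 6, "os_months": [1, 2, 3, 4, 5, 6.0], "event": [True] * 6}
        )
        with pytest.raises(InputError):
            maxstat_cutoff(df, "x")

    def test_matches_exhaustive_oracle(self, null_cohort):
        res = maxstat_cutoff(null_cohort, "tv_baseline_ml")
        cut, stat = exhaustive_maxstat(
            null_cohort["os_months"].values,
            null_cohort["event"].values,
            null_cohort["tv_baseline_ml"].values,
        )
        assert res.cutoff == pytest.approx(cut)
        assert abs(res.statistic) == pytest.approx(stat, abs=1e-9)

    def test_permutation_p_on_null_is_unremarkable(self, null_cohort):
        res = maxstat_cutoff(null_cohort, "tv_baseline_ml", n_permutations=200, seed=4)
        assert res.p_value > 0.05  # covariate independent of survival


class TestMartingale:
    def test_null_model_equals_event_minus_nelson_aalen(self, null_cohort):
        from lifelines import NelsonAalenFitter

        resid = martingale_residuals(null_cohort)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(
            null_cohort["os_months"], null_cohort["event"]
        )
        H = naf.cumulative_hazard_.iloc[:, 0]
        expected = null_cohort["event"].astype(float).to_numpy() - np.array(
            [H[H.index <= t].iloc[-1] if (H.index <= t).any() else 0.0
             for t in null_cohort["os_months"]]
        )
        assert np.allclose(resid.to_numpy(), expected, atol=1e-10)

    def test_residuals_sum_to_zero_null_and_fitted(self, null_cohort):
        assert abs(martingale_residuals(null_cohort).sum()) < 1e-8
        fit = cox_fit(null_cohort, ["tv_baseline_ml"])
        resid = martingale_residuals(null_cohort, fit, ["tv_baseline_ml"])
        assert abs(resid.sum()) < 1e-8
        assert resid.max() <= 1.0 + 1e-12

    def test_censored_at_first_event_has_negative_residual(self):
        df = pd.DataFrame(
            {"os_months": [2.0, 2.0, 5.0, 7.0], "event": [True, False, True, True]}
        )
        resid = martingale_residuals(df)
        assert resid.iloc[1] < 0
        assert resid.iloc[1] == pytest.approx(-1.0 / 4.0)  # -H(t1) = -1/4

    def test_threshold_effect_shows_in_residuals(self):
        """Covariate with a true step effect: null-model residuals correlate
        positively with the high side of the step."""
        rng = np.random.default_rng(8)
        n = 300
        x = rng.uniform(0, 10, n)
        lam = np.where(x > 5, 0.3, 0.05)
        t = rng.exponential(1 / lam)
        df = pd.DataFrame({"os_months": t, "event": np.ones(n, bool), "x": x})
        resid = martingale_residuals(df)
        assert np.corrcoef((x > 5).astype(float), resid)[0, 1] > 0.3


class TestCorrelation:
    def test_monotone_and_antimonotone(self):
        df = pd.DataFrame(
            {
                "tv_decline_pct": [1.0, 2, 3, 4, 5],
                "psa_decline_pct": [10.0, 20, 30, 40, 50],
                "psa_responder": [False, False, True, True, True],
            }
        )
        assert correlate_and_compare(df)["spearman_rho"] == pytest.approx(1.0)
        df["psa_decline_pct"] = df["psa_decline_pct"][::-1].to_numpy()
        assert correlate_and_compare(df)["spearman_rho"] == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame(
            {"tv_decline_pct": [1.0], "psa_decline_pct": [2.0], "psa_responder": [True]}
        )
        with pytest.raises(InputError):
            correlate_and_compare(df)

    def test_simulator_rank_correlation_near_target(self):
        """The cohort generator couples volumetric and PSA decline with
        Spearman rho ~= 0.67; at n=33 the estimate should usually land
        within +-0.25 (checked over 100 replicates)."""
        hits = 0
        for rep in range(100):
            c = simulate_cohort(
                CohortSimSpec(n_patients=33, frac_low_expression=0.0, seed=5000 + rep)
            )
            rho = correlate_and_compare(c)["spearman_rho"]
            if abs(rho - 0.67) <= 0.25:
                hits += 1
        assert hits >= 90


class TestRunPaperAnalysis:
    def test_report_structure_on_simulated_cohort(self):
        cohort = simulate_cohort(CohortSimSpec(n_patients=80, seed=41))
        report = run_paper_analysis(cohort)
        models = report["models"]
        assert "uni_cox_tv_baseline_ml" in models
        assert "uni_cox_tv_response_full" in models
        assert "uni_cox_tv_response_high_expr" in models
        assert "km_median_tv_baseline_ml" in models
        assert abs(models["martingale_null"]["sum"]) < 1e-8
        assert report["median_os_months"] > 0

    def test_km_fixture_medians_propagate(self, km_fixture):
        df = km_fixture.rename(columns={"group": "tv_responder"}).copy()
        df["tv_ratio"] = [2.0, 1.1, 0.9, 2.5, 3.0, 1.0]
        df["low_expression"] = False
        df["mean_suv_max_baseline"] = [20.0, 21, 22, 23, 24, 25]
        report = run_paper_analysis(df)
        km = report["models"]["km_tv_responder_full"]
        assert km["groups"][0]["median_months"] == pytest.approx(4.0)
        assert km["groups"][1]["median_months"] == pytest.approx(12.0)

    def test_null_cohort_rarely_significant(self, null_cohort):
        report = run_paper_analysis(null_cohort)
        ps = [
            m["covariates"][next(iter(m["covariates"]))]["p"]
            for k, m in report["models"].items()
            if isinstance(m, dict) and "covariates" in m and k.startswith("uni_")
        ]
        assert sum(p < 0.05 for p in ps) <= max(2, int(0.3 * len(ps)))
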