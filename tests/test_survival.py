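import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cescore import simulate as sim
from cescore.survival import (
    FitFailureError,
    UndefinedTestError,
    cox_fit,
    five_year_survival_test,
    km_estimate,
    logrank_test,
    stratified_treatment_analysis,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def logrank_oracle(time, event, group):
    """Two-group log-rank by explicit hypergeometric accumulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g1 = np.asarray(group) == np.asarray(group)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var
    return stat, stats.chi2.sf(stat, 1)


def cox_loglik_oracle(beta, time, event, x):
    """Partial log-likelihood for one covariate, no ties."""
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


def cox_grid_oracle(time, event, x, lo=-5.0, hi=5.0, step=1e-5):
    grid = np.arange(lo, hi, step)
    risk_sets = [time >= time[i] for i in np.flatnonzero(event == 1)]
    ll = np.zeros_like(grid)
    for i, risk in zip(np.flatnonzero(event == 1), risk_sets):
        ll += grid * x[i] - np.log(np.exp(np.outer(grid, x[risk])).sum(axis=1))
    return grid[np.argmax(ll)]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKM:
    def test_worked_example(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        np.testing.assert_allclose(km.times, [1, 2, 4])
        np.testing.assert_allclose(km.survival, [0.8, 0.6, 0.3])
        assert km.survival_at(3) == pytest.approx(0.6)
        assert km.survival_at(0.5) == 1.0

    def test_no_events_flat_curve(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100) == 1.0

    def test_duplicating_records_leaves_curve_unchanged(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 0]
        a = km_estimate(t, e)
        b = km_estimate(t * 2, e * 2)
        np.testing.assert_allclose(a.survival, b.survival)

    def test_curve_non_increasing_and_starts_at_one(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2, 50)
        e = rng.integers(0, 2, 50)
        km = km_estimate(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival_at(0) <= 1.0 and km.survival_at(-0.0) <= 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 0])

    def test_risk_table(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        np.testing.assert_array_equal(km.at_risk, [5, 4, 2])
        np.testing.assert_array_equal(km.n_events, [1, 1, 1])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        # same event pattern in both groups at shared times
        res = logrank_test(t, e, ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_toy_matches_brute_force(self):
        t = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = logrank_test(t, e, g)
        stat, p = logrank_oracle(t, e, g)
        assert res.statistic == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_random_cohorts_match_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 40
            t = rng.exponential(3, n).round(2)  # induces ties
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            g = rng.choice(["a", "b"], n)
            if len(set(g)) < 2:
                continue
            res = logrank_test(t, e, g)
            stat, _ = logrank_oracle(t, e, g)
            assert res.statistic == pytest.approx(stat, rel=1e-8)

    def test_zero_events_undefined(self):
        with pytest.raises(UndefinedTestError):
            logrank_test([1, 2], [0, 0], ["a", "b"])

    def test_time_transform_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(2, 30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        g = rng.choice(["a", "b"], 30)
        a = logrank_test(t, e, g)
        b = logrank_test(np.exp(t), e, g)  # strictly increasing transform
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_k_group_supported(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(2, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        g = np.repeat(["a", "b", "c"], 20)
        res = logrank_test(t, e, g)
        assert res.df == 2

    def test_detects_planted_hazard(self):
        hits = 0
        for seed in range(30):
            cfg = sim.SimConfig(seed=seed, hazard_beta=0.7)
            rng = np.random.default_rng(seed)
            ces = pd.Series(rng.normal(100, 5, 300),
                            index=[f"s{i}" for i in range(300)])
            cohort = sim.simulate_cohort(cfg, ces)
            from cescore.scoring import stratify
            strata = stratify(ces, mode="quantile_tertile")
            keep = strata.labels != "intermediate"
            sub = cohort.loc[keep]
            res = logrank_test(sub["time"], sub["event"], strata.labels.loc[keep])
            hits += res.p_value < 0.01
        assert hits >= 27  # >= 90% of seeds


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

class TestCox:
    def test_binary_covariate_matches_grid_search(self):
        df = pd.DataFrame(
            {
                "time": [1.0, 3.0, 5.0, 2.0, 4.0, 6.0],
                "event": [1, 1, 1, 1, 1, 0],
                "x": [0, 0, 0, 1, 1, 1],
            }
        )
        fit = cox_fit(df, ["x"])
        beta_oracle = cox_grid_oracle(
            df["time"].to_numpy(), df["event"].to_numpy(), df["x"].to_numpy()
        )
        assert fit.table.loc["x", "coef"] == pytest.approx(beta_oracle, abs=1e-4)

    def test_continuous_covariate_matches_grid_search(self):
        rng = np.random.default_rng(5)
        n = 12
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * x))
        df = pd.DataFrame({"time": t, "event": np.ones(n, int), "x": x})
        fit = cox_fit(df, ["x"])
        beta_oracle = cox_grid_oracle(t, np.ones(n, int), x)
        assert fit.table.loc["x", "coef"] == pytest.approx(beta_oracle, abs=1e-4)

    def test_ci_contains_hr_and_hr_positive(self):
        rng = np.random.default_rng(6)
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        c = rng.uniform(0, 3, n)
        df = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x})
        fit = cox_fit(df, ["x"])
        lo, hi = fit.ci("x")
        assert 0 < lo <= fit.hr("x") <= hi

    def test_null_coverage(self):
        rng = np.random.default_rng(7)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 80
            x = rng.normal(size=n)
            t = rng.exponential(1.0, n)
            c = rng.uniform(0, 2.5, n)
            df = pd.DataFrame(
                {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
            )
            fit = cox_fit(df, ["x"])
            lo, hi = fit.ci("x")
            covered += lo <= 1.0 <= hi
        assert 0.90 <= covered / n_rep <= 0.99

    def test_centering_invariance(self):
        rng = np.random.default_rng(8)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        df = pd.DataFrame({"time": t, "event": np.ones(n, int), "x": x})
        fit1 = cox_fit(df, ["x"])
        df2 = df.assign(x=df["x"] + 100.0)
        fit2 = cox_fit(df2, ["x"])
        assert fit1.table.loc["x", "coef"] == pytest.approx(
            fit2.table.loc["x", "coef"], abs=1e-6
        )

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(9)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        df = pd.DataFrame({"time": t, "event": np.ones(n, int), "x": x})
        fit1 = cox_fit(df, ["x"])
        fit2 = cox_fit(df.assign(x=2.0 * df["x"]), ["x"])
        assert fit2.table.loc["x", "coef"] == pytest.approx(
            fit1.table.loc["x", "coef"] / 2.0, abs=1e-6
        )

    def test_categorical_expansion_with_reference(self):
        rng = np.random.default_rng(10)
        n = 90
        grade = rng.choice(["1", "2", "3"], n)
        t = rng.exponential(np.exp(-0.5 * (grade == "3")))
        df = pd.DataFrame({"time": t, "event": np.ones(n, int), "grade": grade})
        fit = cox_fit(df, ["grade"])
        assert {"grade[2]", "grade[3]"} == set(fit.table.index)
        fit_ref3 = cox_fit(df, ["grade"], reference_levels={"grade": "3"})
        assert {"grade[1]", "grade[2]"} == set(fit_ref3.table.index)

    def test_constant_covariate_error(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1], "x": [1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_more_parameters_than_events_error(self):
        df = pd.DataFrame(
            {"time": [1, 2, 3, 4], "event": [1, 0, 0, 0],
             "x": [1, 2, 3, 4], "y": [4, 3, 2, 1]}
        )
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["x", "y"])

    def test_score_test_agrees_with_logrank_on_untied_data(self):
        rng = np.random.default_rng(11)
        n = 40
        x = (rng.random(n) > 0.5).astype(float)
        t = rng.exponential(np.exp(-0.7 * x))
        e = np.ones(n, int)
        # score test at beta=0 from the oracle partial likelihood
        eps = 1e-5
        u0 = (cox_loglik_oracle(eps, t, e, x) - cox_loglik_oracle(-eps, t, e, x)) / (2 * eps)
        i0 = -(
            cox_loglik_oracle(eps, t, e, x)
            - 2 * cox_loglik_oracle(0.0, t, e, x)
            + cox_loglik_oracle(-eps, t, e, x)
        ) / eps**2
        score_stat = u0**2 / i0
        res = logrank_test(t, e, x)
        assert res.statistic == pytest.approx(score_stat, rel=1e-4)


# ---------------------------------------------------------------------------
# five-year survival
# ---------------------------------------------------------------------------

class TestFiveYear:
    def test_all_survivors_degenerate(self):
        a = pd.DataFrame({"time": [6, 7], "event": [0, 0]})
        b = pd.DataFrame({"time": [8, 9], "event": [0, 0]})
        res = five_year_survival_test(a, b)
        assert res.proportions == {"A": 1.0, "B": 1.0}
        assert res.p_value == pytest.approx(1.0)

    def test_hand_chi_square(self):
        a = pd.DataFrame({"time": [6.0] * 40 + [1.0] * 10, "event": [0] * 40 + [1] * 10})
        b = pd.DataFrame({"time": [6.0] * 20 + [1.0] * 30, "event": [0] * 20 + [1] * 30})
        res = five_year_survival_test(a, b)
        assert res.statistic == pytest.approx(100 / 6, rel=1e-9)
        assert res.p_value < 0.001

    def test_censored_before_horizon_excluded_and_counted(self):
        a = pd.DataFrame({"time": [6.0] * 5 + [2.0] * 10, "event": [0] * 15})
        b = pd.DataFrame({"time": [6.0] * 5 + [1.0] * 5, "event": [0] * 5 + [1] * 5})
        res = five_year_survival_test(a, b)
        assert res.n_excluded == {"A": 10, "B": 0}
        assert res.counts.loc["A", "surviving"] == 5

    def test_no_classifiable_subjects_error(self):
        a = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        b = pd.DataFrame({"time": [6.0], "event": [0]})
        with pytest.raises(ValueError, match="classifiable"):
            five_year_survival_test(a, b)


# ---------------------------------------------------------------------------
# treatment-stratified analysis
# ---------------------------------------------------------------------------

def simulate_treatment_cohort(seed, n=600, hazard_beta=0.7, treat_beta=-0.9):
    cfg = sim.SimConfig(seed=seed, hazard_beta=hazard_beta, treat_beta=treat_beta)
    rng = np.random.default_rng(seed + 10_000)
    ces = pd.Series(rng.normal(100, 5, n), index=[f"s{i}" for i in range(n)])
    return sim.simulate_cohort(cfg, ces)


class TestStratifiedTreatment:
    def test_four_rows_on_large_cohort(self):
        cohort = simulate_treatment_cohort(seed=0)
        forest = stratified_treatment_analysis(cohort)
        assert {r.label for r in forest.rows} == {
            "treated_within_high",
            "treated_within_low",
            "high_within_treated",
            "high_within_untreated",
        }

    def test_interaction_pattern(self):
        cohort = simulate_treatment_cohort(seed=1)
        forest = stratified_treatment_analysis(cohort)
        high = forest.row("treated_within_high")
        low = forest.row("treated_within_low")
        assert high.hr < 1 and high.cox_p < 0.05
        assert low.ci_low <= 1.0 <= low.ci_high

    def test_small_cells_dropped_with_note(self):
        cohort = simulate_treatment_cohort(seed=2, n=40)
        forest = stratified_treatment_analysis(cohort)
        assert forest.dropped  # high stratum has ~13 subjects -> below floor
        labels = {r.label for r in forest.rows}
        assert "treated_within_high" not in labels

    def test_null_interaction_coverage(self):
        covered = 0
        n_rep = 40
        for seed in range(n_rep):
            cohort = simulate_treatment_cohort(seed=seed, hazard_beta=0.0, treat_beta=0.0)
            forest = stratified_treatment_analysis(cohort)
            r = forest.row("treated_within_high")
            covered += r.ci_low <= 1.0 <= r.ci_high
        assert covered >= 0.85 * n_rep
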