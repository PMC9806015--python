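import numpy as np
import pandas as pd
import pytest

import spatialtme as st
from spatialtme.survival import (
    IRRSModel,
    cox_unpenalized_reference,
    delong_test,
    lasso_cox_select,
)
from spatialtme.synthetic import CohortSpec, gaussian_features, simulate_cohort


def exp_cohort(n, log_hr, censoring, seed, names=("a",)):
    spec = CohortSpec(
        n_patients=n, true_log_hr=log_hr, censoring_rate=censoring, seed=seed
    )
    return simulate_cohort(spec, gaussian_features(list(names)))


class TestStratifiedSplit:
    def test_553_patients_split_387_166(self):
        df = pd.DataFrame(
            {"event": np.r_[np.ones(240, int), np.zeros(313, int)],
             "time_days": np.arange(553) + 1.0}
        )
        train, test = st.stratified_split(df, seed=0)
        assert (len(train), len(test)) == (387, 166)
        assert len(set(train.index) & set(test.index)) == 0

    def test_ten_patients_split_7_3(self):
        df = pd.DataFrame({"event": [0, 1] * 5, "time_days": np.arange(10) + 1.0})
        train, test = st.stratified_split(df, seed=1)
        assert (len(train), len(test)) == (7, 3)

    def test_event_proportion_preserved_across_seeds(self):
        df = exp_cohort(300, {"a": 0.5}, 0.4, seed=2)
        overall = df["event"].mean()
        for seed in range(100):
            train, _ = st.stratified_split(df, seed=seed)
            assert abs(train["event"].mean() - overall) < 0.02

    def test_split_is_deterministic_per_seed_and_varies_across_seeds(self):
        df = exp_cohort(100, {"a": 0.3}, 0.3, seed=3)
        t1, _ = st.stratified_split(df, seed=5)
        t2, _ = st.stratified_split(df, seed=5)
        t3, _ = st.stratified_split(df, seed=6)
        assert list(t1.index) == list(t2.index)
        assert list(t1.index) != list(t3.index)

    def test_tiny_stratum_is_a_validation_error(self):
        df = pd.DataFrame({"event": [1] + [0] * 9, "time_days": np.arange(10) + 1.0})
        with pytest.raises(ValueError):
            st.stratified_split(df)


class TestUnivariateCox:
    def test_constant_variable_is_excluded(self):
        df = exp_cohort(100, {"a": 0.0}, 0.2, seed=4)
        df["const"] = 1.0
        with pytest.raises(ValueError):
            st.univariate_cox(df, "const")

    def test_null_variable_ci_covers_one(self):
        covered = 0
        for seed in range(100):
            df = exp_cohort(2000, {}, 0.3, seed=seed, names=("x",))
            res = st.univariate_cox(df, "x")
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 93


class TestLassoCox:
    def test_zero_penalty_limit_matches_unpenalized_cox(self):
        df = exp_cohort(500, {"a": 0.5, "b": -0.3}, 0.2, seed=11, names=("a", "b", "c"))
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        X = df[["a", "b", "c"]].to_numpy()
        y = Surv.from_arrays(df["event"].astype(bool), df["time_days"])
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e-9], fit_baseline_model=False)
        m.fit(X, y)
        ref = cox_unpenalized_reference(df, ["a", "b", "c"])
        assert np.abs(m.coef_.ravel() - ref).max() < 1e-3

    def test_full_shrinkage_end_of_path_selects_nothing(self):
        df = exp_cohort(200, {}, 0.3, seed=12, names=tuple("abcde"))
        path = lasso_cox_select(df, list("abcde"), folds=5, seed=0)
        # the largest penalty of the path shrinks every coefficient to zero
        first = path.coefs.iloc[:, 0]
        assert (first == 0).all()

    def test_pure_noise_candidates_select_few(self):
        names = tuple(f"n{i}" for i in range(8))
        df = exp_cohort(250, {}, 0.3, seed=13, names=names)
        path = lasso_cox_select(df, list(names), folds=5, seed=0)
        assert len(path.selected) <= 3


class TestIrrsScore:
    def test_zero_weights_give_zero_score(self):
        model = IRRSModel(variables=["a"], weights={"a": 0.0}, cutoff=0.0)
        feats = pd.DataFrame({"a": [0.3, 0.9]})
        assert (st.compute_irrs(feats, model) == 0.0).all()

    def test_forced_arithmetic_half_ln2(self):
        model = IRRSModel(variables=["a"], weights={"a": np.log(2)}, cutoff=0.0)
        feats = pd.DataFrame({"a": [0.5]})
        assert st.compute_irrs(feats, model).iloc[0] == pytest.approx(
            0.5 * np.log(2)
        )

    def test_monotone_in_risk_variables(self):
        model = IRRSModel(
            variables=["a", "b"], weights={"a": np.log(2), "b": -0.4}, cutoff=0.0
        )
        feats = pd.DataFrame({"a": [0.1, 0.2, 0.9], "b": [1.0, 1.0, 1.0]})
        s = st.compute_irrs(feats, model)
        assert s.is_monotonic_increasing

    def test_linearity_in_the_feature_vector(self):
        model = IRRSModel(
            variables=["a", "b"], weights={"a": 0.7, "b": -0.2}, cutoff=0.0
        )
        feats = pd.DataFrame({"a": [0.4], "b": [0.8]})
        s1 = st.compute_irrs(feats, model).iloc[0]
        s3 = st.compute_irrs(3 * feats, model).iloc[0]
        assert s3 == pytest.approx(3 * s1)

    def test_missing_variable_is_flagged(self):
        model = IRRSModel(variables=["zz"], weights={"zz": 1.0}, cutoff=0.0)
        with pytest.raises(KeyError):
            st.compute_irrs(pd.DataFrame({"a": [1.0]}), model)


class TestOptimalCutoff:
    def test_two_distinct_scores_cut_between_them(self):
        rng = np.random.default_rng(5)
        scores = np.r_[np.zeros(15), np.ones(15)]
        time = np.r_[rng.exponential(100, 15), rng.exponential(30, 15)]
        event = np.ones(30, int)
        cut, chi2 = st.optimal_cutoff(scores, time, event)
        assert 0.0 <= cut < 1.0
        assert chi2 > 0

    def test_bimodal_scores_with_true_separation_recover_the_gap(self):
        rng = np.random.default_rng(6)
        n = 150
        group = rng.integers(0, 2, n)
        scores = np.where(group, rng.normal(2.0, 0.3, n), rng.normal(0.0, 0.3, n))
        time = np.where(group, rng.exponential(50, n), rng.exponential(150, n))
        event = np.ones(n, int)
        cut, chi2 = st.optimal_cutoff(scores, time, event)
        assert 0.7 < cut < 1.5  # between the modes
        assert chi2 > 10

    def test_null_scores_yield_unremarkable_statistic(self):
        rng = np.random.default_rng(7)
        n = 200
        scores = rng.normal(size=n)
        time = rng.exponential(100, n)
        event = np.ones(n, int)
        _, chi2 = st.optimal_cutoff(scores, time, event)
        # max over ~81 correlated scans of a chi2(1) stays modest under the null
        assert chi2 < 15

    def test_constant_scores_are_an_error(self):
        with pytest.raises(ValueError):
            st.optimal_cutoff(
                np.ones(30), np.arange(30) + 1.0, np.ones(30, int)
            )


class TestKmAndCoxReporting:
    def test_km_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(50, 100)
        rep = st.km_logrank(t, np.ones(100, int), np.zeros(100, int))
        curve = rep.km_curves[0]
        for q in (25, 50, 75):
            tq = np.percentile(t, q)
            emp = np.mean(t > tq)
            km = curve[curve["time"] <= tq]["survival"].iloc[-1]
            assert km == pytest.approx(emp, abs=1e-9)

    def test_hazard_ratio_recovery_through_group_label(self):
        spec = CohortSpec(
            n_patients=550, true_log_hr={"grp": np.log(2.7)},
            censoring_rate=0.2, seed=9,
        )
        df = simulate_cohort(
            spec, lambda n, rng: pd.DataFrame({"grp": rng.integers(0, 2, n)})
        )
        mv = st.multivariate_cox(df, ["grp"])
        assert mv.loc["grp", "hr"] == pytest.approx(2.7, rel=0.25)

    def test_duplicated_covariate_raises_collinearity_error(self):
        df = exp_cohort(100, {"a": 0.5}, 0.2, seed=10)
        df["a2"] = df["a"]
        with pytest.raises(ValueError):
            st.multivariate_cox(df, ["a", "a2"])

    def test_adjusted_hr_close_to_unadjusted_for_independent_covariates(self):
        spec = CohortSpec(
            n_patients=2000, true_log_hr={"grp": 0.7}, censoring_rate=0.2, seed=14
        )
        df = simulate_cohort(
            spec, lambda n, rng: pd.DataFrame({"grp": rng.integers(0, 2, n)})
        )
        un = st.univariate_cox(df, "grp")
        mv = st.multivariate_cox(df, ["grp", "age", "sex"])
        assert mv.loc["grp", "log_hr"] == pytest.approx(un.log_hr, abs=0.1)


class TestTimeDependentAuc:
    def test_perfect_marker_reaches_auc_one(self):
        rng = np.random.default_rng(11)
        n = 300
        time = rng.exponential(500, n)
        event = np.ones(n, int)
        horizon = 365
        scores = ((time <= horizon)).astype(float)
        aucs, _ = st.time_dependent_auc(scores, time, event, horizons=(horizon,))
        assert aucs[horizon] == pytest.approx(1.0)

    def test_negated_score_flips_the_auc(self):
        df = exp_cohort(400, {"a": 0.8}, 0.2, seed=12)
        aucs, _ = st.time_dependent_auc(
            df["a"], df["time_days"], df["event"], horizons=(365,)
        )
        flipped, _ = st.time_dependent_auc(
            -df["a"], df["time_days"], df["event"], horizons=(365,)
        )
        assert flipped[365] == pytest.approx(1 - aucs[365], abs=1e-9)

    def test_horizon_beyond_follow_up_is_missing(self):
        df = exp_cohort(100, {"a": 0.5}, 0.2, seed=13)
        aucs, _ = st.time_dependent_auc(
            df["a"], df["time_days"], df["event"],
            horizons=(int(df["time_days"].max() * 10),),
        )
        assert np.isnan(list(aucs.values())[0])


class TestCohortSummary:
    def test_event_percentage_and_median_without_censoring(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(1000, 201)
        df = pd.DataFrame({"time_days": t, "event": np.ones(201, int)})
        s = st.cohort_summary(df)
        assert s["event_pct"] == pytest.approx(100.0)
        assert s["median_dfs_days"] == pytest.approx(np.median(t), rel=0.01)

    def test_one_year_recurrence_matches_exponential_closed_form(self):
        lam = 1 / 1000.0
        n = 4000
        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            {"time_days": rng.exponential(1 / lam, n), "event": np.ones(n, int)}
        )
        s = st.cohort_summary(df)
        expected = 100 * (1 - np.exp(-365 * lam))
        se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
        assert abs(s["recurrence_rate_365d"] - expected) < 3 * se


class TestCutoffTransfer:
    def test_cutoff_learned_on_train_is_applied_verbatim(self):
        df = exp_cohort(300, {"a": 0.9}, 0.3, seed=16)
        train, test = st.stratified_split(df, seed=0)
        model = st.fit_irrs(train, ["a"], seed=0)
        scored = st.apply_irrs(model, test)
        assert (scored["irrs_group"] == np.where(
            scored["irrs"] > model.cutoff, "high", "low"
        )).all()


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(17)
        labels = rng.integers(0, 2, 100)
        s = rng.normal(size=100)
        auc_a, auc_b, p = delong_test(labels, s, s)
        assert auc_a == auc_b
        assert p == 1.0

    def test_informative_beats_noise(self):
        rng = np.random.default_rng(18)
        labels = rng.integers(0, 2, 400)
        good = labels + rng.normal(0, 0.5, 400)
        noise = rng.normal(size=400)
        auc_a, auc_b, p = delong_test(labels, good, noise)
        assert auc_a > 0.8 and abs(auc_b - 0.5) < 0.1
        assert p < 0.001
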