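import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines import AalenAdditiveFitter, CoxPHFitter, NelsonAalenFitter

from seqtrials import (MSMDesign, ScenarioParams, apply_artificial_censoring,
                       build_trials, fit_aalen_msm, fit_cox_msm,
                       simulate_cohort, to_person_period)
from seqtrials import hazard_msm
from seqtrials.weights import WeightSeries

common_effect_test = hazard_msm.test_common_treatment_effect


def _static_survival_data(n=300, seed=2):
    """Single-interval right-censored data with static covariates."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    a = rng.integers(0, 2, n)
    h = np.clip(0.5 + 0.2 * a + 0.1 * x, 0.01, None)
    T = rng.exponential(1 / h)
    event = T < 1.0
    T = np.minimum(T, 1.0)
    pp = pd.DataFrame({"tstart": 0.0, "tstop": T, "event": event.astype(int),
                       "A": a, "x": x})
    pp.attrs["K"] = 1
    return pp


class TestAalen:
    def test_intercept_only_equals_nelson_aalen(self, cohort_s1, pp_s1):
        fit = fit_aalen_msm(pp_s1, MSMDesign(treatment=None))
        naf = NelsonAalenFitter().fit(cohort_s1.T, cohort_s1.event)
        cum = fit.cumulative()
        ref = naf.cumulative_hazard_.reindex(cum["time"], method="ffill")
        np.testing.assert_allclose(cum["intercept"].to_numpy(),
                                   ref.iloc[:, 0].to_numpy(), atol=1e-10)

    def test_weight_scale_invariance(self, pp_s1):
        design = MSMDesign(treatment="lags", covariates=("L0",))
        w = WeightSeries(values=np.full(len(pp_s1), 1.0), kind="iptw")
        w5 = WeightSeries(values=np.full(len(pp_s1), 5.0), kind="iptw")
        f1 = fit_aalen_msm(pp_s1, design, weights=w)
        f5 = fit_aalen_msm(pp_s1, design, weights=w5)
        np.testing.assert_allclose(f1.increments, f5.increments, atol=1e-12)

    def test_unit_weights_match_reference_additive_fit(self):
        pp = _static_survival_data()
        fit = fit_aalen_msm(pp, MSMDesign(treatment="current",
                                          covariates=("x",)))
        aaf = AalenAdditiveFitter(coef_penalizer=0.0, smoothing_penalizer=0.0)
        df = pd.DataFrame({"T": pp["tstop"], "E": pp["event"],
                           "a": pp["A"], "x": pp["x"]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aaf.fit(df, duration_col="T", event_col="E")
        cum = fit.cumulative().set_index("time")
        ref = aaf.cumulative_hazards_.reindex(cum.index, method="ffill")
        for ours, theirs in [("intercept", "Intercept"), ("A", "a"),
                             ("x", "x")]:
            np.testing.assert_allclose(cum[ours].to_numpy(),
                                       ref[theirs].to_numpy(), atol=1e-8)

    def test_lag_columns_enter_from_their_interval(self, pp_s1):
        fit = fit_aalen_msm(pp_s1, MSMDesign(treatment="lags"))
        for j in range(1, 5):
            col = fit.columns.index(f"A_lag{j}")
            early = fit.intervals < j
            assert np.all(fit.increments[early, col] == 0.0)
            assert np.any(fit.increments[~early, col] != 0.0)

    def test_randomized_treatment_slope_recovery(self):
        # with no frailty in the hazard and randomized treatment the
        # sequential-trials additive MSM recovers the direct treatment
        # effect over the first interval after initiation
        params = ScenarioParams(alphaU=0.0, gammaL=0.0)
        cohort = simulate_cohort(params, n=50_000, seed=17)
        stack = apply_artificial_censoring(build_trials(cohort), cohort)
        fit = fit_aalen_msm(stack, MSMDesign(treatment="arm",
                                             covariates=("L_base",)))
        ba1 = fit.cum_at([1.0])["arm"].iloc[0]
        assert ba1 == pytest.approx(params.alphaA, abs=0.01)

    def test_pooled_and_per_trial_paths_agree(self, cohort_s1):
        # under the generator the treatment coefficient is shared across
        # trials, so trial-0-only and pooled paths estimate the same curve
        stack = apply_artificial_censoring(build_trials(cohort_s1), cohort_s1)
        design = MSMDesign(treatment="arm", covariates=("L_base",))
        pooled = fit_aalen_msm(stack, design)
        t0 = fit_aalen_msm(stack[stack["trial"] == 0], design)
        for tau in (1.0, 2.0):
            d = abs(pooled.cum_at([tau])["arm"].iloc[0]
                    - t0.cum_at([tau])["arm"].iloc[0])
            assert d < 0.05


class TestCox:
    def test_no_covariates_baseline_is_weighted_nelson_aalen(self, pp_s1):
        rng = np.random.default_rng(0)
        w = WeightSeries(values=rng.uniform(0.5, 2.0, len(pp_s1)), kind="iptw")
        fit = fit_cox_msm(pp_s1, MSMDesign(treatment=None), weights=w)
        # independent weighted Nelson-Aalen computation
        tstop = pp_s1["tstop"].to_numpy()
        tstart = pp_s1["tstart"].to_numpy()
        ev = pp_s1["event"].to_numpy() == 1
        order = np.argsort(tstop[ev])
        times = tstop[ev][order]
        expected = []
        for t, wv in zip(times, w.values[ev][order]):
            at_risk = (tstart < t) & (t <= tstop)
            expected.append(wv / w.values[at_risk].sum())
        np.testing.assert_allclose(fit.baseline_increments, expected,
                                   rtol=1e-10)

    def test_unit_weights_match_reference_cox(self):
        pp = _static_survival_data(n=500, seed=4)
        fit = fit_cox_msm(pp, MSMDesign(treatment="current",
                                        covariates=("x",)))
        cph = CoxPHFitter()
        df = pd.DataFrame({"T": pp["tstop"], "E": pp["event"],
                           "A": pp["A"], "x": pp["x"]})
        cph.fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(fit.params[["A", "x"]].to_numpy(),
                                   cph.params_[["A", "x"]].to_numpy(),
                                   atol=1e-6)

    def test_two_group_exponential_log_rate_ratio(self):
        rng = np.random.default_rng(8)
        n = 8000
        a = rng.integers(0, 2, n)
        lam = np.where(a == 1, 0.4, 0.2)
        T = rng.exponential(1 / lam)
        event = T < 1.0
        pp = pd.DataFrame({"tstart": 0.0, "tstop": np.minimum(T, 1.0),
                           "event": event.astype(int), "A": a})
        pp.attrs["K"] = 1
        fit = fit_cox_msm(pp, MSMDesign(treatment="current"))
        assert fit.params["A"] == pytest.approx(np.log(2.0), abs=0.1)

    def test_trial_stratified_baseline(self, cohort_s1):
        stack = apply_artificial_censoring(build_trials(cohort_s1), cohort_s1)
        fit = fit_cox_msm(stack, MSMDesign(treatment="arm",
                                           covariates=("L_base",),
                                           trial_strata=True))
        assert set(fit.strata_baselines) == set(range(5))
        # the standardization default is the trial-0 baseline, which covers
        # the full horizon
        assert fit.baseline_times.max() > 4.0


class TestCommonEffect:
    def test_duplicated_trial_gives_null_statistic(self, cohort_s1):
        stack = apply_artificial_censoring(build_trials(cohort_s1), cohort_s1)
        t0 = stack[stack["trial"] == 0]
        dup = t0.copy()
        dup["trial"] = 1
        both = pd.concat([t0, dup], ignore_index=True)
        res = common_effect_test(
            both, MSMDesign(treatment="arm", covariates=("L_base",)))
        assert res.statistic == pytest.approx(0.0, abs=1e-3)
        assert res.p_value > 0.99

    def test_size_under_homogeneity(self):
        # common effect holds under the generator: rejection near nominal
        rejections = 0
        reps = 25
        for r in range(reps):
            cohort = simulate_cohort("scenario1", n=1200, seed=100 + r)
            stack = apply_artificial_censoring(build_trials(cohort), cohort)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = common_effect_test(
                    stack, MSMDesign(treatment="arm", covariates=("L_base",)))
            rejections += res.p_value < 0.05
        assert rejections / reps <= 0.2

    def test_power_under_heterogeneity(self):
        # a strong arm effect in trial 0 only must be detected more often
        # than the nominal level
        rng = np.random.default_rng(44)
        rejections = 0
        reps = 15
        for _ in range(reps):
            frames = []
            for tr in (0, 1):
                n = 1500
                arm = rng.integers(0, 2, n)
                lam = np.where((arm == 1) & (tr == 0), 0.9, 0.3)
                T = rng.exponential(1 / lam)
                event = T < 2.0
                T = np.minimum(T, 2.0)
                k = (T > 1.0).astype(int) + 1    # rows per person
                for j in (0, 1):
                    alive = T > j
                    frames.append(pd.DataFrame({
                        "id": np.flatnonzero(alive) + tr * n,
                        "trial": tr, "j": j, "tstart": float(j),
                        "tstop": np.minimum(T[alive], j + 1.0),
                        "event": (event[alive] & (T[alive] <= j + 1)).astype(int),
                        "arm": arm[alive], "L_base": 0.0}))
            stack = pd.concat(frames, ignore_index=True)
            res = common_effect_test(
                stack, MSMDesign(treatment="arm"))
            rejections += res.p_value < 0.05
        assert rejections / reps > 0.5
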