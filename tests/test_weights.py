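import numpy as np
import pandas as pd
import pytest

from seqtrials import (apply_artificial_censoring, build_trials, compute_ipacw,
                       compute_ipcw, compute_iptw, fit_treatment_models,
                       simulate_cohort, to_person_period, truncate_weights)
from seqtrials.cohort import LongitudinalCohort, ValidationError
from seqtrials.weights import TreatmentModelSet, WeightSeries


@pytest.fixture(scope="module")
def models_s1(pp_s1):
    return fit_treatment_models(pp_s1, numerator="L0")


class TestTreatmentModels:
    def test_fitted_probabilities_match_empirical_proportions(self):
        # saturated toy data: binary L, one visit; the logistic fit must
        # reproduce the conditional treated proportions exactly
        n = np.array([40, 60])        # L = 0, 1
        treated = np.array([10, 30])
        L, A = [], []
        for l in (0, 1):
            L += [float(l)] * n[l]
            A += [1] * treated[l] + [0] * (n[l] - treated[l])
        cohort = LongitudinalCohort(ids=np.arange(n.sum()),
                                    A=np.array(A)[:, None],
                                    L=np.array(L)[:, None],
                                    T=np.ones(n.sum()),
                                    event=np.zeros(n.sum(), dtype=bool))
        pp = to_person_period(cohort)
        models = fit_treatment_models(pp, numerator="marginal")
        pred = models.denominator.predict(pp)
        expected = np.where(np.array(L) == 1, 30 / 60, 10 / 40)
        np.testing.assert_allclose(pred, expected, atol=1e-8)
        # per-visit numerator reproduces the crude treated fraction
        np.testing.assert_allclose(models.numerator.predict(pp),
                                   40 / 100, atol=1e-8)

    def test_treated_history_rows_never_enter_the_fits(self, cohort_s1, pp_s1,
                                                       models_s1):
        # corrupting rows with treated history must leave the fits unchanged
        pp2 = pp_s1.copy()
        mask = pp2["A_lag1"] == 1
        pp2.loc[mask, "L"] = 999.0
        refit = fit_treatment_models(pp2, numerator="L0")
        np.testing.assert_allclose(refit.denominator.params,
                                   models_s1.denominator.params)
        np.testing.assert_allclose(refit.numerator.params,
                                   models_s1.numerator.params)

    def test_null_confounding_recovers_zero_coefficient(self):
        from seqtrials import ScenarioParams
        cohort = simulate_cohort(ScenarioParams(gammaL=0.0), n=20_000, seed=21)
        pp = to_person_period(cohort)
        models = fit_treatment_models(pp, numerator="marginal")
        # denominator design is [intercept, L]
        assert abs(models.denominator.params[1]) < 0.05


class TestIPTW:
    def test_mean_stabilized_weight_near_one(self, pp_s1, models_s1):
        w = compute_iptw(models_s1, pp_s1, stabilization="conditional_L0")
        means = pd.Series(w.values).groupby(pp_s1["k"].to_numpy()).mean()
        assert (np.abs(means - 1.0) < 0.05).all()

    def test_self_ratio_weights_are_exactly_one(self, pp_s1, models_s1):
        selfed = TreatmentModelSet(denominator=models_s1.denominator,
                                   numerator=models_s1.denominator,
                                   numerator_kind="L0")
        w = compute_iptw(selfed, pp_s1, stabilization="conditional_L0")
        np.testing.assert_allclose(w.values, 1.0)

    def test_absorbed_treatment_contributes_unit_factors(self, cohort_s1,
                                                         pp_s1, models_s1):
        # for someone treated from the first visit onwards the weight is the
        # k = 0 factor at every later interval
        w = compute_iptw(models_s1, pp_s1, stabilization="conditional_L0")
        df = pd.DataFrame({"id": pp_s1["id"], "k": pp_s1["k"], "w": w.values})
        treated0 = cohort_s1.ids[cohort_s1.A[:, 0] == 1]
        sub = df[df["id"].isin(treated0)]
        per_id = sub.groupby("id")["w"].nunique()
        assert (per_id == 1).all()

    def test_weights_match_independent_per_individual_loop(self, pp_s1,
                                                           models_s1):
        # enumeration oracle: recompute the cumulative products row by row
        w = compute_iptw(models_s1, pp_s1, stabilization="conditional_L0")
        p_den = models_s1.denominator.predict(pp_s1)
        p_num = models_s1.numerator.predict(pp_s1)
        expected = {}
        acc = {}
        for i in range(len(pp_s1)):
            row = pp_s1.iloc[i]
            key = row["id"]
            if row["A_lag1"] == 1:
                f = 1.0
            else:
                f = ((p_num[i] if row["A"] == 1 else 1 - p_num[i])
                     / (p_den[i] if row["A"] == 1 else 1 - p_den[i]))
            acc[key] = acc.get(key, 1.0) * f
            expected[i] = acc[key]
        np.testing.assert_allclose(w.values,
                                   [expected[i] for i in range(len(pp_s1))],
                                   rtol=1e-10)


@pytest.fixture(scope="module")
def stack_and_weights(cohort_s1, pp_s1):
    raw = build_trials(cohort_s1)
    stack = apply_artificial_censoring(raw, cohort_s1)
    models = fit_treatment_models(pp_s1, numerator="trial_baseline",
                                  trials=raw)
    return stack, compute_ipacw(models, stack), models


class TestIPACW:
    def test_first_interval_weight_is_one(self, stack_and_weights):
        stack, w, _ = stack_and_weights
        assert np.allclose(w.values[stack["j"].to_numpy() == 0], 1.0)

    def test_initiator_arm_weight_is_one(self, stack_and_weights):
        stack, w, _ = stack_and_weights
        assert np.allclose(w.values[stack["arm"].to_numpy() == 1], 1.0)

    def test_noninitiator_weights_match_independent_loop(self, stack_and_weights):
        stack, w, models = stack_and_weights
        p_den = models.denominator.predict(stack)
        p_num = models.trial_numerator.predict(stack)
        acc, expected = {}, np.ones(len(stack))
        for i in range(len(stack)):
            row = stack.iloc[i]
            key = (row["id"], row["trial"])
            f = 1.0
            if row["arm"] == 0 and row["j"] >= 1:
                f = (1 - p_num[i]) / (1 - p_den[i])
            acc[key] = acc.get(key, 1.0) * f
            expected[i] = acc[key]
        np.testing.assert_allclose(w.values, expected, rtol=1e-10)

    def test_mean_weight_near_one(self, stack_and_weights):
        stack, w, _ = stack_and_weights
        sub = stack["arm"].to_numpy() == 0
        means = pd.Series(w.values[sub]).groupby(
            stack.loc[sub, "j"].to_numpy()).mean()
        assert (np.abs(means - 1.0) < 0.1).all()


class TestIPCW:
    def test_no_dropout_gives_unit_weights(self, pp_s1):
        from seqtrials.weights import fit_censoring_models
        cm = fit_censoring_models(pp_s1)     # no dropout column
        w = compute_ipcw(cm, pp_s1)
        assert np.all(w.values == 1.0)

    def test_synthetic_dropout_inverse_retention(self):
        # saturated censoring model on binary L: weights equal ratios of
        # marginal to conditional retention probabilities
        rng = np.random.default_rng(3)
        n = 5000
        L = rng.integers(0, 2, n).astype(float)
        p_drop = np.where(L == 1, 0.3, 0.1)
        drop = rng.random(n) < p_drop
        pp = pd.DataFrame({"id": np.arange(n), "k": 0, "tstart": 0.0,
                           "tstop": 1.0, "event": 0, "A": 0, "A_lag1": 0,
                           "L": L, "L0": L, "dropout": drop.astype(int)})
        from seqtrials.weights import fit_censoring_models
        cm = fit_censoring_models(pp)
        w = compute_ipcw(cm, pp)
        ret_marg = 1 - drop.mean()
        for l in (0, 1):
            ret_l = 1 - drop[L == l].mean()
            np.testing.assert_allclose(np.unique(w.values[L == l]),
                                       ret_marg / ret_l, rtol=1e-6)


class TestTruncation:
    def test_definition_and_projection(self):
        w = WeightSeries(values=np.arange(1.0, 101.0), kind="iptw")
        cap = np.percentile(w.values, 95, method="lower")
        t = truncate_weights(w, 95)
        assert t.values.max() == pytest.approx(cap)
        assert (t.values[w.values <= cap] == w.values[w.values <= cap]).all()
        assert (w.values > cap).sum() == (t.values == cap).sum() - \
            (w.values == cap).sum()
        # idempotent
        np.testing.assert_allclose(truncate_weights(t, 95).values, t.values)

    def test_degenerate_distribution_unchanged(self):
        w = WeightSeries(values=np.full(50, 2.5), kind="iptw")
        np.testing.assert_array_equal(truncate_weights(w, 95).values, w.values)

    def test_percentile_validated(self):
        w = WeightSeries(values=np.ones(3), kind="iptw")
        with pytest.raises(ValidationError):
            truncate_weights(w, 0.0)
        with pytest.raises(ValidationError):
            truncate_weights(w, 101)
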