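"""High-level causal survival estimators with a scikit-learn interface.

Both estimators consume a :class:`~seqtrials.cohort.LongitudinalCohort`
(or a wide one-row-per-individual DataFrame) and estimate marginal
counterfactual survival under the sustained "always treated" and "never
treated" strategies, together with their risk difference, standardized to
the cohort's baseline-confounder population:

* :class:`MSMIPTW` keeps everyone under observation, re-weights
  person-periods by stabilized inverse-probability-of-treatment weights,
  and fits a hazard MSM in the full treatment history.
* :class:`SequentialTrials` emulates a trial at every visit, artificially
  censors records at deviation from the baseline arm, re-weights by
  inverse-probability-of-artificial-censoring weights, and fits a pooled
  hazard MSM in the constant arm conditional on the trial-baseline
  confounder.

Both follow the fit / fitted-attribute / get_params conventions, so they
compose with scikit-learn model selection and with the bootstrap helper.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import (LongitudinalCohort, RegimeSpec, ValidationError,
                     to_person_period)
from .hazard_msm import MSMDesign, fit_aalen_msm, fit_cox_msm
from .standardize import risk_difference, standardize_marginal, survival_under_regime
from .trials import EligibilitySpec, apply_artificial_censoring, build_trials
from .weights import (compute_ipacw, compute_ipcw, compute_iptw,
                      fit_censoring_models, fit_treatment_models, truncate_weights)


def _as_cohort(X) -> LongitudinalCohort:
    if isinstance(X, LongitudinalCohort):
        return X
    if isinstance(X, pd.DataFrame):
        from .cohort import read_cohort
        import io
        buf = io.StringIO()
        X.to_csv(buf, index=False)
        buf.seek(0)
        return read_cohort(buf)
    raise ValidationError("X must be a LongitudinalCohort or a wide DataFrame")


class _BaseCausalSurvival(BaseEstimator):
    """Shared fitted-curve plumbing for both approaches."""

    def _finalize(self, fit, pop, taus):
        K = self._K_
        always = RegimeSpec.always(K)
        never = RegimeSpec.never(K)
        self.msm_ = fit
        self.survival_always_ = self._standardize(fit, always, pop, taus)
        self.survival_never_ = self._standardize(fit, never, pop, taus)
        self.risk_difference_ = risk_difference(self.survival_always_,
                                                self.survival_never_, taus)
        return self

    def predict_survival(self, regime="always", taus=None):
        """Marginal survival under a regime ('always', 'never', or a
        RegimeSpec), standardized to the population used in fit."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "msm_")
        if taus is None:
            taus = np.asarray(self.taus, dtype=float)
        if isinstance(regime, str):
            regime = (RegimeSpec.always(self._K_) if regime == "always"
                      else RegimeSpec.never(self._K_))
        return self._standardize(self.msm_, regime, self.population_, taus)

    def predict_risk_difference(self, taus=None):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "msm_")
        if taus is None:
            taus = np.asarray(self.taus, dtype=float)
        s1 = self.predict_survival("always", taus)
        s0 = self.predict_survival("never", taus)
        return risk_difference(s1, s0, taus)


class MSMIPTW(_BaseCausalSurvival):
    """Whole-cohort weighted hazard MSM in the full treatment history.

    Parameters
    ----------
    msm : {"aalen", "cox"}
        Additive-hazards MSM with time-varying cumulative coefficients, or
        Cox MSM with weighted Breslow baseline.
    conditioning : {"L0", None}
        Condition the MSM (and the weight numerator) on the baseline
        confounder, standardizing marginal curves over the cohort's L0
        population by cloning, or fit a fully marginal MSM.
    truncate : optional percentile in (0, 100] at which weights are capped.
    taus : default report grid for the fitted curves.
    ipcw : account for a loss-to-follow-up process recorded in a
        ``dropout`` person-period column (no-op when absent).
    """

    def __init__(self, msm="aalen", conditioning="L0", truncate=None,
                 taus=(1.0, 2.0, 3.0, 4.0, 5.0), ipcw=False):
        self.msm = msm
        self.conditioning = conditioning
        self.truncate = truncate
        self.taus = taus
        self.ipcw = ipcw

    def fit(self, X, y=None):
        cohort = _as_cohort(X)
        self._K_ = cohort.K
        pp = to_person_period(cohort)
        numerator = "L0" if self.conditioning == "L0" else "marginal"
        self.treatment_models_ = fit_treatment_models(pp, numerator=numerator)
        w = compute_iptw(self.treatment_models_, pp,
                         stabilization=("conditional_L0" if numerator == "L0"
                                        else "marginal"))
        if self.ipcw:
            cm = fit_censoring_models(pp)
            w_c = compute_ipcw(cm, pp)
            w.values = w.values * w_c.values
        if self.truncate is not None:
            w = truncate_weights(w, self.truncate)
        self.weights_ = w
        self.person_period_ = pp
        covs = ("L0",) if self.conditioning == "L0" else ()
        design = MSMDesign(treatment="lags", covariates=covs)
        fitter = fit_aalen_msm if self.msm == "aalen" else fit_cox_msm
        fit = fitter(pp, design, weights=w)
        self.population_ = pd.DataFrame({"L0": cohort.L[:, 0]})
        return self._finalize(fit, self.population_, np.asarray(self.taus, float))

    def _standardize(self, fit, regime, pop, taus):
        if fit.design.covariates:
            return standardize_marginal(fit, regime, pop, taus)
        return survival_under_regime(fit, regime, taus=taus)


class SequentialTrials(_BaseCausalSurvival):
    """Pooled sequential-trial emulation with artificial-censoring weights.

    Parameters
    ----------
    msm : {"aalen", "cox"}.
    washout : eligibility rule; "full" admits only the treatment-naive.
    k_star : depth of trial-baseline confounder history conditioned on.
    trial_strata : stratify the Cox baseline hazard by trial (the trial-0
        baseline is then used for standardization).
    equal_length : cap all trials at a common follow-up horizon.
    truncate : optional weight-truncation percentile.
    """

    def __init__(self, msm="aalen", washout="full", k_star=0,
                 trial_strata=False, equal_length=False, truncate=None,
                 taus=(1.0, 2.0, 3.0, 4.0, 5.0)):
        self.msm = msm
        self.washout = washout
        self.k_star = k_star
        self.trial_strata = trial_strata
        self.equal_length = equal_length
        self.truncate = truncate
        self.taus = taus

    def fit(self, X, y=None):
        cohort = _as_cohort(X)
        self._K_ = cohort.K
        pp = to_person_period(cohort)
        spec = EligibilitySpec(washout=self.washout)
        raw = build_trials(cohort, spec, k_star=self.k_star,
                           equal_length=self.equal_length)
        stack = apply_artificial_censoring(raw, cohort)
        self.treatment_models_ = fit_treatment_models(
            pp, numerator="trial_baseline", trials=raw)
        w = compute_ipacw(self.treatment_models_, stack)
        if self.truncate is not None:
            w = truncate_weights(w, self.truncate)
        self.weights_ = w
        self.trials_ = stack
        covs = ("L_base",) + tuple(f"L_base_lag{s}"
                                   for s in range(1, self.k_star + 1))
        design = MSMDesign(treatment="arm", covariates=covs,
                           trial_strata=self.trial_strata)
        fitter = fit_aalen_msm if self.msm == "aalen" else fit_cox_msm
        fit = fitter(stack, design, weights=w)
        # clones take the cohort baseline confounder as their trial-baseline value
        pop = {"L_base": cohort.L[:, 0]}
        for s in range(1, self.k_star + 1):
            pop[f"L_base_lag{s}"] = cohort.L[:, 0]
        self.population_ = pd.DataFrame(pop)
        return self._finalize(fit, self.population_, np.asarray(self.taus, float))

    def _standardize(self, fit, regime, pop, taus):
        return standardize_marginal(fit, regime, pop, taus)
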