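"""Counterfactual survival curves and marginal risk differences.

A fitted hazard MSM implies a conditional counterfactual survival
function S(t | regime, baseline covariates) = exp(-cumulative hazard).
Marginal curves for a reference population are obtained by cloning: every
member contributes a conditional curve under each regime with treatment
forced to the regime's path, and the curves are averaged.  The risk
difference RD(tau) reported here is the "always treated" survival minus
the "never treated" survival, so a positive RD means better survival
under sustained treatment.

Fitting over all event times up to the maximum horizon and reading the
step-function curves at any tau guarantees monotone survival estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import RegimeSpec, ValidationError
from .hazard_msm import AalenFit, CoxFit


@dataclass
class SurvivalCurve:
    """A counterfactual survival step function on a time grid."""

    times: np.ndarray
    S: np.ndarray
    regime: str
    population: str = "marginal"
    n_clamped: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if (np.diff(self.S) > 1e-12).any():
            raise ValidationError("survival curve must be nonincreasing")

    def at(self, taus) -> np.ndarray:
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        idx = np.searchsorted(self.times, taus, side="right") - 1
        return np.where(idx >= 0, self.S[np.maximum(idx, 0)], 1.0)


@dataclass
class RiskDifferenceCurve:
    times: np.ndarray
    RD: np.ndarray
    S1: np.ndarray
    S0: np.ndarray
    population: str = "marginal"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.times, "S1": self.S1, "S0": self.S0,
                             "RD": self.RD})


@dataclass
class ReferencePopulation:
    """Covariate records the marginal curves are standardized over."""

    covariates: pd.DataFrame

    def __post_init__(self):
        if len(self.covariates) < 1:
            raise ValidationError("reference population must be nonempty")
        if self.covariates.isna().any().any():
            raise ValidationError("reference covariates must be complete")

    @property
    def n(self) -> int:
        return len(self.covariates)


def _regime_value(design, col: str, m: int, regime: RegimeSpec) -> float:
    """Treatment design value at visit interval m under a forced regime."""
    if col == "A":
        return float(regime.a(m))
    if col.startswith("A_lag"):
        j = int(col.removeprefix("A_lag"))
        return float(regime.a(m - j)) if m - j >= 0 else 0.0
    if col == "A_duration":
        return float(regime.values[: m + 1].sum())
    if col == "arm":
        v = np.unique(regime.values)
        if len(v) != 1:
            raise ValidationError("constant-arm fits require a constant regime")
        return float(v[0])
    raise ValidationError(f"unknown treatment column {col!r}")


def _aalen_event_pieces(fit: AalenFit, regime: RegimeSpec):
    """Split per-event increments into a regime-specific base part and the
    covariate-coefficient parts."""
    base = np.zeros(len(fit.times))
    cov_inc = {}
    for c, name in enumerate(fit.columns):
        inc = fit.increments[:, c]
        if name == "intercept":
            base += inc
        elif name in fit.design.covariates:
            cov_inc[name] = inc
        else:
            vals = np.array([_regime_value(fit.design, name, m, regime)
                             for m in range(int(fit.intervals.max()) + 1)]) \
                if len(fit.times) else np.empty(0)
            base += inc * vals[fit.intervals] if len(fit.times) else 0.0
    return base, cov_inc


def _cox_event_pieces(fit: CoxFit, regime: RegimeSpec):
    """Per-event baseline-hazard increments scaled by the regime's
    treatment term; covariate linear predictor handled by the caller."""
    g = np.zeros(len(fit.baseline_times))
    for name, beta in fit.params.items():
        if name in fit.design.covariates:
            continue
        vals = np.array([_regime_value(fit.design, name, m, regime)
                         for m in range(int(fit.baseline_intervals.max()) + 1)]) \
            if len(fit.baseline_times) else np.empty(0)
        g += beta * vals[fit.baseline_intervals] if len(g) else 0.0
    return fit.baseline_increments * np.exp(g)


def _cum_at(times: np.ndarray, inc: np.ndarray, taus: np.ndarray) -> np.ndarray:
    cum = np.cumsum(inc)
    idx = np.searchsorted(times, taus, side="right") - 1
    return np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)


def _pl_at(times: np.ndarray, inc: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Product-limit survival from hazard increments along the last axis.

    Tied event times are collapsed first, so the discrete hazard at a tied
    time is the summed increment (matching weighted survivor proportions).
    """
    if len(times) == 0:
        return np.ones(inc.shape[:-1] + (len(taus),))
    starts = np.concatenate([[0], np.flatnonzero(np.diff(times)) + 1])
    u = times[starts]
    agg = np.add.reduceat(inc, starts, axis=-1)
    cp = np.cumprod(np.clip(1.0 - agg, 0.0, None), axis=-1)
    idx = np.searchsorted(u, taus, side="right") - 1
    return np.where(idx >= 0, cp[..., np.maximum(idx, 0)], 1.0)


def _check_support(fit, covariates: pd.DataFrame):
    for c, (lo, hi) in getattr(fit, "covariate_range", {}).items():
        if c in covariates.columns:
            v = covariates[c]
            if (v < lo).any() or (v > hi).any():
                warnings.warn(f"standardization covariate {c!r} outside the "
                              "support seen in fitting (extrapolation)")


def survival_under_regime(fit, regime: RegimeSpec,
                          covariates: dict | None = None,
                          taus=None, transform: str = "exp") -> SurvivalCurve:
    """Conditional (or fully marginal) survival curve under a forced regime.

    ``covariates`` must supply one value per conditioning covariate of the
    fit, and must be omitted for an unconditional fit.  The curve is the
    exact step function implied by the fitted cumulative coefficients
    (additive model) or by the Breslow baseline and log-hazard ratios
    (Cox), evaluated at ``taus`` (default: the event-time grid).

    ``transform`` maps the cumulative hazard to survival: "exp" (the
    continuous-time model formula, the default) or "product_limit"
    (S = prod(1 - dH), which matches discrete weighted survivor
    proportions exactly when event times are heavily tied).
    """
    cond = tuple(fit.design.covariates)
    if cond and covariates is None:
        raise ValidationError(f"fit conditions on {cond}; covariate values required")
    if not cond and covariates:
        raise ValidationError("covariates supplied for an unconditional fit")
    if isinstance(fit, AalenFit):
        times = fit.times
        base, cov_inc = _aalen_event_pieces(fit, regime)
        inc = base.copy()
        for c in cond:
            inc = inc + cov_inc[c] * float(covariates[c])
    elif isinstance(fit, CoxFit):
        times = fit.baseline_times
        inc = _cox_event_pieces(fit, regime)
        lp = sum(fit.params[c] * float(covariates[c]) for c in cond) if cond else 0.0
        inc = inc * np.exp(lp)
    else:
        raise ValidationError(f"unsupported fit type {type(fit).__name__}")
    if taus is None:
        taus = times
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    if transform == "product_limit":
        S = _pl_at(times, inc, taus)
    elif transform == "exp":
        S = np.exp(-_cum_at(times, inc, taus))
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    n_clamped = int(((S > 1) | (S < 0)).sum())
    S = np.clip(np.minimum.accumulate(np.minimum(S, 1.0)), 0.0, 1.0)
    pop = "conditional" if cond else "marginal"
    return SurvivalCurve(times=taus, S=S, regime=regime.label, population=pop,
                         n_clamped=n_clamped)


def standardize_marginal(fit, regime: RegimeSpec, pop,
                         taus=(1.0, 2.0, 3.0, 4.0, 5.0),
                         transform: str = "exp") -> SurvivalCurve:
    """Cloning-based empirical standardization to a reference population.

    Every member of the population is cloned with treatment forced to the
    regime; the marginal curve is the arithmetic mean of the members'
    conditional survival curves.  For the additive model the conditional
    cumulative hazard is linear in the covariates, so the average is
    computed in closed form without materializing the clones.
    """
    if isinstance(pop, pd.DataFrame):
        pop = ReferencePopulation(pop)
    cond = tuple(fit.design.covariates)
    missing = [c for c in cond if c not in pop.covariates.columns]
    if missing:
        raise ValidationError(f"population lacks covariates {missing}")
    if not cond:
        curve = survival_under_regime(fit, regime, taus=taus,
                                      transform=transform)
        return SurvivalCurve(times=curve.times, S=curve.S, regime=regime.label,
                             population="marginal", n_clamped=curve.n_clamped)
    _check_support(fit, pop.covariates)
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    Xc = pop.covariates[list(cond)].to_numpy(float)
    if isinstance(fit, AalenFit):
        base, cov_inc = _aalen_event_pieces(fit, regime)
        if transform == "product_limit":
            # per-member per-event hazard increments (small-scale use)
            inc_m = base[None, :] + Xc @ np.vstack([cov_inc[c] for c in cond])
            S_members = _pl_at(fit.times, inc_m, taus)
        else:
            Hbase = _cum_at(fit.times, base, taus)
            Hcov = np.column_stack([_cum_at(fit.times, cov_inc[c], taus)
                                    for c in cond])       # (ntau, ncov)
            # member-level cumulative hazards: Hbase[t] + Xc @ Hcov[t]
            H = Hbase[None, :] + Xc @ Hcov.T              # (n, ntau)
            S_members = np.exp(-H)
    elif isinstance(fit, CoxFit):
        inc = _cox_event_pieces(fit, regime)
        lp = Xc @ fit.params[list(cond)].to_numpy()
        if transform == "product_limit":
            inc_m = np.exp(lp)[:, None] * inc[None, :]
            S_members = _pl_at(fit.baseline_times, inc_m, taus)
        else:
            C = _cum_at(fit.baseline_times, inc, taus)
            S_members = np.exp(-np.outer(np.exp(lp), C))
    else:
        raise ValidationError(f"unsupported fit type {type(fit).__name__}")
    n_clamped = int(((S_members > 1) | (S_members < 0)).sum())
    S = np.clip(S_members, 0.0, 1.0).mean(axis=0)
    S = np.minimum.accumulate(np.minimum(S, 1.0))
    return SurvivalCurve(times=taus, S=S, regime=regime.label,
                         population="marginal", n_clamped=n_clamped)


def risk_difference(s1: SurvivalCurve, s0: SurvivalCurve,
                    taus=None) -> RiskDifferenceCurve:
    """RD(tau) = S_always(tau) - S_never(tau) on a shared time grid."""
    if s1.population != s0.population:
        raise ValidationError("survival curves refer to different populations")
    if taus is None:
        taus = np.union1d(s1.times, s0.times)
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    v1, v0 = s1.at(taus), s0.at(taus)
    return RiskDifferenceCurve(times=taus, RD=v1 - v0, S1=v1, S0=v0,
                               population=s1.population)
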