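"""Weighted hazard marginal structural models on person-period data.

Two model families are fitted to weighted start-stop (counting-process)
rows aligned to the visit grid:

* An Aalen additive-hazards MSM with time-varying cumulative
  coefficients.  At each event time the coefficient increment solves the
  weighted least-squares normal equations over the at-risk design matrix;
  cumulating the increments yields step-function coefficient paths.
  Treatment-history designs use an interval-dependent layout: the lag-j
  treatment column only enters the design for event times at or beyond
  interval j, where it is first defined.
* A Cox proportional-hazards MSM, maximizing the weighted partial
  likelihood (Efron ties), with the cumulative baseline hazard from a
  weighted Breslow estimator; optionally with a trial-stratified baseline
  for the sequential-trials analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ValidationError
from .weights import WeightSeries


class SingularDesignError(RuntimeError):
    pass


@dataclass(frozen=True)
class MSMDesign:
    """Hazard-model design specification.

    treatment : {"lags", "current", "duration", "arm", None}
        How the hazard depends on treatment: the full per-visit lag
        expansion (one coefficient per visits-since-baseline), the current
        status only, the cumulative duration, the constant trial arm, or
        no treatment term.
    covariates : names of baseline-conditioning columns (e.g. ("L0",) for
        the whole-cohort analysis, ("L_base",) for the trial stack).
    n_lags : highest treatment lag for "lags" (default: table's K - 1).
    trial_strata : stratify the Cox baseline hazard by trial.
    """

    treatment: str | None = "current"
    covariates: tuple = ()
    n_lags: int | None = None
    trial_strata: bool = False

    def treatment_columns(self, K: int) -> list[str]:
        if self.treatment == "lags":
            n = self.n_lags if self.n_lags is not None else K - 1
            return ["A"] + [f"A_lag{j}" for j in range(1, n + 1)]
        if self.treatment == "current":
            return ["A"]
        if self.treatment == "duration":
            return ["A_duration"]
        if self.treatment == "arm":
            return ["arm"]
        if self.treatment is None:
            return []
        raise ValidationError(f"unknown treatment term {self.treatment!r}")


def _design_matrix(data: pd.DataFrame, design: MSMDesign, intercept: bool):
    """Return (X, names, active_from): active_from[c] is the first visit
    interval at which column c is defined (0 = always)."""
    K = data.attrs.get("K", int(data["tstart"].max()) + 1)
    cols, active = [], []
    if intercept:
        cols.append(("intercept", np.ones(len(data))))
        active.append(0)
    tcols = design.treatment_columns(K)
    if design.treatment == "duration" and "A_duration" not in data.columns:
        lag_cols = [c for c in data.columns if c.startswith("A_lag")]
        data = data.assign(A_duration=data["A"] + data[lag_cols].sum(axis=1))
    for c in tcols:
        if c not in data.columns:
            raise ValidationError(f"design column {c!r} missing from data")
        cols.append((c, data[c].to_numpy(float)))
        active.append(int(c.removeprefix("A_lag")) if c.startswith("A_lag") else 0)
    for c in design.covariates:
        if c not in data.columns:
            raise ValidationError(f"covariate column {c!r} missing from data")
        cols.append((c, data[c].to_numpy(float)))
        active.append(0)
    if cols:
        X = np.column_stack([v for _, v in cols])
    else:
        X = np.empty((len(data), 0))
    names = [n for n, _ in cols]
    return X, names, np.asarray(active, dtype=int)


def _weights_array(w, n) -> np.ndarray:
    if w is None:
        return np.ones(n)
    if isinstance(w, WeightSeries):
        w = w.values
    w = np.asarray(w, dtype=float)
    if len(w) != n:
        raise ValidationError("weight vector does not align with the data rows")
    return w


@dataclass
class AalenFit:
    """Additive-hazards MSM fit: per-event-time coefficient increments.

    ``increments[e, c]`` is the jump of cumulative coefficient c at
    ``times[e]``; columns not active at that event time hold 0.  Cumulative
    coefficient paths are step functions starting at 0.
    """

    times: np.ndarray
    increments: np.ndarray
    columns: list[str]
    intervals: np.ndarray          # visit interval (floor of event time) per event
    design: MSMDesign
    n_events: int = 0
    n_skipped: int = 0
    covariate_range: dict = field(default_factory=dict)

    def cumulative(self) -> pd.DataFrame:
        df = pd.DataFrame(np.cumsum(self.increments, axis=0),
                          columns=self.columns)
        df.insert(0, "time", self.times)
        return df

    def cum_at(self, taus) -> pd.DataFrame:
        """Cumulative coefficients evaluated at arbitrary times."""
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        cum = np.cumsum(self.increments, axis=0)
        idx = np.searchsorted(self.times, taus, side="right") - 1
        out = np.where(idx[:, None] >= 0, cum[np.maximum(idx, 0)], 0.0)
        return pd.DataFrame(out, columns=self.columns, index=taus)

    def to_frame(self) -> pd.DataFrame:
        return self.cumulative()


def fit_aalen_msm(data: pd.DataFrame, design: MSMDesign,
                  weights=None, singular: str = "skip") -> AalenFit:
    """Weighted Aalen additive-hazards fit on visit-grid start-stop rows.

    Rows must satisfy tstart integer, tstart < tstop <= tstart + 1, with
    piecewise-constant covariates within each row.  At every event time t
    the increment of the cumulative coefficients solves

        (X_R' W X_R) dB(t) = X_e' w_e,

    where R is the at-risk set (tstart < t <= tstop) and e the event row.
    Increments with a singular weighted design are skipped with a warning
    (``singular="skip"``) or raise (``singular="strict"``).  The fit is
    invariant to rescaling all weights by a constant.
    """
    tstart = data["tstart"].to_numpy(float)
    tstop = data["tstop"].to_numpy(float)
    ev = data["event"].to_numpy() == 1
    if not np.allclose(tstart, np.round(tstart)) or (tstop <= tstart).any() \
            or (tstop > tstart + 1 + 1e-9).any():
        raise ValidationError("rows must be visit-grid intervals [k, k+1)")
    X, names, active_from = _design_matrix(data, design, intercept=True)
    w = _weights_array(weights, len(data))
    p = X.shape[1]
    m_idx = np.round(tstart).astype(int)

    all_t, all_m, all_inc = [], [], []
    n_skipped = 0
    for m in np.unique(m_idx):
        rows = m_idx == m
        Xm, wm, stopm, evm = X[rows], w[rows], tstop[rows], ev[rows]
        if not evm.any():
            continue
        cols = np.flatnonzero(active_from <= m)
        Xa = Xm[:, cols]
        order = np.argsort(stopm, kind="stable")
        Xa, wm_o, stop_o = Xa[order], wm[order], stopm[order]
        ev_o = evm[order]
        # suffix sums of w * x x' over rows sorted by tstop
        outer = (wm_o[:, None, None] * Xa[:, :, None] * Xa[:, None, :])
        suffix = np.zeros((len(Xa) + 1, len(cols), len(cols)))
        suffix[:-1] = np.cumsum(outer[::-1], axis=0)[::-1]
        ev_pos = np.flatnonzero(ev_o)
        t_e = stop_o[ev_pos]
        t_order = np.argsort(t_e, kind="stable")
        ev_pos, t_e = ev_pos[t_order], t_e[t_order]
        pos = np.searchsorted(stop_o, t_e, side="left")
        G = suffix[pos]
        rhs = wm_o[ev_pos, None] * Xa[ev_pos]
        dB = np.zeros_like(rhs)
        # scale-aware singularity detection via determinant vs diagonal scale
        with np.errstate(all="ignore"):
            diag = np.einsum("eii->ei", G)
            scale = np.prod(np.maximum(diag, 1e-300), axis=1)
            ok = np.abs(np.linalg.det(G)) > 1e-12 * scale
        if ok.any():
            dB[ok] = np.linalg.solve(G[ok], rhs[ok][..., None])[..., 0]
        if (~ok).any():
            if singular == "strict":
                raise SingularDesignError(
                    f"singular weighted design at event times {t_e[~ok][:5]}")
            n_skipped += int((~ok).sum())
        inc = np.zeros((len(t_e), p))
        inc[:, cols] = dB
        all_t.append(t_e)
        all_m.append(np.full(len(t_e), m))
        all_inc.append(inc)
    if all_t:
        times = np.concatenate(all_t)
        order = np.argsort(times, kind="stable")
        times = times[order]
        intervals = np.concatenate(all_m)[order]
        incs = np.concatenate(all_inc)[order]
    else:
        times = np.empty(0)
        intervals = np.empty(0, int)
        incs = np.empty((0, p))
    if n_skipped:
        warnings.warn(f"{n_skipped} singular Aalen increments skipped")
    cov_range = {c: (float(data[c].min()), float(data[c].max()))
                 for c in design.covariates}
    return AalenFit(times=times, increments=incs, columns=names,
                    intervals=intervals, design=design, n_events=int(ev.sum()),
                    n_skipped=n_skipped, covariate_range=cov_range)


@dataclass
class CoxFit:
    """Cox MSM fit: log-hazard ratios plus weighted Breslow baseline."""

    params: pd.Series
    cov: pd.DataFrame
    baseline_times: np.ndarray
    baseline_increments: np.ndarray    # dH0 at each event time
    baseline_intervals: np.ndarray
    design: MSMDesign
    n_events: int = 0
    covariate_range: dict = field(default_factory=dict)
    strata_baselines: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table plus the cumulative baseline as CSV-ready data."""
        coefs = pd.DataFrame({"term": self.params.index,
                              "log_hazard_ratio": self.params.to_numpy()})
        base = pd.DataFrame({"time": self.baseline_times,
                             "cum_baseline_hazard":
                                 np.cumsum(self.baseline_increments)})
        coefs["kind"], base["kind"] = "coefficient", "baseline"
        return pd.concat([coefs, base], ignore_index=True)

    def cumulative_baseline(self, taus) -> np.ndarray:
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        cum = np.cumsum(self.baseline_increments)
        idx = np.searchsorted(self.baseline_times, taus, side="right") - 1
        return np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)


def _breslow(data, lp, w):
    """Weighted Breslow cumulative-baseline-hazard increments."""
    tstart = data["tstart"].to_numpy(float)
    tstop = data["tstop"].to_numpy(float)
    ev = data["event"].to_numpy() == 1
    m_idx = np.round(tstart).astype(int)
    r = w * np.exp(lp)
    all_t, all_m, all_dh = [], [], []
    for m in np.unique(m_idx):
        rows = m_idx == m
        stopm, evm, rm, wm = tstop[rows], ev[rows], r[rows], w[rows]
        if not evm.any():
            continue
        order = np.argsort(stopm, kind="stable")
        stop_o, ev_o, r_o, w_o = stopm[order], evm[order], rm[order], wm[order]
        suffix = np.zeros(len(r_o) + 1)
        suffix[:-1] = np.cumsum(r_o[::-1])[::-1]
        ev_pos = np.flatnonzero(ev_o)
        t_e = stop_o[ev_pos]
        pos = np.searchsorted(stop_o, t_e, side="left")
        dh = w_o[ev_pos] / suffix[pos]
        all_t.append(t_e)
        all_m.append(np.full(len(t_e), m))
        all_dh.append(dh)
    t = np.concatenate(all_t) if all_t else np.empty(0)
    order = np.argsort(t, kind="stable")
    return (t[order],
            np.concatenate(all_dh)[order] if all_t else np.empty(0),
            np.concatenate(all_m)[order] if all_t else np.empty(0, int))


def fit_cox_msm(data: pd.DataFrame, design: MSMDesign,
                weights=None) -> CoxFit:
    """Weighted Cox MSM via the partial likelihood on start-stop rows.

    Coefficients come from lifelines' time-varying Cox fitter (Efron tie
    correction); the cumulative baseline hazard is the weighted Breslow
    estimator, computed per stratum when ``design.trial_strata`` is set
    (the trial-0 baseline is then the default for standardization).
    """
    from lifelines import CoxTimeVaryingFitter

    X, names, _ = _design_matrix(data, design, intercept=False)
    if not names:
        # no covariates: baseline only, equal to the weighted Nelson-Aalen
        w = _weights_array(weights, len(data))
        t, dh, mi = _breslow(data, np.zeros(len(data)), w)
        return CoxFit(params=pd.Series(dtype=float), cov=pd.DataFrame(),
                      baseline_times=t, baseline_increments=dh,
                      baseline_intervals=mi, design=design,
                      n_events=int((data["event"] == 1).sum()))
    w = _weights_array(weights, len(data))
    df = pd.DataFrame(X, columns=names)
    df["tstart"] = data["tstart"].to_numpy(float)
    df["tstop"] = data["tstop"].to_numpy(float)
    df["event"] = data["event"].to_numpy(int)
    df["_id"] = np.arange(len(df))
    df["_w"] = w
    strata = None
    if design.trial_strata:
        if "trial" not in data.columns:
            raise ValidationError("trial_strata requires a 'trial' column")
        df["trial"] = data["trial"].to_numpy()
        strata = ["trial"]
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(df, id_col="_id", start_col="tstart", stop_col="tstop",
                event_col="event", weights_col="_w", strata=strata)
    params = ctv.params_.rename(lambda c: str(c))
    cov = pd.DataFrame(np.asarray(ctv.variance_matrix_), index=params.index,
                       columns=params.index)
    lp = X @ params.to_numpy()
    if design.trial_strata:
        strata_baselines = {}
        for tr, sub_idx in data.groupby(data["trial"].to_numpy()).groups.items():
            loc = data.index.get_indexer(sub_idx)
            t, dh, mi = _breslow(data.iloc[loc], lp[loc], w[loc])
            strata_baselines[tr] = (t, dh, mi)
        t0, dh0, mi0 = strata_baselines[min(strata_baselines)]
        cox = CoxFit(params=params, cov=cov, baseline_times=t0,
                     baseline_increments=dh0, baseline_intervals=mi0,
                     design=design, n_events=int((data["event"] == 1).sum()),
                     strata_baselines=strata_baselines)
    else:
        t, dh, mi = _breslow(data, lp, w)
        cox = CoxFit(params=params, cov=cov, baseline_times=t,
                     baseline_increments=dh, baseline_intervals=mi,
                     design=design, n_events=int((data["event"] == 1).sum()))
    cox.covariate_range = {c: (float(data[c].min()), float(data[c].max()))
                           for c in design.covariates}
    return cox


@dataclass
class HeterogeneityTest:
    statistic: float
    df: int
    p_value: float
    dropped_terms: list


def test_common_treatment_effect(trials: pd.DataFrame, design: MSMDesign,
                                 weights=None) -> HeterogeneityTest:
    """Wald test of trial-by-arm interactions in the Cox sequential MSM.

    Tests whether the log hazard ratio for the arm is common across
    trials; interaction terms that are inestimable (no events in a
    trial-arm cell) are dropped with the degrees of freedom reduced.
    """
    from scipy import stats

    tvals = np.sort(trials["trial"].unique())
    if len(tvals) < 2:
        raise ValidationError("need at least 2 trials to test homogeneity")
    aug = trials.copy()
    inter_cols = []
    for tr in tvals[1:]:
        col = f"arm_x_trial{tr}"
        aug[col] = aug["arm"] * (aug["trial"] == tr)
        inter_cols.append(col)
    # drop interactions with no events in the initiator cell of that trial
    keep, dropped = [], []
    for tr, col in zip(tvals[1:], inter_cols):
        cell = aug[(aug["trial"] == tr) & (aug["arm"] == 1)]
        if (cell["event"] == 1).any():
            keep.append(col)
        else:
            dropped.append(col)
    if dropped:
        warnings.warn(f"dropping inestimable interactions {dropped}")
    full = MSMDesign(treatment="arm",
                     covariates=tuple(design.covariates) + tuple(keep),
                     trial_strata=design.trial_strata)
    fit = fit_cox_msm(aug, full, weights=weights)
    beta = fit.params[keep].to_numpy()
    V = fit.cov.loc[keep, keep].to_numpy()
    stat = float(beta @ np.linalg.solve(V, beta))
    df = len(keep)
    return HeterogeneityTest(statistic=stat, df=df,
                             p_value=float(stats.chi2.sf(stat, df)),
                             dropped_terms=dropped)
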