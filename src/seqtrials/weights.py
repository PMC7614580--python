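"""Stabilized inverse-probability weights for the two estimation approaches.

Three weight families are computed from pooled logistic models for the
treatment process:

* IPTW for the whole-cohort marginal-structural-model analysis: the
  cumulative product over visits of stabilized ratios
  ``Pr(A_k | limited history) / Pr(A_k | full confounder history)``,
  with factors equal to 1 once treatment is absorbed.
* IPACW for the sequential-trials analysis: within each emulated trial the
  weight is 1 during the first interval and, on the non-initiator arm,
  thereafter the cumulative product of stabilized probabilities of having
  remained untreated; initiators under absorbing treatment keep weight 1.
* IPCW, a generic hook for ordinary loss-to-follow-up, which reduces to
  all-ones when no dropout process exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ValidationError

PROB_FLOOR = 1e-12


class FitError(RuntimeError):
    pass


class PositivityError(RuntimeError):
    pass


@dataclass
class _Logit:
    """A fitted pooled logistic model plus its design recipe."""

    params: np.ndarray
    columns: list
    builder: callable          # df -> X
    name: str

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = self.builder(df)
        from scipy.special import expit
        return expit(X @ self.params)


def _fit_logit(y, X, columns, builder, name) -> _Logit:
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    keep = X.any(axis=0)  # drop empty indicator columns (no rows at risk)
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"{name}: dropping empty design columns {dropped}")
        columns = [c for c, k in zip(columns, keep) if k]
        inner_builder, kept = builder, keep

        def builder(df, _b=inner_builder, _k=kept):
            return _b(df)[:, _k]

        X = X[:, keep]
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels internal failure
        raise FitError(f"logistic fit failed for {name}: {exc}") from exc
    if not np.isfinite(res.params).all() or np.abs(res.params).max() > 30:
        raise FitError(f"perfect separation suspected in {name}")
    return _Logit(params=np.asarray(res.params), columns=columns, builder=builder,
                  name=name)


def _onehot(k: np.ndarray, levels: np.ndarray) -> np.ndarray:
    return (np.asarray(k)[:, None] == levels[None, :]).astype(float)


@dataclass
class TreatmentModelSet:
    """Denominator and numerator treatment models for weight construction.

    The denominator conditions on the current confounder, the numerator
    only on baseline (or nothing), both restricted to rows where treatment
    had not yet been initiated; under absorbing treatment the probability
    of continuing treatment is 1 and contributes no factor.
    """

    denominator: _Logit
    numerator: _Logit | None = None
    numerator_kind: str = "marginal"
    trial_numerator: _Logit | None = None
    absorbing: bool = True
    discontinuation: dict = field(default_factory=dict)


def _untreated_rows(pp: pd.DataFrame) -> pd.Series:
    if "A_lag1" not in pp.columns:
        raise ValidationError("person-period table must carry A_lag1")
    return pp["A_lag1"] == 0


@dataclass
class _FormulaLogit:
    """Formula-specified pooled logistic model (statsmodels formula API)."""

    results: object
    formula: str
    name: str

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.results.predict(df))


def _fit_formula_logit(formula: str, data: pd.DataFrame, name: str) -> _FormulaLogit:
    try:
        res = sm.GLM.from_formula(formula, data=data,
                                  family=sm.families.Binomial()).fit()
    except Exception as exc:
        raise FitError(f"logistic fit failed for {name} ({formula!r}): {exc}") \
            from exc
    if not np.isfinite(res.params).all() or np.abs(res.params).max() > 30:
        raise FitError(f"perfect separation suspected in {name} ({formula!r})")
    return _FormulaLogit(results=res, formula=formula, name=name)


def fit_treatment_models(pp: pd.DataFrame, numerator: str = "L0",
                         trials: pd.DataFrame | None = None,
                         absorbing: bool = True,
                         den_formula: str | None = None,
                         num_formula: str | None = None) -> TreatmentModelSet:
    """Fit the pooled logistic treatment-process models.

    Parameters
    ----------
    pp : person-period table (one row per individual-visit survived to).
    numerator : {"marginal", "L0", "trial_baseline"}
        "marginal": separate intercept per visit; "L0": separate intercept
        and baseline-confounder coefficient per visit; "trial_baseline":
        additionally fit the sequential-trials numerator, in which the
        baseline confounder of trial k replaces L0 (requires ``trials``,
        the *uncensored* trial stack so deviation outcomes are observed).
    absorbing : treat initiation as absorbing (Pr(continue)=1).  When
        False, discontinuation models are fitted as well so that weights
        for switching off treatment can be formed.

    Only rows with ``A_lag1 == 0`` enter the initiation fits, so rows with
    treated history cannot influence the models.  ``den_formula`` /
    ``num_formula`` override the default model forms with statsmodels
    formulas over the person-period columns (e.g. ``"A ~ C(k)*L"`` for a
    saturated model in a binary confounder).
    """
    untreated = _untreated_rows(pp)
    sub = pp.loc[untreated]
    if len(sub) == 0:
        raise FitError("no untreated person-periods to fit treatment models on")

    if den_formula is not None:
        den = _fit_formula_logit(den_formula, sub, "treatment denominator")
    else:
        den = _fit_logit(
            sub["A"], np.column_stack([np.ones(len(sub)), sub["L"]]),
            ["intercept", "L"],
            lambda df: np.column_stack([np.ones(len(df)), df["L"]]),
            "treatment denominator (A ~ L | untreated)",
        )

    levels = np.sort(sub["k"].unique())
    if num_formula is not None:
        num = _fit_formula_logit(num_formula, sub, "treatment numerator")
    elif numerator == "marginal":
        num = _fit_logit(sub["A"], _onehot(sub["k"], levels),
                         [f"k{v}" for v in levels],
                         lambda df, lv=levels: _onehot(df["k"], lv),
                         "treatment numerator (A ~ visit)")
    elif numerator in ("L0", "trial_baseline"):
        def build(df, lv=levels):
            oh = _onehot(df["k"], lv)
            return np.column_stack([oh, oh * np.asarray(df["L0"])[:, None]])

        num = _fit_logit(sub["A"], build(sub),
                         [f"k{v}" for v in levels] + [f"k{v}:L0" for v in levels],
                         build, "treatment numerator (A ~ visit * L0)")
    else:
        raise ValidationError(f"unknown numerator specification {numerator!r}")

    trial_num = None
    if numerator == "trial_baseline":
        if trials is None:
            raise ValidationError("trial_baseline numerator requires the uncensored "
                                  "trial stack")
        dec = _decision_rows(trials, arm=0)
        lv = np.sort(dec["visit"].unique())

        def tbuild(df, lv=lv):
            oh = _onehot(df["visit"], lv)
            return np.column_stack([oh, oh * np.asarray(df["L_base"])[:, None]])

        trial_num = _fit_logit(dec["A"], tbuild(dec),
                               [f"v{v}" for v in lv] + [f"v{v}:Lbase" for v in lv],
                               tbuild,
                               "artificial-censoring numerator (A ~ visit * L_base)")

    ms = TreatmentModelSet(denominator=den, numerator=num,
                           numerator_kind=numerator, trial_numerator=trial_num,
                           absorbing=absorbing)
    if not absorbing:
        ms.discontinuation = _fit_discontinuation(pp, trials)
    return ms


def _decision_rows(trials: pd.DataFrame, arm: int) -> pd.DataFrame:
    """Treatment decisions at risk of deviation, from the uncensored stack.

    For the non-initiator arm these are rows at trial time >= 1 whose
    treatment had remained at the arm value through the previous visit;
    the row's own ``A`` is the decision outcome.
    """
    from .trials import group_starts, grouped_cumsum

    t = trials.sort_values(["id", "trial", "j"], kind="stable")
    dev = (t["A"].to_numpy() != t["arm"].to_numpy()).astype(int)
    cum_dev = grouped_cumsum(dev, group_starts(t))
    prev_dev = cum_dev - dev          # deviations strictly before this row
    mask = ((t["arm"].to_numpy() == arm) & (t["j"].to_numpy() >= 1)
            & (prev_dev == 0))
    return t.loc[mask]


def _fit_discontinuation(pp: pd.DataFrame, trials: pd.DataFrame | None) -> dict:
    """Models for stopping treatment (non-absorbing settings only)."""
    treated = pp.loc[pp["A_lag1"] == 1]
    if len(treated) == 0:
        return {}
    out = {}
    out["denominator"] = _fit_logit(
        treated["A"], np.column_stack([np.ones(len(treated)), treated["L"]]),
        ["intercept", "L"],
        lambda df: np.column_stack([np.ones(len(df)), df["L"]]),
        "discontinuation denominator (A ~ L | treated)")
    if trials is not None:
        dec = _decision_rows(trials, arm=1)
        if len(dec):
            lv = np.sort(dec["visit"].unique())

            def tbuild(df, lv=lv):
                oh = _onehot(df["visit"], lv)
                return np.column_stack([oh, oh * np.asarray(df["L_base"])[:, None]])

            out["trial_numerator"] = _fit_logit(
                dec["A"], tbuild(dec),
                [f"v{v}" for v in lv] + [f"v{v}:Lbase" for v in lv],
                tbuild, "artificial-censoring numerator (treated arm)")
    return out


@dataclass
class WeightSeries:
    """Per-row multiplicative weights aligned with a person-period table."""

    values: np.ndarray
    kind: str
    cumulative: bool = True
    n_floored: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values <= 0).any():
            raise ValidationError("weights must be positive")

    def __len__(self):
        return len(self.values)


def _floor_probs(p: np.ndarray, what: str) -> tuple[np.ndarray, int]:
    n_low = int((p < PROB_FLOOR).sum())
    if n_low:
        warnings.warn(f"positivity: {n_low} {what} probabilities floored at "
                      f"{PROB_FLOOR}")
    return np.maximum(p, PROB_FLOOR), n_low


def _grouped_cumprod(factors: np.ndarray, group_start: np.ndarray) -> np.ndarray:
    """Cumulative product within contiguous groups (vectorized)."""
    logf = np.log(factors)
    cs = np.cumsum(logf)
    start_idx = np.maximum.accumulate(np.where(group_start,
                                               np.arange(len(factors)), 0))
    base = (cs - logf)[start_idx]          # log-cumsum just before each group
    return np.exp(cs - base)


def _cumprod_by(df_keys: pd.DataFrame, factors: np.ndarray) -> np.ndarray:
    start = np.ones(len(factors), dtype=bool)
    if len(factors) > 1:
        same = np.ones(len(factors) - 1, dtype=bool)
        for col in df_keys.columns:
            v = df_keys[col].to_numpy()
            same &= v[1:] == v[:-1]
        start[1:] = ~same
    return _grouped_cumprod(factors, start)


def compute_iptw(models: TreatmentModelSet, pp: pd.DataFrame,
                 stabilization: str = "conditional_L0") -> WeightSeries:
    """Stabilized inverse-probability-of-treatment weights.

    The weight on the row for interval k is the product over visits j <= k
    of the numerator probability of the observed A_j divided by the
    denominator probability, with unit factors wherever treatment was
    already absorbed.  ``stabilization`` chooses the numerator:
    "marginal" (per-visit intercepts) or "conditional_L0" (per-visit
    intercepts and baseline-confounder coefficients); it must match how
    the models were fitted.
    """
    wanted = "marginal" if stabilization == "marginal" else "L0"
    if models.numerator_kind not in (wanted, "trial_baseline"):
        raise ValidationError(
            f"models fitted with numerator {models.numerator_kind!r}, "
            f"incompatible with stabilization {stabilization!r}")
    orig_index = pp.index
    pp = pp.sort_values(["id", "k"], kind="stable")
    untreated = _untreated_rows(pp).to_numpy()
    a = pp["A"].to_numpy()

    p_den = models.denominator.predict(pp)
    p_num = models.numerator.predict(pp)
    obs_den = np.where(a == 1, p_den, 1.0 - p_den)
    obs_num = np.where(a == 1, p_num, 1.0 - p_num)
    obs_den, nfl = _floor_probs(obs_den, "denominator")
    obs_num, _ = _floor_probs(obs_num, "numerator")
    factors = np.where(untreated, obs_num / obs_den, 1.0)
    w = _cumprod_by(pp[["id"]], factors)
    kind = "iptw" if stabilization == "marginal" else "iptw_conditional_L0"
    # pp was sorted; map weights back to the caller's row order
    ws = pd.Series(w, index=pp.index).reindex(orig_index)
    return WeightSeries(values=ws.to_numpy(), kind=kind, n_floored=nfl)


def compute_ipacw(models: TreatmentModelSet, trials: pd.DataFrame) -> WeightSeries:
    """Stabilized inverse-probability-of-artificial-censoring weights.

    ``trials`` must be the artificially censored stack.  Weights are 1 on
    every first interval and on the initiator arm under absorbing
    treatment; on the non-initiator arm at trial time >= 1 each interval
    contributes the stabilized probability of having remained untreated at
    that visit (numerator conditional on the trial-baseline confounder,
    denominator on the current one).
    """
    if models.trial_numerator is None:
        raise ValidationError("models lack the trial-baseline numerator; fit with "
                              "numerator='trial_baseline'")
    t = trials.sort_values(["id", "trial", "j"], kind="stable")
    arm = t["arm"].to_numpy()
    j = t["j"].to_numpy()

    factors = np.ones(len(t))
    active = (arm == 0) & (j >= 1)
    if active.any():
        sub = t.loc[active]
        p_den = models.denominator.predict(sub)          # Pr(start | current L)
        p_num = models.trial_numerator.predict(sub)      # Pr(start | baseline L)
        stay_den, nfl = _floor_probs(1.0 - p_den, "denominator")
        stay_num, _ = _floor_probs(1.0 - p_num, "numerator")
        factors[active] = stay_num / stay_den
    else:
        nfl = 0
    if not models.absorbing and models.discontinuation:
        act1 = (arm == 1) & (j >= 1)
        if act1.any():
            sub = t.loc[act1]
            p_den = models.discontinuation["denominator"].predict(sub)
            p_num = models.discontinuation["trial_numerator"].predict(sub)
            cont_den, n2 = _floor_probs(p_den, "denominator")
            cont_num, _ = _floor_probs(p_num, "numerator")
            factors[act1] = cont_num / cont_den
            nfl += n2
    w = _cumprod_by(t[["id", "trial"]], factors)
    ws = pd.Series(w, index=t.index).sort_index()
    return WeightSeries(values=ws.reindex(trials.index).to_numpy(),
                        kind="ipacw", n_floored=nfl)


def fit_censoring_models(pp: pd.DataFrame, dropout_col: str = "dropout"):
    """Pooled logistic models for interval-wise loss to follow-up."""
    if dropout_col not in pp.columns or not pp[dropout_col].any():
        return None
    y = pp[dropout_col]
    den = _fit_logit(y, np.column_stack([np.ones(len(pp)), pp["L"]]),
                     ["intercept", "L"],
                     lambda df: np.column_stack([np.ones(len(df)), df["L"]]),
                     "censoring denominator (C ~ L)")
    levels = np.sort(pp["k"].unique())
    num = _fit_logit(y, _onehot(pp["k"], levels), [f"k{v}" for v in levels],
                     lambda df, lv=levels: _onehot(df["k"], lv),
                     "censoring numerator (C ~ visit)")
    return {"denominator": den, "numerator": num}


def compute_ipcw(censor_models, pp: pd.DataFrame) -> WeightSeries:
    """Stabilized inverse-probability-of-censoring weights.

    With no loss-to-follow-up process (``censor_models`` is None) every
    weight is exactly 1.
    """
    if censor_models is None:
        return WeightSeries(values=np.ones(len(pp)), kind="ipcw")
    orig_index = pp.index
    pp = pp.sort_values(["id", "k"], kind="stable")
    p_den = censor_models["denominator"].predict(pp)
    p_num = censor_models["numerator"].predict(pp)
    stay_den, nfl = _floor_probs(1.0 - p_den, "denominator")
    stay_num, _ = _floor_probs(1.0 - p_num, "numerator")
    w = _cumprod_by(pp[["id"]], stay_num / stay_den)
    ws = pd.Series(w, index=pp.index).reindex(orig_index)
    return WeightSeries(values=ws.to_numpy(), kind="ipcw", n_floored=nfl)


def truncate_weights(w: WeightSeries, percentile: float = 95.0) -> WeightSeries:
    """Cap weights at the given pooled percentile of their distribution.

    The cap is the lower (order-statistic) percentile, so it is always an
    observed weight value and truncation is exactly idempotent.
    """
    if not (0 < percentile <= 100):
        raise ValidationError("percentile must be in (0, 100]")
    if len(w) == 0:
        raise ValidationError("empty weight series")
    cap = np.percentile(w.values, percentile, method="lower")
    return WeightSeries(values=np.minimum(w.values, cap), kind="truncated",
                        cumulative=w.cumulative, n_floored=w.n_floored)


def weight_summary(table: pd.DataFrame, w: WeightSeries,
                   by: str = "k") -> pd.DataFrame:
    """Mean and max weight by time period (diagnostic export surface)."""
    df = pd.DataFrame({"period": table[by].to_numpy(), "w": w.values})
    g = df.groupby("period")["w"].agg(["mean", "max", "count"]).reset_index()
    g.insert(0, "kind", w.kind)
    return g
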