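"""Synthetic longitudinal cohorts with treatment-confounder feedback.

The generator produces survival data with a single Normal time-dependent
confounder L, an absorbing binary treatment A initiated by a logistic
model in the current L, a shared Normal frailty U, and an event-time
process with a piecewise-constant conditional additive hazard

    h(t | treatment, confounder, frailty)
        = alpha0 + alphaA * A_k + alphaL * L_k + alphaU * U     on [k, k+1).

Treatment lowers future L (deltaA < 0) while higher L raises both the
hazard (alphaL > 0) and the chance of starting treatment (gammaL > 0),
producing genuine time-dependent confounding with feedback.  Ground-truth
counterfactual survival curves are obtained by re-running the same
mechanism with the treatment path forced, emulating a very large
randomized trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort import LongitudinalCohort, ValidationError


@dataclass(frozen=True)
class ScenarioParams:
    """Coefficients of the data-generating mechanism.

    ``u_scale`` is the *variance* of the frailty U (sd = sqrt(u_scale)); the
    default scenarios use a small frailty variance of 0.1.  Treatment is
    absorbing in all presets: once started it continues, so the logistic
    initiation model is only ever evaluated for untreated histories and no
    coefficient for past treatment is needed.
    """

    delta0: float = 0.0
    deltaL: float = 0.8
    deltaA: float = -1.0
    deltaT: float = 0.1
    gamma0: float = -1.0
    gammaL: float = 0.5
    alpha0: float = 0.2
    alphaA: float = -0.04
    alphaL: float = 0.015
    alphaU: float = 0.015
    u_scale: float = 0.1
    K: int = 5
    admin_censor_time: float = 5.0
    treatment_absorbing: bool = True

    def __post_init__(self):
        vals = asdict(self)
        for name, v in vals.items():
            if name != "treatment_absorbing" and not np.isfinite(v):
                raise ValidationError(f"non-finite parameter {name}")
        if self.K < 1 or self.admin_censor_time <= 0:
            raise ValidationError("K >= 1 and admin_censor_time > 0 required")

    def replace(self, **kw) -> "ScenarioParams":
        return replace(self, **kw)


#: Named presets: a moderate-confounding base case, a rare-initiation
#: variant, and a strong-confounding variant.
SCENARIOS = {
    "scenario1": ScenarioParams(),
    "scenario2": ScenarioParams(gamma0=-3.0),
    "scenario3": ScenarioParams(gammaL=3.0),
}


def get_scenario(name_or_params, **overrides) -> ScenarioParams:
    """Resolve a scenario preset by name, a params object, or a YAML path."""
    if isinstance(name_or_params, ScenarioParams):
        p = name_or_params
    elif name_or_params in SCENARIOS:
        p = SCENARIOS[name_or_params]
    elif isinstance(name_or_params, str) and name_or_params.endswith((".yml", ".yaml")):
        with open(name_or_params) as fh:
            cfg = yaml.safe_load(fh)
        base = cfg.pop("base", "scenario1")
        p = SCENARIOS[base].replace(**cfg)
    else:
        raise ValidationError(f"unknown scenario {name_or_params!r}")
    return p.replace(**overrides) if overrides else p


def draw_event_time(hazard_pieces: np.ndarray, horizon: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample piecewise-exponential event times by inversion.

    ``hazard_pieces`` is (n, m): one nonnegative rate per unit interval
    [j, j+1) per individual, covering [0, horizon).  Returns times with
    ``inf`` where no event occurs before the horizon.
    """
    h = np.atleast_2d(np.asarray(hazard_pieces, dtype=float))
    if (h < 0).any():
        raise ValidationError("negative hazard rate passed to draw_event_time")
    n, m = h.shape
    widths = np.minimum(np.arange(1, m + 1, dtype=float), horizon) - np.arange(m)
    widths = np.clip(widths, 0.0, 1.0)
    Hcum = np.cumsum(h * widths, axis=1)
    E = rng.exponential(1.0, n)
    hit = Hcum >= E[:, None]
    any_hit = hit.any(axis=1)
    j = np.argmax(hit, axis=1)
    rows = np.arange(n)
    Hprev = np.where(j > 0, Hcum[rows, np.maximum(j - 1, 0)], 0.0)
    rate = h[rows, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (E - Hprev) / rate
    t = np.where(any_hit, j + frac, np.inf)
    return np.where(t < horizon, t, np.inf)


def _draw_paths(params: ScenarioParams, n: int, rng: np.random.Generator,
                forced: int | None):
    """Draw (U, L, A) visit-by-visit; ``forced`` pins the whole A path."""
    K = params.K
    U = rng.normal(0.0, np.sqrt(params.u_scale), n)
    L = np.empty((n, K))
    A = np.empty((n, K), dtype=int)
    for k in range(K):
        if k == 0:
            mean = U
        else:
            mean = (params.delta0 + params.deltaL * L[:, k - 1]
                    + params.deltaA * A[:, k - 1] + params.deltaT * k + U)
        L[:, k] = rng.normal(mean, 1.0)
        if forced is not None:
            A[:, k] = forced
            continue
        p = expit(params.gamma0 + params.gammaL * L[:, k])
        start = rng.random(n) < p
        if k == 0:
            A[:, 0] = start
        elif params.treatment_absorbing:
            A[:, k] = np.where(A[:, k - 1] == 1, 1, start)
        else:
            A[:, k] = start
    return U, L, A


def _hazard_matrix(params: ScenarioParams, A, L, U):
    """Per-interval conditional hazards, clipped at 0 (count returned)."""
    h = params.alpha0 + params.alphaA * A + params.alphaL * L + params.alphaU * U[:, None]
    n_neg = int((h < 0).sum())
    return np.clip(h, 0.0, None), n_neg


def simulate_cohort(params="scenario1", n: int = 5000, seed=None,
                    forced_regime: int | None = None) -> LongitudinalCohort:
    """Generate an observational cohort (or a forced-regime trial arm).

    Draw order per cohort: frailty, then per visit the confounder and the
    treatment indicator, then one exponential deviate per individual for
    the event-time inversion.  A fixed seed therefore reproduces the cohort
    exactly.
    """
    params = get_scenario(params)
    if n < 1:
        raise ValidationError("n >= 1 required")
    rng = np.random.default_rng(seed)
    U, L, A = _draw_paths(params, n, rng, forced_regime)
    h, n_neg = _hazard_matrix(params, A, L, U)
    t = draw_event_time(h, params.admin_censor_time, rng)
    event = np.isfinite(t)
    T = np.where(event, t, params.admin_censor_time)
    cohort = LongitudinalCohort(
        ids=np.arange(n), A=A, L=L, T=T, event=event, U=U,
        admin_censor_time=params.admin_censor_time,
    )
    cohort.n_negative_hazards = n_neg   # clipping diagnostic
    return cohort


@dataclass
class TruthCurves:
    """True counterfactual survival under always/never treated regimes."""

    times: np.ndarray
    S1: np.ndarray
    S0: np.ndarray
    N_truth: int

    @property
    def RD(self) -> np.ndarray:
        return self.S1 - self.S0

    def at(self, taus) -> pd.DataFrame:
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        s1 = _step_lookup(self.times, self.S1, taus)
        s0 = _step_lookup(self.times, self.S0, taus)
        return pd.DataFrame({"tau": taus, "S1": s1, "S0": s0, "RD": s1 - s0})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "S1": self.S1, "S0": self.S0,
                             "RD": self.RD})


def _step_lookup(times, values, taus):
    """Right-continuous step-function lookup with S(t<times[0]) = 1."""
    idx = np.searchsorted(times, taus, side="right") - 1
    out = np.where(idx >= 0, values[np.maximum(idx, 0)], 1.0)
    return out


def compute_truth(params="scenario1", N: int = 1_000_000, seed=None,
                  grid: np.ndarray | None = None) -> TruthCurves:
    """Counterfactual survival by simulating a large two-arm randomized trial.

    The frailty, confounder process and event-time mechanism are identical
    to the observational generator; only the treatment path is forced.
    With no censoring before the horizon the Kaplan-Meier estimate equals
    the empirical survivor function, which is what is evaluated here.
    """
    params = get_scenario(params)
    if grid is None:
        grid = np.round(np.arange(0.0, params.admin_censor_time + 1e-9, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    curves = {}
    for a in (1, 0):
        U, L, A = _draw_paths(params, N, rng, forced=a)
        h, _ = _hazard_matrix(params, A, L, U)
        t = draw_event_time(h, params.admin_censor_time, rng)
        # empirical survivor function of the uncensored counterfactual time
        t_sorted = np.sort(t[np.isfinite(t)])
        n_ev = np.searchsorted(t_sorted, grid, side="right")
        curves[a] = 1.0 - n_ev / N
    return TruthCurves(times=grid, S1=curves[1], S0=curves[0], N_truth=N)


def load_truth_fixture() -> TruthCurves:
    """Packaged truth curves (N = 1e6 randomized-trial simulation).

    Treatment-assignment parameters do not enter the counterfactual world,
    so one set of curves serves every scenario preset.
    """
    from importlib.resources import files

    df = pd.read_csv(files("seqtrials.data").joinpath("truth_curves.csv"))
    return TruthCurves(times=df["t"].to_numpy(), S1=df["S1"].to_numpy(),
                       S0=df["S0"].to_numpy(), N_truth=1_000_000)
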