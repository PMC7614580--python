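"""Emulated sequential trials: eligibility, arm assignment, artificial censoring.

A trial is formed at every visit k.  Individuals alive and still
treatment-naive (per the washout rule) at visit k enter trial k with arm
equal to their observed treatment at k: initiators (A_k = 1) versus
non-initiators (A_k = 0).  Follow-up inside a trial is measured from the
trial's start; artificial censoring then cuts each record at the first
later visit where observed treatment deviates from the arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LongitudinalCohort, ValidationError


@dataclass
class EligibilitySpec:
    """Who may enter the trial starting at visit k.

    ``washout`` is the number of immediately preceding visits that must be
    untreated; "full" requires the entire prior history untreated (the
    strict treatment-naive rule, under which an individual can initiate in
    at most one trial).  ``predicate`` optionally further restricts entry:
    a callable ``(cohort, k) -> bool mask of shape (n,)``.
    """

    washout: int | str = "full"
    predicate: object = None

    def __post_init__(self):
        if self.washout != "full" and (not isinstance(self.washout, int)
                                       or self.washout < 0):
            raise ValidationError("washout must be 'full' or an integer >= 0")

    def eligible(self, cohort: LongitudinalCohort, k: int) -> np.ndarray:
        alive = cohort.T > k
        if k == 0:
            naive = np.ones(cohort.n, dtype=bool)
        elif self.washout == "full":
            naive = (cohort.A[:, :k] == 0).all(axis=1)
        else:
            lo = max(0, k - self.washout)
            naive = (cohort.A[:, lo:k] == 0).all(axis=1)
        ok = alive & naive
        if self.predicate is not None:
            ok &= np.asarray(self.predicate(cohort, k), dtype=bool)
        return ok


def build_trials(cohort: LongitudinalCohort, spec: EligibilitySpec | None = None,
                 k_star: int = 0, equal_length: bool = False) -> pd.DataFrame:
    """Stack the emulated trials (before artificial censoring).

    One row per (individual, trial, interval of time since trial start)
    survived to, with columns:

    id, trial, arm, j (interval index), tstart = j, tstop (trial time),
    event, visit = trial + j, A (observed treatment at the visit),
    L (current confounder), L_base (confounder at the trial's start),
    L_base_lag1.. for ``k_star`` > 0, and any time-fixed covariates.

    Later trials have shorter maximum follow-up by default; with
    ``equal_length`` every trial is capped at the length of the last
    possible trial so all trials share a fixed horizon.
    """
    spec = spec or EligibilitySpec()
    if k_star < 0:
        raise ValidationError("k_star must be >= 0")
    K = cohort.K
    nvis = cohort.n_visits()
    horizon_cap = K - (K - 1) if equal_length else None  # last trial has 1 interval
    frames = []
    for k in range(k_star, K):
        elig = np.flatnonzero(spec.eligible(cohort, k))
        if len(elig) == 0:
            continue
        n_int = nvis[elig] - k                      # intervals from trial start
        if equal_length:
            n_int = np.minimum(n_int, horizon_cap)
        i = np.repeat(elig, n_int)
        offs = np.concatenate([[0], np.cumsum(n_int)])[:-1]
        j = np.arange(int(n_int.sum())) - np.repeat(offs, n_int)
        visit = j + k
        tstop_cal = np.minimum(visit + 1.0, cohort.T[i])
        last = visit == nvis[i] - 1
        if equal_length:
            last = last & (tstop_cal < visit + 1.0)  # event only if inside cap
        d = {
            "id": cohort.ids[i],
            "trial": k,
            "arm": cohort.A[i, k],
            "j": j,
            "tstart": j.astype(float),
            "tstop": tstop_cal - k,
            "event": (last & cohort.event[i]).astype(int),
            "visit": visit,
            "A": cohort.A[i, visit],
            "L": cohort.L[i, visit],
            "L_base": cohort.L[i, k],
        }
        for s in range(1, k_star + 1):
            d[f"L_base_lag{s}"] = cohort.L[i, k - s]
        if cohort.Z is not None:
            for z in range(cohort.Z.shape[1]):
                d[f"Z{z}"] = cohort.Z[i, z]
        frames.append(pd.DataFrame(d))
    stack = pd.concat(frames, ignore_index=True)
    stack.attrs["K"] = K
    stack.attrs["k_star"] = k_star
    stack.attrs["censored"] = False
    return stack


def group_starts(t: pd.DataFrame, keys=("id", "trial")) -> np.ndarray:
    """Boolean first-row-of-group marks for a table sorted by ``keys``."""
    start = np.ones(len(t), dtype=bool)
    if len(t) > 1:
        same = np.ones(len(t) - 1, dtype=bool)
        for col in keys:
            v = t[col].to_numpy()
            same &= v[1:] == v[:-1]
        start[1:] = ~same
    return start


def grouped_cumsum(values: np.ndarray, start: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each group start (contiguous groups)."""
    cs = np.cumsum(values)
    start_idx = np.maximum.accumulate(np.where(start, np.arange(len(values)), 0))
    return cs - (cs - values)[start_idx]


def apply_artificial_censoring(trials: pd.DataFrame,
                               cohort: LongitudinalCohort | None = None
                               ) -> pd.DataFrame:
    """Censor each trial record at the first deviation from its arm.

    A deviation observed at visit m (> trial start k) removes the interval
    [m, m+1) and everything after it from that trial record, i.e. the
    record is right-censored at trial time m - k.  Initiators under
    absorbing treatment never deviate.  Events occurring before the
    deviation are retained.
    """
    t = trials.sort_values(["id", "trial", "j"], kind="stable")
    dev = (t["A"].to_numpy() != t["arm"].to_numpy()).astype(int)
    hit = grouped_cumsum(dev, group_starts(t)) > 0
    out = t.loc[~hit].reset_index(drop=True)
    out.attrs.update(trials.attrs)
    out.attrs["censored"] = True
    return out


def person_time(trials: pd.DataFrame) -> float:
    return float((trials["tstop"] - trials["tstart"]).sum())
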