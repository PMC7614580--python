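"""Exact nonparametric estimators for the two-visit binary setting.

With one binary confounder L and binary treatment A measured at two
visits, and discrete survival indicators Y1, Y2, both causal approaches
admit closed-form nonparametric estimators from the cell counts of the
data's branching structure (a causal tree).  The whole-cohort weighting
estimator and the trial-starting-at-0 standardized estimator are
algebraically identical at both horizons - the module's central
theorem-check - while the trial starting at visit 1 targets a population
defined by the later confounder, optionally re-standardized to the
baseline confounder distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ValidationError


class PositivityError(RuntimeError):
    pass


@dataclass
class CausalTreeCounts:
    """Cell counts for every pathway (L0, A0, Y1[, L1, A1, Y2]).

    Arrays are indexed by the binary values in the order the subscripts
    appear: e.g. ``n_l0a0_y1[l0, a0, y1]``.  Second-visit counts are
    restricted to survivors (Y1 = 0).
    """

    n: int
    n_l0: np.ndarray                 # (2,)
    n_l0a0: np.ndarray               # (2, 2)
    n_l0a0_y1: np.ndarray            # (2, 2, 2)
    n_l0a0_l1: np.ndarray            # (2, 2, 2)      given Y1 = 0
    n_l0a0_l1a1: np.ndarray          # (2, 2, 2, 2)   given Y1 = 0
    n_l0a0_l1a1_y2: np.ndarray       # (2, 2, 2, 2, 2) given Y1 = 0

    def validate(self):
        checks = [
            (self.n_l0.sum(), self.n),
            (self.n_l0a0.sum(axis=1), self.n_l0),
            (self.n_l0a0_y1.sum(axis=2), self.n_l0a0),
            (self.n_l0a0_l1.sum(axis=2), self.n_l0a0_y1[:, :, 0]),
            (self.n_l0a0_l1a1.sum(axis=3), self.n_l0a0_l1),
            (self.n_l0a0_l1a1_y2.sum(axis=4), self.n_l0a0_l1a1),
        ]
        for child, parent in checks:
            if not np.array_equal(np.asarray(child), np.asarray(parent)):
                raise ValidationError("child counts do not sum to their parent")
        for arr in (self.n_l0, self.n_l0a0, self.n_l0a0_y1, self.n_l0a0_l1,
                    self.n_l0a0_l1a1, self.n_l0a0_l1a1_y2):
            if (np.asarray(arr) < 0).any():
                raise ValidationError("counts must be nonnegative")
        return self

    @classmethod
    def from_arrays(cls, n_l0a0_y1, n_l0a0_l1a1_y2) -> "CausalTreeCounts":
        """Build the full nested structure from the two leaf-count arrays."""
        n_l0a0_y1 = np.asarray(n_l0a0_y1)
        n_l0a0_l1a1_y2 = np.asarray(n_l0a0_l1a1_y2)
        return cls(
            n=int(n_l0a0_y1.sum()),
            n_l0=n_l0a0_y1.sum(axis=(1, 2)),
            n_l0a0=n_l0a0_y1.sum(axis=2),
            n_l0a0_y1=n_l0a0_y1,
            n_l0a0_l1=n_l0a0_l1a1_y2.sum(axis=(3, 4)),
            n_l0a0_l1a1=n_l0a0_l1a1_y2.sum(axis=4),
            n_l0a0_l1a1_y2=n_l0a0_l1a1_y2,
        ).validate()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for idx in np.ndindex(2, 2, 2):
            rows.append({"cell": "L0=%d,A0=%d,Y1=%d" % idx,
                         "count": int(self.n_l0a0_y1[idx])})
        for idx in np.ndindex(2, 2, 2, 2, 2):
            rows.append({"cell": "L0=%d,A0=%d,Y1=0,L1=%d,A1=%d,Y2=%d" % idx,
                         "count": int(self.n_l0a0_l1a1_y2[idx])})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CausalTreeCounts":
        y1 = np.zeros((2, 2, 2), dtype=int)
        y2 = np.zeros((2, 2, 2, 2, 2), dtype=int)
        for _, row in df.iterrows():
            parts = dict(p.split("=") for p in row["cell"].split(","))
            if "L1" in parts:
                y2[int(parts["L0"]), int(parts["A0"]), int(parts["L1"]),
                   int(parts["A1"]), int(parts["Y2"])] = row["count"]
            else:
                y1[int(parts["L0"]), int(parts["A0"]),
                   int(parts["Y1"])] = row["count"]
        return cls.from_arrays(y1, y2)


def tree_counts(data: pd.DataFrame) -> CausalTreeCounts:
    """Exhaustively cross-tabulate two-period binary records.

    ``data`` has columns L0, A0, Y1 and, on rows with Y1 = 0, also
    L1, A1, Y2 (elsewhere they must be missing or are ignored).
    """
    for col in ("L0", "A0", "Y1"):
        v = data[col]
        if not np.isin(v.dropna(), (0, 1)).all() or v.isna().any():
            raise ValidationError(f"column {col} must be binary")
    surv = data["Y1"] == 0
    for col in ("L1", "A1", "Y2"):
        v = data.loc[surv, col]
        if v.isna().any() or not np.isin(v, (0, 1)).all():
            raise ValidationError(f"column {col} must be binary where Y1 = 0")
    y1 = np.zeros((2, 2, 2), dtype=int)
    np.add.at(y1, (data["L0"].astype(int), data["A0"].astype(int),
                   data["Y1"].astype(int)), 1)
    sub = data.loc[surv]
    y2 = np.zeros((2, 2, 2, 2, 2), dtype=int)
    np.add.at(y2, (sub["L0"].astype(int), sub["A0"].astype(int),
                   sub["L1"].astype(int), sub["A1"].astype(int),
                   sub["Y2"].astype(int)), 1)
    return CausalTreeCounts.from_arrays(y1, y2)


def _require_positive(value, name):
    if np.any(np.asarray(value) <= 0):
        raise PositivityError(f"zero count in stratum {name}")


def _maybe_correct(counts: CausalTreeCounts, correction: float) -> CausalTreeCounts:
    if correction == 0:
        return counts
    warnings.warn("applying a continuity correction to all tree cells; "
                  "exploratory use only")
    return CausalTreeCounts.from_arrays(
        counts.n_l0a0_y1 + correction, counts.n_l0a0_l1a1_y2 + correction)


def np_msm_iptw(counts: CausalTreeCounts, a: int, horizon: int,
                correction: float = 0.0) -> float:
    """Whole-cohort inverse-probability-weighted survival estimate.

    Horizon 1 sums, over baseline-confounder strata, the survivor count in
    the arm divided by the empirical treatment probability; horizon 2 adds
    the second weighting factor for staying on the regime, over the four
    (L0, L1) combinations.
    """
    c = _maybe_correct(counts, correction)
    if horizon == 1:
        total = 0.0
        for l0 in (0, 1):
            _require_positive(c.n_l0a0[l0, a], f"L0={l0},A0={a}")
            _require_positive(c.n_l0[l0], f"L0={l0}")
            p_a = c.n_l0a0[l0, a] / c.n_l0[l0]
            total += c.n_l0a0_y1[l0, a, 0] / p_a
        return float(total / c.n)
    if horizon == 2:
        total = 0.0
        for l0 in (0, 1):
            p_a0 = c.n_l0a0[l0, a] / c.n_l0[l0]
            _require_positive(c.n_l0a0[l0, a], f"L0={l0},A0={a}")
            for l1 in (0, 1):
                _require_positive(c.n_l0a0_l1a1[l0, a, l1, a],
                                  f"L0={l0},A0={a},L1={l1},A1={a}")
                _require_positive(c.n_l0a0_l1[l0, a, l1],
                                  f"L0={l0},A0={a},L1={l1}")
                p_a1 = c.n_l0a0_l1a1[l0, a, l1, a] / c.n_l0a0_l1[l0, a, l1]
                total += c.n_l0a0_l1a1_y2[l0, a, l1, a, 0] / (p_a0 * p_a1)
        return float(total / c.n)
    raise ValidationError("horizon must be 1 or 2")


def np_seqtrial(counts: CausalTreeCounts, a: int, horizon: int, trial: int = 0,
                standardize_to_L0: bool = False, correction: float = 0.0) -> float:
    """Sequential-trials nonparametric survival estimate.

    Trial 0 standardizes stratum-specific survivor proportions over the
    baseline-confounder distribution (horizon 1) or multiplies in the
    artificial-censoring-weighted second-period survival (horizon 2);
    either agrees exactly with the whole-cohort weighting estimator.
    Trial 1 is restricted to untreated first-period survivors and
    estimates one-period survival stratified by the later confounder,
    standardized either to that trial's own confounder distribution or,
    with ``standardize_to_L0``, to the baseline distribution.
    """
    c = _maybe_correct(counts, correction)
    if trial == 0 and horizon == 1:
        total = 0.0
        for l0 in (0, 1):
            _require_positive(c.n_l0a0[l0, a], f"L0={l0},A0={a}")
            total += (c.n_l0a0_y1[l0, a, 0] / c.n_l0a0[l0, a]) * (c.n_l0[l0] / c.n)
        return float(total)
    if trial == 0 and horizon == 2:
        total = 0.0
        for l0 in (0, 1):
            _require_positive(c.n_l0a0[l0, a], f"L0={l0},A0={a}")
            s1 = c.n_l0a0_y1[l0, a, 0] / c.n_l0a0[l0, a]
            n_surv = c.n_l0a0_y1[l0, a, 0]
            _require_positive(n_surv, f"L0={l0},A0={a},Y1=0")
            inner = 0.0
            for l1 in (0, 1):
                _require_positive(c.n_l0a0_l1a1[l0, a, l1, a],
                                  f"L0={l0},A0={a},L1={l1},A1={a}")
                inner += (c.n_l0a0_l1a1_y2[l0, a, l1, a, 0]
                          * c.n_l0a0_l1[l0, a, l1]
                          / c.n_l0a0_l1a1[l0, a, l1, a])
            s2_given_1 = inner / n_surv
            total += s1 * s2_given_1 * (c.n_l0[l0] / c.n)
        return float(total)
    if trial == 1:
        if horizon != 2:
            raise ValidationError("the trial starting at visit 1 estimates "
                                  "survival over the second period (horizon 2)")
        # restricted to A0 = 0, Y1 = 0; strata defined by L1
        num = c.n_l0a0_l1a1_y2[:, 0, :, a, 0].sum(axis=0)   # by l1
        den = c.n_l0a0_l1a1[:, 0, :, a].sum(axis=0)
        n_l1 = c.n_l0a0_l1[:, 0, :].sum(axis=0)
        if standardize_to_L0:
            wts = c.n_l0 / c.n
        else:
            _require_positive(n_l1.sum(), "A0=0,Y1=0")
            wts = n_l1 / n_l1.sum()
        # empty confounder strata carry no weight and simply drop out
        total = 0.0
        for l1 in (0, 1):
            if wts[l1] == 0 and n_l1[l1] == 0:
                continue
            _require_positive(den[l1], f"A0=0,Y1=0,L1={l1},A1={a}")
            total += (num[l1] / den[l1]) * wts[l1]
        return float(total)
    raise ValidationError("trial must be 0 or 1")


def combine_trials(est0: tuple[float, float], est1: tuple[float, float]) -> float:
    """Inverse-variance-weighted combination of two trial estimates."""
    (e0, v0), (e1, v1) = est0, est1
    if v0 < 0 or v1 < 0:
        raise ValidationError("variances must be nonnegative")
    if v0 == 0 or v1 == 0:
        warnings.warn("zero variance supplied; falling back to the simple mean")
        return float((e0 + e1) / 2)
    w0, w1 = 1.0 / v0, 1.0 / v1
    return float((w0 * e0 + w1 * e1) / (w0 + w1))


def bootstrap_variance(data: pd.DataFrame, estimator, B: int = 200,
                       seed=None) -> float:
    """Nonparametric bootstrap variance of a tree estimator over individuals."""
    rng = np.random.default_rng(seed)
    n = len(data)
    vals = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            vals.append(estimator(tree_counts(data.iloc[idx])))
        except PositivityError:
            continue
    if len(vals) < 2:
        raise PositivityError("too few valid bootstrap resamples")
    return float(np.var(vals, ddof=1))
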