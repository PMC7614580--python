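"""Nonparametric bootstrap over individuals for percentile intervals.

The resampling unit is the individual, so all of a person's rows - and
all of their appearances across emulated trials - travel together.  The
entire pipeline (trial formation, weight-model fitting, MSM fitting,
standardization) is re-run in every resample, so the intervals reflect
the uncertainty of the weights as well as of the MSM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .cohort import LongitudinalCohort, ValidationError


@dataclass
class BootstrapResult:
    taus: np.ndarray
    point: pd.DataFrame           # point estimates: S1, S0, RD per tau
    lower: pd.DataFrame
    upper: pd.DataFrame
    level: float
    B: int
    n_failed: int
    samples: np.ndarray | None = None   # (B, ntau, 3) raw statistics

    def to_frame(self) -> pd.DataFrame:
        out = self.point.copy()
        for q in ("S1", "S0", "RD"):
            out[f"{q}_lo"] = self.lower[q]
            out[f"{q}_hi"] = self.upper[q]
        return out


def _estimates(est, cohort, taus) -> np.ndarray:
    est.fit(cohort)
    rd = est.predict_risk_difference(taus)
    return np.column_stack([rd.S1, rd.S0, rd.RD])


def bootstrap_ci(estimator, cohort: LongitudinalCohort, B: int = 200,
                 level: float = 0.95, seed=None,
                 taus=(1.0, 2.0, 3.0, 4.0, 5.0),
                 keep_samples: bool = False,
                 _indices=None) -> BootstrapResult:
    """Percentile bootstrap intervals for S1, S0 and RD at each tau.

    Intervals are the empirical quantiles at (1-level)/2 and 1-(1-level)/2
    of the B resample statistics, using numpy's default linearly
    interpolated (type-7) quantile.  Resamples whose fit fails are dropped
    and counted; more than 10% failures is an error.  ``_indices``
    (testing hook) supplies explicit resample index arrays.
    """
    if B < 2:
        raise ValidationError("B must be >= 2")
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    rng = np.random.default_rng(seed)
    point = _estimates(clone(estimator), cohort, taus)
    stats, n_failed = [], 0
    for b in range(B):
        idx = (rng.integers(0, cohort.n, cohort.n) if _indices is None
               else np.asarray(_indices[b]))
        try:
            stats.append(_estimates(clone(estimator), cohort.subset(idx), taus))
        except Exception as exc:
            n_failed += 1
            warnings.warn(f"bootstrap resample {b} failed: {exc}")
    if n_failed > 0.10 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap resamples failed")
    arr = np.stack(stats)                      # (B_ok, ntau, 3)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(arr, alpha, axis=0)
    hi = np.quantile(arr, 1.0 - alpha, axis=0)
    cols = ["S1", "S0", "RD"]
    return BootstrapResult(
        taus=taus,
        point=pd.DataFrame(point, columns=cols, index=taus),
        lower=pd.DataFrame(lo, columns=cols, index=taus),
        upper=pd.DataFrame(hi, columns=cols, index=taus),
        level=level, B=B, n_failed=n_failed,
        samples=arr if keep_samples else None,
    )
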