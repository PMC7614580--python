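"""Longitudinal cohort data model and person-period expansion.

A cohort records, for each individual, a binary treatment indicator ``A_k``
and a real-valued time-dependent confounder ``L_k`` at regularly spaced
visits k = 0, 1, ..., K-1 (visit k occurs at time k), together with a
continuous event-or-censoring time ``T`` and an event indicator.  Variables
are assumed constant between visits.  Both causal estimators in this
package consume this object, either directly or after expansion to
person-period (counting-process) form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """Raised when input data violate the cohort contract."""


@dataclass
class LongitudinalCohort:
    """Wide, visit-indexed longitudinal survival data.

    Parameters
    ----------
    ids : array of shape (n,)
        Individual identifiers.
    A : int array of shape (n, K)
        Binary treatment status at each visit.  Entries at visits the
        individual did not survive to are ignored.
    L : float array of shape (n, K)
        Time-dependent confounder at each visit.
    T : float array of shape (n,)
        Event or censoring time, in visit-scale units, 0 < T <= admin_censor_time.
    event : bool array of shape (n,)
        1 if ``T`` is an event time, 0 if censored.
    Z : optional float array of shape (n, p)
        Time-fixed covariates.
    U : optional float array of shape (n,)
        Latent frailty.  Retained only by the simulator for truth
        computation; estimators never read it.
    admin_censor_time : float
        Administrative censoring time (K by default).
    """

    ids: np.ndarray
    A: np.ndarray
    L: np.ndarray
    T: np.ndarray
    event: np.ndarray
    Z: np.ndarray | None = None
    U: np.ndarray | None = None
    admin_censor_time: float | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.A = np.asarray(self.A, dtype=int)
        self.L = np.asarray(self.L, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.admin_censor_time is None:
            self.admin_censor_time = float(self.K)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def K(self) -> int:
        return self.A.shape[1]

    def validate(self):
        if self.A.shape != self.L.shape or self.A.shape[0] != self.n:
            raise ValidationError("A and L must be (n, K) arrays aligned with ids")
        bad = self.T < 0
        if bad.any():
            raise ValidationError(f"negative T for ids {self.ids[bad][:10].tolist()}")
        bad = self.T > self.admin_censor_time + 1e-9
        if bad.any():
            raise ValidationError(
                f"T beyond administrative censoring for ids {self.ids[bad][:10].tolist()}"
            )
        # A must be 0/1 at every visit survived to
        surv = visits_survived(self.T, self.K)
        mask = np.arange(self.K)[None, :] < surv[:, None]
        vals = self.A[mask]
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("treatment indicators must be 0/1")
        if not np.isfinite(self.L[mask]).all():
            raise ValidationError("missing or non-finite confounder values are rejected")

    def n_visits(self) -> np.ndarray:
        """Number of visit intervals each individual contributes."""
        return visits_survived(self.T, self.K)

    def subset(self, idx: np.ndarray) -> "LongitudinalCohort":
        """Row subset / resample (ids are re-labelled to stay unique)."""
        idx = np.asarray(idx)
        return LongitudinalCohort(
            ids=np.arange(len(idx)),
            A=self.A[idx],
            L=self.L[idx],
            T=self.T[idx],
            event=self.event[idx],
            Z=None if self.Z is None else self.Z[idx],
            U=None if self.U is None else self.U[idx],
            admin_censor_time=self.admin_censor_time,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row-per-individual representation."""
        d = {"id": self.ids}
        for k in range(self.K):
            d[f"A{k}"] = self.A[:, k]
        for k in range(self.K):
            d[f"L{k}"] = self.L[:, k]
        d["T"] = self.T
        d["event"] = self.event.astype(int)
        if self.U is not None:
            d["U"] = self.U
        if self.Z is not None:
            for j in range(self.Z.shape[1]):
                d[f"Z{j}"] = self.Z[:, j]
        return pd.DataFrame(d)


@dataclass
class RegimeSpec:
    """A deterministic treatment strategy a(k) assigned at each visit."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("regime values must be 0/1")

    @classmethod
    def always(cls, K: int) -> "RegimeSpec":
        return cls("always", np.ones(K, dtype=int))

    @classmethod
    def never(cls, K: int) -> "RegimeSpec":
        return cls("never", np.zeros(K, dtype=int))

    def a(self, k: int) -> int:
        return int(self.values[k])


def visits_survived(T: np.ndarray, K: int) -> np.ndarray:
    """ceil(min(T, K)): the number of visit intervals [k, k+1) entered.

    An event at exactly an integer time belongs to the interval ending at
    that time, so T = 2.0 yields intervals k = 0, 1 only.
    """
    T = np.asarray(T, dtype=float)
    return np.minimum(np.ceil(T), K).astype(int)


def read_cohort(path, schema: dict | None = None) -> LongitudinalCohort:
    """Read a wide CSV (columns id, A0.., L0.., T, event) into a cohort.

    ``schema`` optionally maps the canonical column names to those in the
    file, e.g. ``{"id": "patid", "T": "time", "event": "died"}``; it may be
    a dict or a path to a YAML file containing one.
    """
    if isinstance(schema, str):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    schema = schema or {}
    df = pd.read_csv(path)
    df = df.rename(columns={v: k for k, v in schema.items()})
    for col in ("id", "T", "event"):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    a_cols = sorted([c for c in df.columns if c.startswith("A") and c[1:].isdigit()],
                    key=lambda c: int(c[1:]))
    l_cols = sorted([c for c in df.columns if c.startswith("L") and c[1:].isdigit()],
                    key=lambda c: int(c[1:]))
    if not a_cols or [int(c[1:]) for c in a_cols] != list(range(len(a_cols))):
        raise ValidationError("treatment columns A0..A{K-1} must be contiguous from 0")
    if len(l_cols) != len(a_cols):
        raise ValidationError("need one L column per A column")
    K = len(a_cols)
    # visits after the event/censoring time may legitimately be empty
    surv = visits_survived(df["T"].to_numpy(float), K)
    A = df[a_cols].to_numpy()
    L = df[l_cols].to_numpy(float)
    mask = np.arange(K)[None, :] >= surv[:, None]
    A = np.where(mask, 0, np.nan_to_num(A)).astype(int)
    L = np.where(mask, 0.0, L)
    z_cols = sorted([c for c in df.columns if c.startswith("Z") and c[1:].isdigit()],
                    key=lambda c: int(c[1:]))
    return LongitudinalCohort(
        ids=df["id"].to_numpy(),
        A=A,
        L=L,
        T=df["T"].to_numpy(float),
        event=df["event"].to_numpy(),
        Z=df[z_cols].to_numpy(float) if z_cols else None,
        U=df["U"].to_numpy(float) if "U" in df.columns else None,
    )


def write_cohort(cohort: LongitudinalCohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def to_person_period(cohort: LongitudinalCohort, n_lags_A: int | None = None,
                     n_lags_L: int = 0) -> pd.DataFrame:
    """Expand a cohort to one row per individual per visit interval survived to.

    Row k covers [k, min(k+1, T)); the event indicator is 1 on the last row
    of an individual with an observed event.  Lag columns ``A_lag{j}`` hold
    the treatment j visits before the current one (0 before the start of
    follow-up, matching the no-treatment-before-baseline convention), and
    ``L0`` holds the baseline confounder.

    ``n_lags_A`` defaults to K - 1 (at least 1, so the at-risk-of-initiation
    indicator ``A_lag1`` always exists), making the full treatment history
    available to the treatment-history hazard designs.
    """
    if n_lags_A is None:
        n_lags_A = max(cohort.K - 1, 1)   # A_lag1 always present (0 at k = 0)
    if n_lags_A < 0 or n_lags_L < 0:
        raise ValidationError("lag counts must be >= 0")
    nvis = cohort.n_visits()
    total = int(nvis.sum())
    i = np.repeat(np.arange(cohort.n), nvis)           # individual index per row
    k = np.concatenate([np.arange(m) for m in nvis]) if total else np.empty(0, int)
    # faster equivalent of the concatenate above
    offs = np.concatenate([[0], np.cumsum(nvis)])[:-1]
    k = np.arange(total) - np.repeat(offs, nvis)
    tstop = np.minimum(k + 1.0, cohort.T[i])
    last = k == nvis[i] - 1
    d = {
        "id": cohort.ids[i],
        "k": k,
        "tstart": k.astype(float),
        "tstop": tstop,
        "event": (last & cohort.event[i]).astype(int),
        "A": cohort.A[i, k],
        "L": cohort.L[i, k],
        "L0": cohort.L[i, 0],
    }
    for j in range(1, n_lags_A + 1):
        kj = k - j
        d[f"A_lag{j}"] = np.where(kj >= 0, cohort.A[i, np.maximum(kj, 0)], 0)
    for j in range(1, n_lags_L + 1):
        kj = k - j
        d[f"L_lag{j}"] = np.where(kj >= 0, cohort.L[i, np.maximum(kj, 0)], 0.0)
    if cohort.Z is not None:
        for j in range(cohort.Z.shape[1]):
            d[f"Z{j}"] = cohort.Z[i, j]
    pp = pd.DataFrame(d)
    pp.attrs["K"] = cohort.K
    pp.attrs["n_lags_A"] = n_lags_A
    return pp
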