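"""Predictor derivation: severity means, visit-to-visit instability, org rates.

Four predictors are derived from each patient's 180-day measurement window:

* **clinical severity** — unweighted mean of CGI-S ratings (1-7 scale);
* **clinical instability** — tRMSSD of the CGI-S series;
* **functional severity** — mean of the *inverted* GAF (``100 - GAF``, so
  0-99 with higher = more impairment);
* **functional instability** — tRMSSD of the inverted GAF series.

tRMSSD (time-adjusted root mean square of successive differences) is the
instability statistic for irregularly sampled ordinal series: the root mean
square of per-day rates of change,

    sqrt( mean_i [ ((x_{i+1} - x_i) / (t_{i+1} - t_i))^2 ] ).

An alternative convention dividing the squared difference (rather than the
difference) by the gap, sqrt(mean(dx^2/dt)), is available via
``method="sqrt_dt"``. Same-day duplicate ratings are averaged into a single
observation before differencing (a zero gap makes a rate undefined).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logit

from .data import DX_COLUMNS

METRIC_COLUMNS = (
    "clinical_severity",
    "clinical_instability",
    "functional_severity",
    "functional_instability",
)

#: continuous predictors standardized before model fitting
CONTINUOUS_COLUMNS = METRIC_COLUMNS + ("age", "org_logit_rate")


def mean_severity(values) -> float:
    """Unweighted arithmetic mean of a rating series."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mean_severity requires at least one observation")
    return float(values.mean())


def invert_gaf(value):
    """Flip GAF so that higher values represent more impairment (100 - GAF)."""
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 1) | (arr > 100)):
        raise ValueError("GAF values must lie in [1, 100]")
    out = 100.0 - arr
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def collapse_same_day(days, values) -> tuple[np.ndarray, np.ndarray]:
    """Average duplicate same-day ratings into one observation per day."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(days) < 0):
        raise ValueError("observation days must be sorted")
    uniq, inverse = np.unique(days, return_inverse=True)
    sums = np.bincount(inverse, weights=values)
    counts = np.bincount(inverse)
    return uniq, sums / counts


def trmssd(days, values, method: str = "rate") -> float:
    """Time-adjusted RMSSD of an irregularly sampled series.

    Parameters
    ----------
    days, values
        Ordered observation days (strictly increasing) and ratings.
    method
        ``"rate"`` (default): sqrt(mean((dx/dt)^2)).
        ``"sqrt_dt"``: sqrt(mean(dx^2/dt)).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size < 2:
        raise ValueError("trmssd requires at least two observations")
    dt = np.diff(days)
    if np.any(dt <= 0):
        raise ValueError("observation days must be strictly increasing")
    dx = np.diff(values)
    if method == "rate":
        return float(np.sqrt(np.mean((dx / dt) ** 2)))
    if method == "sqrt_dt":
        return float(np.sqrt(np.mean(dx**2 / dt)))
    raise ValueError(f"unknown tRMSSD method {method!r}")


def org_logit_rate(events: int, n: int) -> float:
    """Continuity-corrected log-odds of hospitalisation at organisation level.

    ``logit((events + 0.5) / (n + 1))`` — the correction keeps small
    organisations with zero observed events finite.
    """
    if n < 1:
        raise ValueError("org_logit_rate requires n >= 1")
    if not 0 <= events <= n:
        raise ValueError("events must lie in [0, n]")
    return float(logit((events + 0.5) / (n + 1)))


def window_metrics(
    cgi_days, cgi_values, gaf_days, gaf_values, method: str = "rate"
) -> dict[str, float]:
    """The four severity/instability predictors for one measurement window."""
    cd, cv = collapse_same_day(cgi_days, cgi_values)
    gd, gv = collapse_same_day(gaf_days, np.asarray(gaf_values, dtype=float))
    gv_inv = 100.0 - gv
    return {
        "clinical_severity": mean_severity(cv),
        "clinical_instability": trmssd(cd, cv, method=method),
        "functional_severity": mean_severity(gv_inv),
        "functional_instability": trmssd(gd, gv_inv, method=method),
    }


def derive_features(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    org_rates: dict[str, float] | None = None,
    method: str = "rate",
) -> pd.DataFrame:
    """One feature row per cohort patient.

    ``cohort`` carries ``patient_id, window_start, window_end``; ratings are
    taken from ``visits`` inside the closed window. Demographics and
    diagnosis flags are joined from ``patients``; when ``org_rates`` (org_id
    -> log-odds) is supplied an ``org_logit_rate`` column is attached.
    """
    vis = visits.sort_values(["patient_id", "day"], kind="stable")
    grouped = dict(tuple(vis.groupby("patient_id", sort=False)))
    rows = []
    for rec in cohort.itertuples(index=False):
        g = grouped[rec.patient_id]
        inside = g[(g["day"] >= rec.window_start) & (g["day"] <= rec.window_end)]
        cgi = inside[inside["cgi_s"].notna()]
        gaf = inside[inside["gaf"].notna()]
        m = window_metrics(
            cgi["day"].to_numpy(float),
            cgi["cgi_s"].to_numpy(float),
            gaf["day"].to_numpy(float),
            gaf["gaf"].to_numpy(float),
            method=method,
        )
        rows.append({"patient_id": rec.patient_id, **m})
    feats = pd.DataFrame(rows)
    keep = ["patient_id", "org_id", "age", "gender"] + list(DX_COLUMNS) + ["race_group"]
    feats = feats.merge(patients[keep], on="patient_id", validate="1:1")
    if org_rates is not None:
        feats["org_logit_rate"] = feats["org_id"].map(org_rates)
        if feats["org_logit_rate"].isna().any():
            missing = feats.loc[feats["org_logit_rate"].isna(), "org_id"].unique()
            raise ValueError(f"no org rate supplied for org(s) {sorted(missing)}")
    return feats


def org_rates_from_cohort(cohort: pd.DataFrame, patients: pd.DataFrame) -> dict[str, float]:
    """Per-organisation hospitalisation log-odds from cohort outcomes."""
    df = cohort.merge(patients[["patient_id", "org_id"]], on="patient_id")
    return {
        org: org_logit_rate(int(g["event"].sum()), len(g))
        for org, g in df.groupby("org_id")
    }


class ScalingConstants:
    """Per-predictor mean/SD frozen on the derivation split.

    External validation always standardizes with the derivation constants —
    the scaling is part of the frozen model, never re-estimated downstream.
    """

    def __init__(self, means: dict[str, float], sds: dict[str, float]):
        for name, sd in sds.items():
            if not sd > 0:
                raise ValueError(f"predictor {name!r} has zero SD; cannot standardize")
        self.means = dict(means)
        self.sds = dict(sds)

    @classmethod
    def fit(cls, features: pd.DataFrame, columns=None) -> "ScalingConstants":
        if len(features) < 2:
            raise ValueError("need at least two rows to estimate scaling constants")
        cols = [c for c in (columns or CONTINUOUS_COLUMNS) if c in features.columns]
        means = {c: float(features[c].mean()) for c in cols}
        sds = {c: float(features[c].std(ddof=1)) for c in cols}
        return cls(means, sds)

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        out = features.copy()
        for c, mu in self.means.items():
            out[c] = (out[c] - mu) / self.sds[c]
        return out

    def to_dict(self) -> dict:
        return {"means": self.means, "sds": self.sds}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingConstants":
        return cls(d["means"], d["sds"])

    def __eq__(self, other):
        return (
            isinstance(other, ScalingConstants)
            and self.means == other.means
            and self.sds == other.sds
        )
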