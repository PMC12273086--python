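"""Discrimination, calibration, operating-point, subgroup and fairness
statistics for internal (optimism-corrected) and external validation.

Conventions:

* the concordance (c-) index is Harrell's estimator for right-censored
  data: among usable pairs (the shorter observed time has the event), the
  fraction where the earlier event carries the higher predicted risk, risk
  ties counting one half;
* PPV and NPV are repinned by Bayes' rule to a prespecified population
  incidence (default 2%) rather than read off raw confusion counts;
* observed risks in calibration bins are one minus the Kaplan-Meier
  survival at 180 days within the bin;
* the Brier score is the plain mean squared error of the predicted
  probabilities against the binary 180-day outcome (censoring ignored;
  follow-up in this design is nearly complete);
* all resampling procedures are deterministic under the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from sksurv.nonparametric import kaplan_meier_estimator

from .data import DX_COLUMNS
from .model import HORIZON_DAYS, CoxRiskModel, ModelSpec


@dataclass(frozen=True)
class OperatingPointConfig:
    flag_fraction: float = 0.05
    prespecified_incidence: float = 0.02

    def __post_init__(self):
        if not 0 < self.flag_fraction < 1:
            raise ValueError("flag_fraction must lie in (0, 1)")
        if not 0 < self.prespecified_incidence < 1:
            raise ValueError("prespecified_incidence must lie in (0, 1)")


def binary_outcome(time, event) -> np.ndarray:
    """1 iff the event occurred within the 180-day horizon."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    return (event & (time <= HORIZON_DAYS)).astype(float)


def c_index(risks, time, event) -> float:
    """Harrell's concordance for right-censored data (risk ties count 0.5)."""
    risks = np.asarray(risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if not event.any():
        raise ValueError("no comparable pairs: no events observed")
    return float(concordance_index(time, -risks, event))


def threshold_metrics(
    risks, time, event, cfg: OperatingPointConfig = OperatingPointConfig()
) -> dict[str, float]:
    """Sensitivity/specificity of flagging the top risk fraction, with PPV
    and NPV repinned to the prespecified incidence.

    Flagging ties are broken by stable patient order. With pi the
    prespecified incidence: PPV = se*pi / (se*pi + (1-sp)(1-pi)) and
    NPV = sp(1-pi) / ((1-se)pi + sp(1-pi)).
    """
    risks = np.asarray(risks, dtype=float)
    n = risks.size
    n_flag = int(round(cfg.flag_fraction * n))
    if n_flag == 0:
        raise ValueError(f"flag_fraction={cfg.flag_fraction} flags zero of {n} patients")
    order = np.argsort(-risks, kind="stable")
    flagged = np.zeros(n, dtype=bool)
    flagged[order[:n_flag]] = True
    y = binary_outcome(time, event).astype(bool)
    se = float(flagged[y].mean()) if y.any() else np.nan
    sp = float((~flagged)[~y].mean()) if (~y).any() else np.nan
    pi = cfg.prespecified_incidence
    ppv = se * pi / (se * pi + (1 - sp) * (1 - pi))
    npv = sp * (1 - pi) / ((1 - se) * pi + sp * (1 - pi))
    return {
        "n_flagged": n_flag,
        "sensitivity": se,
        "specificity": sp,
        "ppv": float(ppv),
        "npv": float(npv),
    }


def km_observed_risk(time, event, horizon: float = HORIZON_DAYS) -> float:
    """1 - Kaplan-Meier survival at the horizon; NaN when no risk time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.max(initial=0.0) <= 0:
        return float("nan")
    times, surv = kaplan_meier_estimator(event, time)
    idx = np.searchsorted(times, horizon, side="right") - 1
    s = float(surv[idx]) if idx >= 0 else 1.0
    return 1.0 - s


def calibration_curve(
    risks, time, event, bins: int = 10, B: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Equal-count calibration bins with bootstrap percentile CIs.

    Columns: bin, n, predicted (bin mean), observed (KM at 180 days),
    ci_lower, ci_upper.
    """
    risks = np.asarray(risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if risks.size < bins:
        raise ValueError(f"need at least {bins} patients for {bins} bins")
    # rank-based equal-count binning; stable order resolves risk ties
    order = np.argsort(risks, kind="stable")
    bin_of = np.empty(risks.size, dtype=int)
    bin_of[order] = (np.arange(risks.size) * bins) // risks.size
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(bins):
        mask = bin_of == b
        t, e, r = time[mask], event[mask], risks[mask]
        obs = km_observed_risk(t, e)
        boot = np.empty(B)
        for i in range(B):
            idx = rng.integers(0, t.size, t.size)
            boot[i] = km_observed_risk(t[idx], e[idx])
        ok = ~np.isnan(boot)
        lo, hi = (
            np.percentile(boot[ok], [2.5, 97.5]) if ok.any() else (np.nan, np.nan)
        )
        rows.append(
            {
                "bin": b,
                "n": int(mask.sum()),
                "predicted": float(r.mean()),
                "observed": obs,
                "ci_lower": float(lo),
                "ci_upper": float(hi),
            }
        )
    return pd.DataFrame(rows)


def brier_score(risks, time, event) -> float:
    """Mean squared error of predicted probabilities against the binary
    180-day outcome (censored-without-event scored as 0)."""
    risks = np.asarray(risks, dtype=float)
    y = binary_outcome(time, event)
    return float(np.mean((risks - y) ** 2))


def roc_points(risks, y) -> pd.DataFrame:
    """ROC curve points (starts at (0,0), ends at (1,1))."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(y, dtype=int), np.asarray(risks, dtype=float))
    if fpr[0] != 0 or tpr[0] != 0:
        fpr, tpr = np.r_[0.0, fpr], np.r_[0.0, tpr]
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr, tpr = np.r_[fpr, 1.0], np.r_[tpr, 1.0]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


@dataclass
class OptimismResult:
    apparent: float
    optimism: float
    corrected: float
    ci_lower: float
    ci_upper: float
    n_redrawn: int
    bootstrap_corrected: np.ndarray


def optimism_corrected_cindex(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    spec: ModelSpec | str,
    B: int = 200,
    seed: int = 0,
    select_transforms: bool = True,
    max_redraws: int = 1000,
) -> OptimismResult:
    """Harrell's optimism bootstrap for the c-index.

    Every data-driven modelling step — including AIC-based transform
    selection — is repeated inside each resample. A resample containing no
    events is redrawn (counted in ``n_redrawn``). The CI is the percentile
    interval of apparent minus per-resample optimism.
    """
    full_model = CoxRiskModel(cohort, features, spec)
    full_fit = full_model.fit(select_transforms=select_transforms)
    risks_full = full_fit.predict_risk(features)
    time = cohort["time"].to_numpy(float)
    event = cohort["event"].to_numpy(bool)
    apparent = c_index(risks_full, time, event)

    rng = np.random.default_rng(seed)
    n = len(cohort)
    optimisms = np.empty(B)
    redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            if event[idx].any():
                break
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("too many event-free bootstrap resamples")
        co_b = cohort.iloc[idx].reset_index(drop=True)
        fe_b = features.iloc[idx].reset_index(drop=True)
        # resampling duplicates patient ids; relabel to keep merges 1:1
        ids = [f"b{i}" for i in range(n)]
        co_b = co_b.assign(patient_id=ids)
        fe_b = fe_b.assign(patient_id=ids)
        fit_b = CoxRiskModel(co_b, fe_b, spec).fit(select_transforms=select_transforms)
        c_boot = c_index(
            fit_b.predict_risk(fe_b), co_b["time"].to_numpy(float),
            co_b["event"].to_numpy(bool),
        )
        c_orig = c_index(fit_b.predict_risk(features), time, event)
        optimisms[b] = c_boot - c_orig
    corrected_dist = apparent - optimisms
    lo, hi = np.percentile(corrected_dist, [2.5, 97.5])
    return OptimismResult(
        apparent=apparent,
        optimism=float(optimisms.mean()),
        corrected=float(apparent - optimisms.mean()),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_redrawn=redrawn,
        bootstrap_corrected=corrected_dist,
    )


def subgroup_cindices(
    risks, time, event, patients: pd.DataFrame
) -> pd.DataFrame:
    """c-index per (non-exclusive) diagnosis subgroup and per race group.

    ``patients`` is row-aligned with the risk/outcome arrays and carries the
    diagnosis flags and ``race_group``. Unknown-race patients enter neither
    race subgroup. Subgroups without a computable c-index are marked NaN.
    """
    risks = np.asarray(risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    rows = []
    groups = [(dx, patients[dx].to_numpy(bool)) for dx in DX_COLUMNS]
    race = patients["race_group"].to_numpy()
    groups += [("white", race == "white"), ("non_white", race == "non_white")]
    for name, mask in groups:
        n = int(mask.sum())
        ne = int(event[mask].sum())
        try:
            c = c_index(risks[mask], time[mask], event[mask]) if n else np.nan
        except (ValueError, ZeroDivisionError):
            c = np.nan
        rows.append({"group": name, "n": n, "n_events": ne, "c_index": c})
    return pd.DataFrame(rows)


def permutation_fairness_test(
    risks, time, event, race_groups, P: int = 100, seed: int = 0
) -> dict[str, float]:
    """Permutation test of the white vs non-white c-index difference.

    Unknown-race patients are excluded. Race labels are permuted across the
    remaining patients holding risks and outcomes fixed; the add-one
    estimator p = (1 + #{|delta_perm| >= |delta_obs|}) / (1 + P) avoids
    degenerate zero p-values.
    """
    risks = np.asarray(risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    race = np.asarray(race_groups)
    keep = (race == "white") | (race == "non_white")
    risks, time, event, race = risks[keep], time[keep], event[keep], race[keep]
    is_white = race == "white"
    if not is_white.any() or is_white.all():
        raise ValueError("both race groups must be non-empty")

    def delta(white_mask: np.ndarray) -> float:
        return abs(
            c_index(risks[white_mask], time[white_mask], event[white_mask])
            - c_index(risks[~white_mask], time[~white_mask], event[~white_mask])
        )

    obs = delta(is_white)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(P):
        perm = rng.permutation(is_white)
        try:
            if delta(perm) >= obs:
                exceed += 1
        except (ValueError, ZeroDivisionError):
            # permuted group without events: count as non-exceeding
            continue
    p = (1 + exceed) / (1 + P)
    cw = c_index(risks[is_white], time[is_white], event[is_white])
    cn = c_index(risks[~is_white], time[~is_white], event[~is_white])
    return {"c_white": cw, "c_non_white": cn, "delta": obs, "p": p}


def compare_models_bootstrap(
    risks_a, risks_b, time, event, B: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Patient-level paired bootstrap of the c-index difference (A - B).

    Returns the observed difference, the percentile 95% CI and an add-one
    two-sided bootstrap p-value.
    """
    risks_a = np.asarray(risks_a, dtype=float)
    risks_b = np.asarray(risks_b, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if risks_a.shape != risks_b.shape:
        raise ValueError("both risk sets must cover the same patients")
    obs = c_index(risks_a, time, event) - c_index(risks_b, time, event)
    rng = np.random.default_rng(seed)
    n = time.size
    deltas = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            if event[idx].any():
                break
        deltas[b] = c_index(risks_a[idx], time[idx], event[idx]) - c_index(
            risks_b[idx], time[idx], event[idx]
        )
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    p = 2 * min(
        (1 + np.sum(deltas <= 0)) / (1 + B), (1 + np.sum(deltas >= 0)) / (1 + B)
    )
    return {
        "delta_c": float(obs),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "p": float(min(p, 1.0)),
    }


@dataclass
class ValidationReport:
    """Container for the statistics of one validation run."""

    kind: str  # "internal" or "external"
    c_index: float
    c_index_ci: tuple[float, float] | None = None
    apparent_c_index: float | None = None
    optimism: float | None = None
    threshold: dict = field(default_factory=dict)
    brier: float | None = None
    calibration: pd.DataFrame | None = None
    roc: pd.DataFrame | None = None
    subgroups: pd.DataFrame | None = None
    fairness: dict | None = None
    model_comparisons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def df(x):
            return x.to_dict(orient="list") if isinstance(x, pd.DataFrame) else x

        return {
            "kind": self.kind,
            "c_index": self.c_index,
            "c_index_ci": list(self.c_index_ci) if self.c_index_ci else None,
            "apparent_c_index": self.apparent_c_index,
            "optimism": self.optimism,
            "threshold": self.threshold,
            "brier": self.brier,
            "calibration": df(self.calibration),
            "roc": df(self.roc),
            "subgroups": df(self.subgroups),
            "fairness": self.fairness,
            "model_comparisons": self.model_comparisons,
        }


def external_cindex_ci(
    risks, time, event, B: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """c-index with a patient-level bootstrap percentile CI."""
    risks = np.asarray(risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    c = c_index(risks, time, event)
    rng = np.random.default_rng(seed)
    n = time.size
    vals = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            if event[idx].any():
                break
        vals[b] = c_index(risks[idx], time[idx], event[idx])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return c, (float(lo), float(hi))
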