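"""Proportional-hazards early-warning-score models.

The central objects follow the Model/Results convention: build a
:class:`CoxRiskModel` from a cohort table (time, event) and a feature table
(predictors), call :meth:`~CoxRiskModel.fit`, and work with the returned
:class:`CoxRiskResults` — coefficients with CIs, ``summary()``, absolute
180-day risk prediction, the Schoenfeld proportional-hazards test, and
text-based save/load.

Four named specifications are available:

* ``baseline`` — diagnosis flags, gender, age;
* ``clinical_benchmark`` — baseline + clinical severity (what a clinician
  plausibly tracks);
* ``unadjusted`` — the four severity/instability metrics + diagnosis,
  gender, age;
* ``adjusted`` — unadjusted + the organisation-level hospitalisation
  log-odds covariate.

Continuous predictors are standardized (derivation-split constants, frozen
into the model); instability predictors may be square-root transformed when
that lowers the AIC. Partial-likelihood maximisation uses the Efron
approximation for tied event times (day-granular data ties often).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .data import DX_COLUMNS
from .features import CONTINUOUS_COLUMNS, METRIC_COLUMNS, ScalingConstants

HORIZON_DAYS = 180
INSTABILITY_COLUMNS = ("clinical_instability", "functional_instability")

_SERIAL_VERSION = "psyews-model-v1"

_BASE_COVARIATES = list(DX_COLUMNS) + ["gender", "age"]
_SPEC_COVARIATES = {
    "baseline": _BASE_COVARIATES,
    "clinical_benchmark": _BASE_COVARIATES + ["clinical_severity"],
    "unadjusted": list(METRIC_COLUMNS) + _BASE_COVARIATES,
    "adjusted": list(METRIC_COLUMNS) + _BASE_COVARIATES + ["org_logit_rate"],
}


@dataclass(frozen=True)
class ModelSpec:
    """Named covariate set plus per-instability sqrt-transform flags."""

    name: str
    covariates: tuple[str, ...]
    sqrt_transforms: dict[str, bool] = field(default_factory=dict)

    @classmethod
    def named(cls, name: str) -> "ModelSpec":
        if name not in _SPEC_COVARIATES:
            raise ValueError(
                f"unknown model spec {name!r}; choose from {sorted(_SPEC_COVARIATES)}"
            )
        return cls(name=name, covariates=tuple(_SPEC_COVARIATES[name]))

    @property
    def instability_covariates(self) -> list[str]:
        return [c for c in self.covariates if c in INSTABILITY_COLUMNS]


@dataclass(frozen=True)
class PHTestResult:
    """Grambsch-Therneau scaled-Schoenfeld test of proportional hazards."""

    per_covariate: pd.DataFrame  # chi2, p per design column
    global_chi2: float
    global_df: int
    global_p: float


class CoxRiskModel:
    """Cox proportional-hazards model of 6-month hospitalisation risk.

    Parameters
    ----------
    cohort
        One row per patient with ``patient_id``, ``time`` (days, in [0, 180])
        and ``event`` columns.
    features
        One row per patient with the predictor columns of ``spec``.
    spec
        A :class:`ModelSpec` or one of the four named specifications.
    scaling
        Frozen standardization constants (external validation / ground-truth
        recovery). When None and ``standardize`` is true, constants are
        estimated from this data (the derivation split).
    standardize
        Standardize continuous predictors. Disable only when the feature
        table is already on the desired scale.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        features: pd.DataFrame,
        spec: ModelSpec | str = "unadjusted",
        scaling: ScalingConstants | None = None,
        standardize: bool = True,
    ):
        if isinstance(spec, str):
            spec = ModelSpec.named(spec)
        self.spec = spec
        self.scaling = scaling
        self.standardize = standardize
        feat_cols = [c for c in features.columns if c not in ("time", "event")]
        data = cohort[["patient_id", "time", "event"]].merge(
            features[feat_cols], on="patient_id", validate="1:1"
        )
        missing = [c for c in spec.covariates if c not in data.columns and c != "gender"]
        if "gender" in spec.covariates and "gender" not in data.columns:
            missing.append("gender")
        if missing:
            raise ValueError(f"feature table is missing covariate(s) {missing}")
        self.data = data

    @classmethod
    def from_tables(cls, cohort, features, spec="unadjusted", **kwargs) -> "CoxRiskModel":
        return cls(cohort, features, spec, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self, select_transforms: bool = False, tol: float | None = None) -> "CoxRiskResults":
        """Maximise the Efron partial likelihood; optionally select sqrt
        transforms for the instability predictors by AIC (kept only when the
        AIC is strictly lower).

        ``tol`` tightens the Newton stopping rule (the terminal parameter
        error is about sqrt(2*tol)); None keeps the solver default.
        """
        spec = self.spec
        if select_transforms and spec.instability_covariates:
            flags = {}
            base_aic = self._fit_once(replace(spec, sqrt_transforms={}), tol).aic
            for var in spec.instability_covariates:
                cand = self._fit_once(replace(spec, sqrt_transforms={var: True}), tol).aic
                flags[var] = cand < base_aic
            spec = replace(spec, sqrt_transforms=flags)
        res = self._fit_once(spec, tol)
        return res

    def _fit_once(self, spec: ModelSpec, tol: float | None = None) -> "CoxRiskResults":
        X, scaling = self._design(self.data, spec, self.scaling)
        if int(self.data["event"].sum()) < 1:
            raise ValueError("cannot fit a Cox model with no events")
        dropped = [c for c in X.columns if X[c].nunique() <= 1]
        X = X.drop(columns=dropped)
        # binary indicators whose on- (or off-) group has no events have no
        # finite MLE (monotone likelihood); exclude and record them
        events = self.data["event"].to_numpy(bool)
        for c in list(X.columns):
            col = X[c]
            if col.nunique() == 2 and set(col.unique()) == {0.0, 1.0}:
                on = col.to_numpy() == 1.0
                if not events[on].any() or not events[~on].any():
                    warnings.warn(
                        f"covariate {c!r} is completely separated "
                        "(an event-free group); excluded from the fit",
                        stacklevel=2,
                    )
                    dropped.append(c)
                    X = X.drop(columns=c)
        # centered rank: the Cox design is translation invariant
        Xc = X.to_numpy(float)
        rank = np.linalg.matrix_rank(Xc - Xc.mean(axis=0))
        if rank < X.shape[1]:
            corr = X.corr().abs()
            np.fill_diagonal(corr.values, 0.0)
            pair = corr.stack().idxmax()
            raise ValueError(
                f"design matrix is rank deficient; near-collinear covariates "
                f"include {pair}"
            )
        df = X.copy()
        df["time"] = self.data["time"].to_numpy(float)
        df["event"] = self.data["event"].to_numpy(int)
        fit_options = None
        if tol is not None:
            fit_options = {"precision": tol, "r_precision": 1e-16}
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event", fit_options=fit_options)
        except ConvergenceError:
            # the default Newton step can overshoot on near-collinear or
            # quasi-separated designs; a damped step reaches the same MLE
            warnings.warn(
                "Newton iteration diverged at the default step size; "
                "retrying with a damped step",
                stacklevel=2,
            )
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={**(fit_options or {}), "step_size": 0.1})
        s0_180 = _baseline_survival_at_zero(cph, HORIZON_DAYS)
        return CoxRiskResults(
            spec=spec,
            params=cph.params_.copy(),
            bse=cph.standard_errors_.copy(),
            vcov=cph.variance_matrix_.copy(),
            scaling=scaling,
            s0_180=s0_180,
            log_likelihood=float(cph.log_likelihood_),
            aic=float(cph.AIC_partial_),
            n=len(df),
            n_events=int(df["event"].sum()),
            dropped_columns=dropped,
            _cph=cph,
            _train_df=df,
        )

    # -- design matrix -----------------------------------------------------

    def _design(
        self, data: pd.DataFrame, spec: ModelSpec, scaling: ScalingConstants | None
    ) -> tuple[pd.DataFrame, ScalingConstants | None]:
        return build_design(data, spec, scaling, self.standardize)


def build_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    scaling: ScalingConstants | None,
    standardize: bool,
    fit_scaling_if_missing: bool = True,
) -> tuple[pd.DataFrame, ScalingConstants | None]:
    """Encode covariates: sqrt transforms, standardization, gender dummies.

    The sqrt transform is applied to the raw instability values before
    standardization, and scaling constants therefore refer to the
    transformed variables.
    """
    cols = {}
    work = data.copy()
    for var, flag in spec.sqrt_transforms.items():
        if flag and var in work.columns:
            work[var] = np.sqrt(work[var].to_numpy(float))
    cont = [c for c in spec.covariates if c in CONTINUOUS_COLUMNS]
    if standardize and cont:
        if scaling is None:
            if not fit_scaling_if_missing:
                raise ValueError("scaling constants required but not supplied")
            # constant predictors stay raw; the constant column is dropped later
            varying = [c for c in cont if work[c].nunique() > 1]
            scaling = ScalingConstants.fit(work, columns=varying)
        for c in cont:
            if c in scaling.means:
                work[c] = (work[c] - scaling.means[c]) / scaling.sds[c]
    for c in spec.covariates:
        if c == "gender":
            g = work["gender"]
            cols["gender_male"] = (g == "male").astype(float)
            cols["gender_unknown"] = (g == "unknown").astype(float)
        elif c in DX_COLUMNS:
            cols[c] = work[c].astype(float)
        else:
            if work[c].isna().any():
                raise ValueError(f"covariate {c!r} has missing values")
            cols[c] = work[c].astype(float)
    return pd.DataFrame(cols, index=work.index), scaling


def _baseline_survival_at_zero(cph: CoxPHFitter, t: float) -> float:
    """S0(t) referenced to a zero covariate vector (lifelines references the
    training mean)."""
    bs = cph.baseline_survival_["baseline survival"]
    times = bs.index.to_numpy(float)
    idx = np.searchsorted(times, t, side="right") - 1
    s_mean = float(bs.iloc[idx]) if idx >= 0 else 1.0
    mean_lp = float(np.dot(cph._norm_mean.loc[cph.params_.index], cph.params_))
    return s_mean ** np.exp(-mean_lp)


@dataclass
class CoxRiskResults:
    """Frozen fitted model: everything needed to emit absolute risks."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    vcov: pd.DataFrame
    scaling: ScalingConstants | None
    s0_180: float
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    dropped_columns: list[str]
    _cph: CoxPHFitter | None = None
    _train_df: pd.DataFrame | None = None

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        with np.errstate(over="ignore"):  # quasi-separated indicators -> inf bound
            return pd.DataFrame(
                {
                    "lower": np.exp(self.params - z * self.bse),
                    "upper": np.exp(self.params + z * self.bse),
                }
            )

    def summary(self) -> pd.DataFrame:
        """Hazard-ratio table with 95% CIs and Wald p-values."""
        z = self.params / self.bse
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se": self.bse,
                "HR lower 95%": ci["lower"],
                "HR upper 95%": ci["upper"],
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    def __str__(self) -> str:
        head = (
            f"CoxRiskResults: spec={self.spec.name!r}, n={self.n}, "
            f"events={self.n_events}, AIC={self.aic:.1f}, "
            f"S0(180)={self.s0_180:.5f}\n"
            f"sqrt transforms: {self.spec.sqrt_transforms or 'none'}\n"
        )
        return head + self.summary().round(4).to_string()

    # -- prediction --------------------------------------------------------

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        X, _ = build_design(
            features, self.spec, self.scaling, standardize=self.scaling is not None,
            fit_scaling_if_missing=False,
        )
        for c in self.dropped_columns:
            if c in X.columns:
                X = X.drop(columns=c)
        missing = [c for c in self.params.index if c not in X.columns]
        if missing:
            raise ValueError(f"features are missing covariate(s) {missing}")
        return X[self.params.index].to_numpy(float) @ self.params.to_numpy()

    def predict_risk(self, features: pd.DataFrame) -> np.ndarray:
        """Absolute 180-day hospitalisation risk, 1 - S0(180)^exp(lp)."""
        lp = self.linear_predictor(features)
        return 1.0 - self.s0_180 ** np.exp(lp)

    # -- proportional hazards test ----------------------------------------

    def test_proportional_hazards(self, transform: str = "identity") -> PHTestResult:
        """Scaled Schoenfeld residual score test, per covariate and global.

        Per-covariate and global chi-square statistics follow the
        Grambsch-Therneau construction with g(t) the identity transform of
        event time by default ("km" selects the Kaplan-Meier transform).
        """
        if self._cph is None or self._train_df is None:
            raise ValueError(
                "proportional-hazards test requires the in-memory fit "
                "(not available on a model loaded from disk)"
            )
        resid = self._cph.compute_residuals(self._train_df, "schoenfeld")
        resid = resid[self.params.index]
        times = self._train_df.loc[resid.index, "time"].to_numpy(float)
        order = np.argsort(times, kind="stable")
        times = times[order]
        R = resid.to_numpy(float)[order]
        d = len(times)
        if transform == "identity":
            g = times
        elif transform == "km":
            # 1 - KM(t-) over the training sample, the survival-package default
            from sksurv.nonparametric import kaplan_meier_estimator

            ev = self._train_df["event"].to_numpy(bool)
            tt = self._train_df["time"].to_numpy(float)
            ut, sp = kaplan_meier_estimator(ev, tt)
            idx = np.searchsorted(ut, times, side="left") - 1
            g = 1.0 - np.where(idx >= 0, sp[idx], 1.0)
        else:
            raise ValueError(f"unknown time transform {transform!r}")
        w = g - g.mean()
        sw2 = float(np.sum(w**2))
        V = self.vcov.loc[self.params.index, self.params.index].to_numpy(float)
        u = R.T @ w
        global_chi2 = float(d * u @ V @ u / sw2)
        per_chi2 = d * (V @ u) ** 2 / (np.diag(V) * sw2)
        per = pd.DataFrame(
            {
                "chi2": per_chi2,
                "p": stats.chi2.sf(per_chi2, 1),
            },
            index=self.params.index,
        )
        p = float(stats.chi2.sf(global_chi2, len(self.params)))
        return PHTestResult(per, global_chi2, len(self.params), p)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "version": _SERIAL_VERSION,
            "spec": {
                "name": self.spec.name,
                "covariates": list(self.spec.covariates),
                "sqrt_transforms": self.spec.sqrt_transforms,
            },
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "vcov": {
                "index": list(self.vcov.index),
                "values": self.vcov.to_numpy().tolist(),
            },
            "scaling": self.scaling.to_dict() if self.scaling else None,
            "s0_180": self.s0_180,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n": self.n,
            "n_events": self.n_events,
            "dropped_columns": self.dropped_columns,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CoxRiskResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != _SERIAL_VERSION:
            raise ValueError(
                f"unsupported model file version {payload.get('version')!r}; "
                f"expected {_SERIAL_VERSION!r}"
            )
        required = {"spec", "params", "bse", "vcov", "scaling", "s0_180",
                    "log_likelihood", "aic", "n", "n_events", "dropped_columns"}
        missing = required - payload.keys()
        if missing:
            raise ValueError(f"model file is missing field(s) {sorted(missing)}")
        spec = ModelSpec(
            name=payload["spec"]["name"],
            covariates=tuple(payload["spec"]["covariates"]),
            sqrt_transforms=dict(payload["spec"]["sqrt_transforms"]),
        )
        idx = payload["vcov"]["index"]
        params = pd.Series(payload["params"], name="coef")
        params.index.name = "covariate"
        bse = pd.Series(payload["bse"], name="se")
        bse.index.name = "covariate"
        return cls(
            spec=spec,
            params=params,
            bse=bse,
            vcov=pd.DataFrame(payload["vcov"]["values"], index=idx, columns=idx),
            scaling=(
                ScalingConstants.from_dict(payload["scaling"])
                if payload["scaling"]
                else None
            ),
            s0_180=payload["s0_180"],
            log_likelihood=payload["log_likelihood"],
            aic=payload["aic"],
            n=payload["n"],
            n_events=payload["n_events"],
            dropped_columns=list(payload["dropped_columns"]),
        )
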