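import json

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import kstest

from psyews.cohort import build_cohort
from psyews.features import ScalingConstants, derive_features
from psyews.model import CoxRiskModel, CoxRiskResults, ModelSpec

from conftest import make_dataset, make_patient


def cox_neg_log_partial_likelihood(beta, x, time, event):
    """Hand-written Cox partial likelihood for untied single-covariate data."""
    nll = 0.0
    for i in np.flatnonzero(event):
        at_risk = time >= time[i]
        nll -= beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return nll


def five_subject_fixture():
    cohort = pd.DataFrame(
        {"patient_id": list("abcde"),
         "time": [3.0, 5.0, 8.0, 11.0, 14.0],
         "event": [True, True, False, True, False]}
    )
    features = pd.DataFrame(
        {"patient_id": list("abcde"), "dx_mdd": [1.0, 0.0, 1.0, 1.0, 0.0]}
    )
    return cohort, features


class TestCoxOracle:
    def test_coefficient_matches_direct_partial_likelihood_maximum(self):
        cohort, features = five_subject_fixture()
        spec = ModelSpec(name="single", covariates=("dx_mdd",))
        fit = CoxRiskModel(cohort, features, spec, standardize=False).fit(tol=1e-14)
        x = features["dx_mdd"].to_numpy()
        t = cohort["time"].to_numpy()
        e = cohort["event"].to_numpy(bool)
        res = minimize_scalar(
            cox_neg_log_partial_likelihood, bounds=(-5, 5), args=(x, t, e),
            method="bounded", options={"xatol": 1e-10},
        )
        assert fit.params["dx_mdd"] == pytest.approx(res.x, abs=1e-6)

    def test_fitted_coefficient_is_a_local_maximum(self):
        cohort, features = five_subject_fixture()
        spec = ModelSpec(name="single", covariates=("dx_mdd",))
        fit = CoxRiskModel(cohort, features, spec, standardize=False).fit()
        x = features["dx_mdd"].to_numpy()
        t = cohort["time"].to_numpy()
        e = cohort["event"].to_numpy(bool)
        best = cox_neg_log_partial_likelihood(fit.params["dx_mdd"], x, t, e)
        for delta in (-0.05, 0.05, -0.5, 0.5):
            assert best <= cox_neg_log_partial_likelihood(
                fit.params["dx_mdd"] + delta, x, t, e
            )

    def test_null_covariate_rarely_exceeds_three_standard_errors(self):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            n = 800
            cohort = pd.DataFrame({
                "patient_id": [f"p{i}" for i in range(n)],
                "time": np.minimum(rng.exponential(100, n), 180.0),
            })
            cohort["event"] = cohort["time"] < 180.0
            features = pd.DataFrame({
                "patient_id": cohort["patient_id"],
                "age": rng.normal(size=n),  # independent of outcome
            })
            spec = ModelSpec(name="null", covariates=("age",))
            fit = CoxRiskModel(cohort, features, spec, standardize=False).fit()
            if abs(fit.params["age"]) < 3 * fit.bse["age"]:
                hits += 1
        assert hits / n_seeds >= 0.9

    def test_no_events_rejected(self):
        cohort, features = five_subject_fixture()
        cohort["event"] = False
        spec = ModelSpec(name="single", covariates=("dx_mdd",))
        with pytest.raises(ValueError, match="no events"):
            CoxRiskModel(cohort, features, spec, standardize=False).fit()

    def test_collinear_covariates_named(self):
        cohort, features = five_subject_fixture()
        features["age"] = 2.0 * features["dx_mdd"] + 1.0
        spec = ModelSpec(name="two", covariates=("dx_mdd", "age"))
        with pytest.raises(ValueError, match="rank deficient"):
            CoxRiskModel(cohort, features, spec, standardize=False).fit()


def simulate_single_covariate(rng, n, lam_fn, censor=180.0):
    """Event times with hazard lam_fn(x) constant in time."""
    x = rng.uniform(0.0, 4.0, n)
    t = rng.exponential(1.0 / lam_fn(x))
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "time": np.minimum(t, censor),
        "event": t <= censor,
        "clinical_instability": x,
    })


class TestTransformSelection:
    def test_sqrt_selected_when_hazard_is_linear_in_sqrt(self):
        chosen = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            df = simulate_single_covariate(
                rng, 2000, lambda x: 0.002 * np.exp(1.5 * np.sqrt(x))
            )
            spec = ModelSpec(name="inst", covariates=("clinical_instability",))
            fit = CoxRiskModel(
                df[["patient_id", "time", "event"]], df, spec
            ).fit(select_transforms=True)
            chosen += fit.spec.sqrt_transforms["clinical_instability"]
        assert chosen >= 3

    def test_raw_kept_when_hazard_is_linear_in_raw(self):
        chosen = 0
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            df = simulate_single_covariate(
                rng, 2000, lambda x: 0.002 * np.exp(0.9 * x)
            )
            spec = ModelSpec(name="inst", covariates=("clinical_instability",))
            fit = CoxRiskModel(
                df[["patient_id", "time", "event"]], df, spec
            ).fit(select_transforms=True)
            chosen += fit.spec.sqrt_transforms["clinical_instability"]
        assert chosen <= 2


class TestPrediction:
    def test_mean_covariates_give_baseline_risk(self):
        rng = np.random.default_rng(4)
        n = 500
        cohort = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "time": np.minimum(rng.exponential(400, n), 180.0),
        })
        cohort["event"] = cohort["time"] < 180.0
        features = pd.DataFrame({
            "patient_id": cohort["patient_id"],
            "age": rng.normal(40, 10, n),
            "clinical_severity": rng.normal(4, 1, n),
        })
        spec = ModelSpec(name="cont", covariates=("age", "clinical_severity"))
        fit = CoxRiskModel(cohort, features, spec).fit()
        at_mean = pd.DataFrame({
            "patient_id": ["m"],
            "age": [features["age"].mean()],
            "clinical_severity": [features["clinical_severity"].mean()],
        })
        assert fit.predict_risk(at_mean)[0] == pytest.approx(1 - fit.s0_180, abs=1e-9)

    def test_risk_monotone_in_positive_coefficient_covariate(self, reference_10k):
        fit = CoxRiskModel(
            reference_10k["cohort"], reference_10k["features"], "unadjusted"
        ).fit()
        feats = reference_10k["features"]
        base = feats.iloc[[0]].copy()
        sign = np.sign(fit.params["functional_severity"])
        grid = []
        for v in (20.0, 40.0, 60.0):
            row = base.copy()
            row["functional_severity"] = v
            grid.append(fit.predict_risk(row)[0])
        if sign > 0:
            assert grid[0] < grid[1] < grid[2]
        risks = fit.predict_risk(feats)
        assert ((risks >= 0) & (risks <= 1)).all()

    def test_missing_covariate_named(self):
        cohort, features = five_subject_fixture()
        spec = ModelSpec(name="single", covariates=("dx_mdd",))
        fit = CoxRiskModel(cohort, features, spec, standardize=False).fit()
        with pytest.raises((ValueError, KeyError), match="dx_mdd"):
            fit.predict_risk(features.drop(columns="dx_mdd"))


class TestAdjustedModel:
    def test_constant_org_rate_reduces_to_unadjusted(self, reference_10k):
        cohort = reference_10k["cohort"].head(3000)
        feats = reference_10k["features"].head(3000).copy()
        feats["org_logit_rate"] = -4.0  # all orgs identical
        fit_adj = CoxRiskModel(cohort, feats, "adjusted").fit()
        fit_un = CoxRiskModel(cohort, feats, "unadjusted").fit()
        assert "org_logit_rate" in fit_adj.dropped_columns
        pd.testing.assert_series_equal(fit_adj.params, fit_un.params)

    def test_benchmark_aic_within_penalty_of_baseline_under_null(self):
        from psyews.simulate import SimulationConfig, simulate_dataset

        for seed in (1, 2):
            cfg = SimulationConfig(n_patients=2500, n_orgs=4, seed=seed,
                                   study_span=450, visit_rate=2.0,
                                   baseline_180d_risk=0.03, org_logit_sd=0.0)
            ds, _ = simulate_dataset(cfg)
            cohort, _ = build_cohort(ds)
            feats = derive_features(cohort, ds.visits, ds.patients)
            aic_base = CoxRiskModel(cohort, feats, "baseline").fit().aic
            aic_bench = CoxRiskModel(cohort, feats, "clinical_benchmark").fit().aic
            assert aic_bench <= aic_base + 2.0


class TestProportionalHazardsTest:
    def test_single_covariate_has_df_one(self):
        rng = np.random.default_rng(9)
        df = simulate_single_covariate(rng, 500, lambda x: 0.01 * np.exp(0.3 * x))
        spec = ModelSpec(name="inst", covariates=("clinical_instability",))
        fit = CoxRiskModel(df[["patient_id", "time", "event"]], df, spec).fit()
        ph = fit.test_proportional_hazards()
        assert ph.global_df == 1
        assert ph.per_covariate.shape[0] == 1
        assert 0 <= ph.global_p <= 1

    def test_null_global_p_uniform(self):
        """Constant hazard ratios -> the global PH p-value is uniform."""
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(5000 + seed)
            n = 300
            x1 = rng.normal(size=n)
            x2 = rng.binomial(1, 0.4, n).astype(float)
            t = rng.exponential(1.0 / (0.01 * np.exp(0.4 * x1 + 0.3 * x2)))
            df = pd.DataFrame({
                "patient_id": [f"p{i}" for i in range(n)],
                "time": np.minimum(t, 180.0), "event": t <= 180.0,
                "age": x1, "dx_mdd": x2,
            })
            spec = ModelSpec(name="two", covariates=("age", "dx_mdd"))
            fit = CoxRiskModel(
                df[["patient_id", "time", "event"]], df, spec, standardize=False
            ).fit()
            ps.append(fit.test_proportional_hazards().global_p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_reversing_effect_detected(self):
        detected = 0
        for seed in range(5):
            rng = np.random.default_rng(7000 + seed)
            n = 3000
            x = rng.binomial(1, 0.5, n).astype(float)
            # hazard ratio e^1 before day 90, e^-1 after
            r1 = 0.004 * np.exp(1.0 * x)
            r2 = 0.004 * np.exp(-1.0 * x)
            t1 = rng.exponential(1.0 / r1)
            t = np.where(t1 < 90, t1, 90 + rng.exponential(1.0 / r2))
            df = pd.DataFrame({
                "patient_id": [f"p{i}" for i in range(n)],
                "time": np.minimum(t, 180.0), "event": t <= 180.0,
                "dx_mdd": x,
            })
            spec = ModelSpec(name="one", covariates=("dx_mdd",))
            fit = CoxRiskModel(
                df[["patient_id", "time", "event"]], df, spec, standardize=False
            ).fit()
            if fit.test_proportional_hazards().global_p < 0.05:
                detected += 1
        assert detected >= 3


class TestSerialization:
    def test_round_trip_preserves_fields_and_predictions(self, tmp_path, reference_10k):
        cohort = reference_10k["cohort"].head(2000)
        feats = reference_10k["features"].head(2000)
        fit = CoxRiskModel(cohort, feats, "unadjusted").fit(select_transforms=True)
        path = fit.save(tmp_path / "model.json")
        back = CoxRiskResults.load(path)
        pd.testing.assert_series_equal(fit.params, back.params)
        assert back.spec == fit.spec
        assert back.scaling == fit.scaling
        assert back.s0_180 == fit.s0_180
        np.testing.assert_array_equal(
            fit.predict_risk(feats), back.predict_risk(feats)
        )

    def test_tampered_file_rejected(self, tmp_path):
        cohort, features = five_subject_fixture()
        spec = ModelSpec(name="single", covariates=("dx_mdd",))
        fit = CoxRiskModel(cohort, features, spec, standardize=False).fit()
        path = fit.save(tmp_path / "model.json")
        payload = json.loads(path.read_text())
        payload["coefficients"] = payload.pop("params")
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="params"):
            CoxRiskResults.load(path)

    def test_version_mismatch_rejected(self, tmp_path):
        cohort, features = five_subject_fixture()
        spec = ModelSpec(name="single", covariates=("dx_mdd",))
        fit = CoxRiskModel(cohort, features, spec, standardize=False).fit()
        path = fit.save(tmp_path / "model.json")
        payload = json.loads(path.read_text())
        payload["version"] = "psyews-model-v999"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="version"):
            CoxRiskResults.load(path)
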