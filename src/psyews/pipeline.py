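"""End-to-end pipeline: simulate -> cohort -> features -> fit -> validate ->
impact -> report.

Every stage reads only prior-stage artifacts from the run directory, and
the whole run is a pure function of (inputs, config, seed): rerunning with
the same configuration reproduces byte-identical outputs. A manifest
records the resolved configuration, SHA-256 digests of every artifact and
per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import impact as impact_mod
from .cohort import build_cohort
from .data import Dataset, read_dataset, write_dataset
from .features import ScalingConstants, derive_features, org_rates_from_cohort
from .model import CoxRiskModel, CoxRiskResults
from .simulate import SimulationConfig, preset_reference, simulate_dataset
from .validation import (
    OperatingPointConfig,
    ValidationReport,
    brier_score,
    calibration_curve,
    compare_models_bootstrap,
    external_cindex_ci,
    optimism_corrected_cindex,
    permutation_fairness_test,
    roc_points,
    subgroup_cindices,
    threshold_metrics,
    binary_outcome,
)

log = logging.getLogger("psyews")

MODEL_NAMES = ("baseline", "clinical_benchmark", "unadjusted", "adjusted")


@dataclass
class PipelineConfig:
    out_dir: str = "psyews_run"
    seed: int = 0
    simulation: SimulationConfig | None = None  # None: read CSVs from out_dir
    models: tuple[str, ...] = MODEL_NAMES
    operating_point: OperatingPointConfig = field(default_factory=OperatingPointConfig)
    b_optimism: int = 200
    n_permutations: int = 100
    b_compare: int = 1000
    calibration_bins: int = 10
    odds_reduction: float = 0.80

    def validate(self) -> "PipelineConfig":
        for name, v in (("b_optimism", self.b_optimism),
                        ("n_permutations", self.n_permutations),
                        ("b_compare", self.b_compare)):
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        return self


@dataclass
class RunManifest:
    config: dict
    digests: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)

    def record(self, path: Path, rows: int | None = None) -> None:
        self.digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        if rows is not None:
            self.row_counts[path.name] = rows

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "digests": self.digests,
             "row_counts": self.row_counts}, indent=1, sort_keys=True))


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages in order inside ``cfg.out_dir``; see module docs."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_dict(cfg))

    # -- stage: data -------------------------------------------------------
    if cfg.simulation is not None:
        sim_cfg = cfg.simulation
        log.info("simulating %d patients (seed %d)", sim_cfg.n_patients, sim_cfg.seed)
        ds, truth = simulate_dataset(sim_cfg)
        paths = write_dataset(ds, out)
        truth.table.to_csv(out / "ground_truth.csv", index=False)
        _write_json(out / "simulation_config.json", sim_cfg.to_dict())
        for p in paths.values():
            manifest.record(p)
        manifest.record(out / "ground_truth.csv", len(truth.table))
    ds = read_dataset(out)

    # -- stage: cohort -----------------------------------------------------
    cohort, exclusions = build_cohort(ds)
    cohort.to_csv(out / "cohort.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    manifest.record(out / "cohort.csv", len(cohort))
    manifest.record(out / "exclusions.csv", len(exclusions))
    log.info("cohort: %d included, %d excluded", len(cohort), len(exclusions))

    # -- stage: features (derivation org rates only; validation rates are
    # computed on the validation cohort itself at external-validation time) -
    deriv_ids = set(ds.split_patients("derivation")["patient_id"])
    val_ids = set(ds.split_patients("validation")["patient_id"])
    co_d = cohort[cohort["patient_id"].isin(deriv_ids)].reset_index(drop=True)
    co_v = cohort[cohort["patient_id"].isin(val_ids)].reset_index(drop=True)
    rates_d = org_rates_from_cohort(co_d, ds.patients)
    rates_v = org_rates_from_cohort(co_v, ds.patients) if len(co_v) else {}
    feats_d = derive_features(co_d, ds.visits, ds.patients, org_rates=rates_d)
    feats_v = (
        derive_features(co_v, ds.visits, ds.patients, org_rates=rates_v)
        if len(co_v)
        else None
    )
    feats_d.to_csv(out / "features_derivation.csv", index=False)
    manifest.record(out / "features_derivation.csv", len(feats_d))
    if feats_v is not None:
        feats_v.to_csv(out / "features_validation.csv", index=False)
        manifest.record(out / "features_validation.csv", len(feats_v))
    pd.DataFrame(
        sorted(rates_d.items()), columns=["org_id", "logit_rate"]
    ).to_csv(out / "org_rates.csv", index=False)
    manifest.record(out / "org_rates.csv", len(rates_d))

    # -- stage: fit --------------------------------------------------------
    fits: dict[str, CoxRiskResults] = {}
    for name in cfg.models:
        fit = CoxRiskModel(co_d, feats_d, name).fit(select_transforms=True)
        fit.save(out / f"model_{name}.json")
        manifest.record(out / f"model_{name}.json")
        fits[name] = fit
        log.info("fitted %s: %d covariates, AIC %.1f", name, len(fit.params), fit.aic)

    # -- stage: validate ---------------------------------------------------
    reports = {}
    pats_d = feats_d  # row-aligned with co_d (merge order preserved)
    for name in cfg.models:
        fit = fits[name]
        risks_d = fit.predict_risk(feats_d)
        internal = _internal_report(cfg, name, co_d, feats_d, risks_d, pats_d)
        reports[f"internal_{name}"] = internal
        if feats_v is not None and co_v["event"].any():
            risks_v = fit.predict_risk(feats_v)
            external = _external_report(cfg, co_v, risks_v, feats_v)
            reports[f"external_{name}"] = external
    if feats_v is not None and co_v["event"].any():
        _add_model_comparisons(cfg, reports, fits, feats_v, co_v)

    report_payload = {k: v.to_dict() for k, v in reports.items()}
    _write_json(out / "validation_report.json", report_payload)
    manifest.record(out / "validation_report.json")
    for k, rep in reports.items():
        if rep.calibration is not None:
            rep.calibration.to_csv(out / f"calibration_{k}.csv", index=False)
            manifest.record(out / f"calibration_{k}.csv")
        if rep.roc is not None:
            rep.roc.to_csv(out / f"roc_{k}.csv", index=False)
            manifest.record(out / f"roc_{k}.csv")

    # -- stage: impact -----------------------------------------------------
    ppv_bench = reports.get("internal_clinical_benchmark")
    ppv_model = reports.get("internal_adjusted") or reports.get("internal_unadjusted")
    impact_payload = {}
    if ppv_bench and ppv_model:
        pb = ppv_bench.threshold.get("ppv")
        pm = ppv_model.threshold.get("ppv")
        if pb and pm and 0 < pb < 1 and 0 < pm < 1 and pm > pb:
            impact_payload = impact_mod.benchmark_comparison(
                ppv_benchmark=pb, ppv_model=pm, odds_reduction=cfg.odds_reduction
            )
    _write_json(out / "impact.json", impact_payload)
    manifest.record(out / "impact.json")

    # -- stage: report -----------------------------------------------------
    text = render_report(cfg, fits, reports, impact_payload)
    (out / "report.txt").write_text(text)
    manifest.record(out / "report.txt")
    manifest.save(out / "manifest.json")
    return manifest


def _internal_report(cfg, name, co_d, feats_d, risks_d, pats_d) -> ValidationReport:
    time = co_d["time"].to_numpy(float)
    event = co_d["event"].to_numpy(bool)
    opt = optimism_corrected_cindex(
        co_d, feats_d, name, B=cfg.b_optimism, seed=cfg.seed + 11
    )
    fairness = None
    race = pats_d["race_group"].to_numpy()
    if ((race == "white").any() and (race == "non_white").any()
            and event[(race == "white")].any() and event[race == "non_white"].any()):
        fairness = permutation_fairness_test(
            risks_d, time, event, race, P=cfg.n_permutations, seed=cfg.seed + 13
        )
    return ValidationReport(
        kind="internal",
        c_index=opt.corrected,
        c_index_ci=(opt.ci_lower, opt.ci_upper),
        apparent_c_index=opt.apparent,
        optimism=opt.optimism,
        threshold=threshold_metrics(risks_d, time, event, cfg.operating_point),
        brier=brier_score(risks_d, time, event),
        calibration=calibration_curve(
            risks_d, time, event, bins=cfg.calibration_bins, seed=cfg.seed + 17
        ),
        roc=roc_points(risks_d, binary_outcome(time, event)),
        subgroups=subgroup_cindices(risks_d, time, event, pats_d),
        fairness=fairness,
    )


def _external_report(cfg, co_v, risks_v, pats_v) -> ValidationReport:
    time = co_v["time"].to_numpy(float)
    event = co_v["event"].to_numpy(bool)
    c, ci = external_cindex_ci(risks_v, time, event, B=cfg.b_compare, seed=cfg.seed + 19)
    fairness = None
    race = pats_v["race_group"].to_numpy()
    if ((race == "white").any() and (race == "non_white").any()
            and event[race == "white"].any() and event[race == "non_white"].any()):
        fairness = permutation_fairness_test(
            risks_v, time, event, race, P=cfg.n_permutations, seed=cfg.seed + 23
        )
    return ValidationReport(
        kind="external",
        c_index=c,
        c_index_ci=ci,
        threshold=threshold_metrics(risks_v, time, event, cfg.operating_point),
        brier=brier_score(risks_v, time, event),
        calibration=calibration_curve(
            risks_v, time, event, bins=cfg.calibration_bins, seed=cfg.seed + 29
        ),
        roc=roc_points(risks_v, binary_outcome(time, event)),
        subgroups=subgroup_cindices(risks_v, time, event, pats_v),
        fairness=fairness,
    )


def _add_model_comparisons(cfg, reports, fits, feats_v, co_v) -> None:
    time = co_v["time"].to_numpy(float)
    event = co_v["event"].to_numpy(bool)
    risk = {n: fits[n].predict_risk(feats_v) for n in fits}
    for primary in ("unadjusted", "adjusted"):
        for ref in ("baseline", "clinical_benchmark"):
            if primary in risk and ref in risk and f"external_{primary}" in reports:
                reports[f"external_{primary}"].model_comparisons[f"vs_{ref}"] = (
                    compare_models_bootstrap(
                        risk[primary], risk[ref], time, event,
                        B=cfg.b_compare, seed=cfg.seed + 31,
                    )
                )


def render_report(cfg, fits, reports, impact_payload) -> str:
    """Human-readable run summary mirroring a results-section layout."""
    lines = ["psyews pipeline report", "=" * 60, ""]
    for name, fit in fits.items():
        lines += [f"--- model: {name} ---", str(fit), ""]
    for key, rep in reports.items():
        lines.append(f"--- validation: {key} ---")
        if rep.kind == "internal":
            lines.append(
                f"c-index {rep.c_index:.3f} "
                f"(apparent {rep.apparent_c_index:.3f}, optimism {rep.optimism:.4f}, "
                f"95% CI {rep.c_index_ci[0]:.3f}-{rep.c_index_ci[1]:.3f})"
            )
        else:
            lines.append(
                f"c-index {rep.c_index:.3f} "
                f"(95% CI {rep.c_index_ci[0]:.3f}-{rep.c_index_ci[1]:.3f})"
            )
        th = rep.threshold
        if th:
            lines.append(
                f"operating point (top {cfg.operating_point.flag_fraction:.0%}, "
                f"pinned incidence {cfg.operating_point.prespecified_incidence:.0%}): "
                f"se {th['sensitivity']:.3f}, sp {th['specificity']:.3f}, "
                f"PPV {th['ppv']:.3f}, NPV {th['npv']:.3f}"
            )
        lines.append(f"Brier score {rep.brier:.4f}")
        if rep.fairness:
            f = rep.fairness
            lines.append(
                f"fairness: c white {f['c_white']:.3f}, non-white "
                f"{f['c_non_white']:.3f}, permutation p {f['p']:.3f}"
            )
        if rep.subgroups is not None:
            lines.append("per-diagnosis / race c-indices:")
            lines.append(rep.subgroups.round(3).to_string(index=False))
        for ref, cmpres in rep.model_comparisons.items():
            lines.append(
                f"delta c {ref}: {cmpres['delta_c']:.3f} "
                f"(95% CI {cmpres['ci_lower']:.3f}-{cmpres['ci_upper']:.3f}, "
                f"p {cmpres['p']:.3f})"
            )
        lines.append("")
    if impact_payload:
        lines.append("--- intervention impact (odds reduction "
                     f"{cfg.odds_reduction:.0%}) ---")
        for k, v in impact_payload.items():
            lines.append(f"{k}: {v:.1f}" if isinstance(v, float) else f"{k}: {v}")
    lines.append("")
    return "\n".join(lines)


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["simulation"] = cfg.simulation.to_dict() if cfg.simulation else None
    d["models"] = list(cfg.models)
    return d


def reference_pipeline_config(
    out_dir: str, n_patients: int = 20000, seed: int = 0, **overrides
) -> PipelineConfig:
    """Study-condition pipeline config on a reference simulation."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        simulation=preset_reference(n_patients=n_patients, seed=seed),
        **overrides,
    )
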