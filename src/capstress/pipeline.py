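"""End-to-end workflow: design -> simulate -> fit models -> verify -> simulate grid.

All randomness flows from one master seed: the simulator uses it directly and
the random forest uses a fixed offset of it, so rerunning a configuration
reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .design import CcdSpec, DesignMatrix, additional_points, generate_ccd, verification_points
from .evaluation import EvaluationReport, acceptance_bands, evaluate_predictions, section_sd
from .io import ensure_dir, write_design, write_labels, write_profiles
from .ml import (
    ClassifierModel,
    GridPrediction,
    GridSpec,
    RfModel,
    RfParams,
    SusceptibilityMap,
    build_training_table,
    default_grid_spec,
    fit_classifier,
    fit_rf,
    grid_frame,
    predict_profile,
    simulate_grid,
    susceptibility_map,
)
from .protocol import ClassLabel, DissolutionProfile
from .rsm import RsmModel, fit_rsm, predict_rsm, significance_table
from .simulator import CapsuleParams, simulate_dataset

#: Offset separating the forest's seed stream from the simulator's.
_RF_SEED_OFFSET = 7919


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one workflow run."""

    ccd: CcdSpec = field(default_factory=CcdSpec)
    simulator: CapsuleParams = field(default_factory=CapsuleParams)
    rf: RfParams = field(default_factory=lambda: RfParams(n_trees=300))
    ridge: float = 1e-8
    classifier_max_iter: int = 200
    cv_folds: int | None = 10
    grid_enabled: bool = True
    map_pressure_step: float = 10.0
    map_timing_step: float = 0.5
    seed: int = 1
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples -> lists happen in YAML anyway; normalize here for equality
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        ccd = d.get("ccd", {})
        ccd = CcdSpec(
            center=tuple(ccd.get("center", (150.0, 12.0))),
            factorial_offset=tuple(ccd.get("factorial_offset", (50.0, 3.0))),
            axial_offset=tuple(ccd.get("axial_offset", (70.0, 4.0))),
            n_center_replicates=ccd.get("n_center_replicates", 5),
        )
        sim = CapsuleParams(**d.get("simulator", {}))
        rf = RfParams(**d.get("rf", {}))
        rest = {
            k: d[k]
            for k in (
                "ridge",
                "classifier_max_iter",
                "cv_folds",
                "grid_enabled",
                "map_pressure_step",
                "map_timing_step",
                "seed",
                "outdir",
            )
            if k in d
        }
        return cls(ccd=ccd, simulator=sim, rf=rf, **rest)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True, eq=False)
class PipelineResult:
    config: RunConfig
    basic: DesignMatrix
    additional: DesignMatrix
    verification: DesignMatrix
    profiles: list[DissolutionProfile]
    labels: list[ClassLabel]
    rsm: RsmModel
    classifier: ClassifierModel
    rf: RfModel
    rsm_predictions: list[DissolutionProfile]
    ml_predictions: list[DissolutionProfile]
    rsm_report: EvaluationReport
    ml_report: EvaluationReport
    grid: list[GridPrediction] | None
    smap: SusceptibilityMap | None


def run_pipeline(config: RunConfig = RunConfig()) -> PipelineResult:
    """Execute the full workflow and (if `config.outdir` is set) write every
    intermediate artifact plus a run log."""
    basic = generate_ccd(config.ccd)
    additional = additional_points()
    verification = verification_points()
    design_all = basic.concat(additional).concat(verification)

    sim_params = replace(config.simulator, seed=config.seed)
    profiles, labels = simulate_dataset(design_all, sim_params)
    by_id = {p.test_id: p for p in profiles}
    lab_by_id = {l.test_id: l for l in labels}

    basic_profiles = [by_id[r.test_id] for r in basic]
    rsm = fit_rsm(basic_profiles, basic)

    train_design = basic.concat(additional)
    train_labels = [lab_by_id[r.test_id] for r in train_design]
    classifier = fit_classifier(
        train_design, train_labels, ridge=config.ridge, max_iter=config.classifier_max_iter
    )
    table = build_training_table(
        [by_id[r.test_id] for r in train_design], train_labels, train_design
    )
    rf_params = replace(config.rf, seed=config.seed + _RF_SEED_OFFSET)
    rf = fit_rf(table, rf_params, cv_folds=config.cv_folds)

    rsm_predictions = [
        predict_rsm(rsm, r.stress.pressure, r.stress.timing, test_id=r.test_id)
        for r in verification
    ]
    ml_predictions = [
        predict_profile(
            classifier, rf, r.stress.pressure, r.stress.timing,
            sampling_times=r.sampling_times, test_id=r.test_id,
        )[0]
        for r in verification
    ]

    cp, ct = config.ccd.center
    center_ids = [
        r.test_id for r in basic if (r.stress.pressure, r.stress.timing) == (cp, ct)
    ]
    sds = section_sd([by_id[i] for i in center_ids], is_timing=ct, ge_time=basic[0].ge_time)
    observed = [by_id[r.test_id] for r in verification]
    bands = {
        r.test_id: acceptance_bands(by_id[r.test_id], sds, r.stress.timing, r.ge_time)
        for r in verification
    }
    rsm_report = evaluate_predictions(rsm_predictions, observed, bands)
    ml_report = evaluate_predictions(ml_predictions, observed, bands)

    grid = smap = None
    if config.grid_enabled:
        grid = simulate_grid(classifier, rf, default_grid_spec())
        n_p = int(round((220 - 80) / config.map_pressure_step)) + 1
        n_t = int(round((16 - 8) / config.map_timing_step)) + 1
        pressures = [80 + config.map_pressure_step * k for k in range(n_p)]
        timings = [8 + config.map_timing_step * k for k in range(n_t)]
        smap = susceptibility_map(classifier, pressures, timings)

    result = PipelineResult(
        config, basic, additional, verification, profiles, labels, rsm, classifier,
        rf, rsm_predictions, ml_predictions, rsm_report, ml_report, grid, smap,
    )
    if config.outdir is not None:
        _write_artifacts(result)
    return result


def _write_artifacts(result: PipelineResult) -> None:
    out = ensure_dir(result.config.outdir)
    cfg = result.config
    design_all = result.basic.concat(result.additional).concat(result.verification)
    write_design(design_all, out / "design.csv")
    write_profiles(result.profiles, out / "profiles.csv")
    write_labels(result.labels, out / "labels.json")
    result.rsm.to_json(out / "rsm_model.json")
    significance_table(result.rsm).to_csv(out / "rsm_significance.csv", index=False)
    result.classifier.to_json(out / "classifier.json")
    if result.rf.cv_report is not None:
        with open(out / "rf_cv.json", "w") as fh:
            json.dump(
                {
                    "mae": result.rf.cv_report.mae,
                    "rmse": result.rf.cv_report.rmse,
                    "n_folds": result.rf.cv_report.n_folds,
                },
                fh,
                indent=1,
            )
    write_profiles(result.rsm_predictions, out / "predicted_rsm.csv")
    write_profiles(result.ml_predictions, out / "predicted_ml.csv")
    result.rsm_report.to_json(out / "evaluation_rsm.json")
    result.ml_report.to_json(out / "evaluation_ml.json")
    if result.grid is not None:
        grid_frame(result.grid).to_csv(out / "grid_profiles.csv", index=False)
    if result.smap is not None:
        result.smap.to_frame().to_csv(out / "susceptibility_map.csv", index=False)
    cfg.to_yaml(out / "config.yaml")
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "package_version": __version__,
                "master_seed": cfg.seed,
                "simulator_seed": cfg.seed,
                "rf_seed": cfg.seed + _RF_SEED_OFFSET,
                "label_source": "simulated ground truth",
                "n_runs": len(design_all),
            },
            fh,
            indent=1,
        )


def workflow_replicate(seed: int, n_trees: int = 300,
                       simulator: CapsuleParams | None = None) -> dict[str, float]:
    """One seeded replicate of the full compare-the-two-models workflow;
    returns pooled verification metrics for both models."""
    config = RunConfig(
        simulator=simulator if simulator is not None else CapsuleParams(),
        rf=RfParams(n_trees=n_trees),
        cv_folds=None,
        grid_enabled=False,
        seed=int(seed),
    )
    res = run_pipeline(config)
    return {
        "rsm_mae": res.rsm_report.mae,
        "ml_mae": res.ml_report.mae,
        "rsm_rmse": res.rsm_report.rmse,
        "ml_rmse": res.ml_report.rmse,
        "rsm_outside": res.rsm_report.outside_fraction,
        "ml_outside": res.ml_report.outside_fraction,
    }
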