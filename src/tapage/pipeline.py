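"""End-to-end orchestration: simulate -> featurize -> train -> attribute -> deviate.

A :class:`RunConfig` fully determines a run; the run directory receives the
resolved configuration, every intermediate artifact (cohort CSVs, feature
matrices, model bundle, attribution maps, deviation report) and a
human-readable summary, so every number in the summary is recomputable from
the run directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import attribution as attr_mod
from . import deviation as dev_mod
from . import features as feat_mod
from . import io as io_mod
from . import model as model_mod
from . import synthetic as syn_mod

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    ``window_days`` applies to both cohorts; the per-cohort overrides exist
    only to catch configuration mistakes — healthy and patient features
    must share one accumulation window.
    """

    seed: int = 7
    window_days: int = 90
    healthy_window_days: int | None = None
    patient_window_days: int | None = None
    n_healthy: int = 120
    n_patients: int = 20
    acceleration_years: float = 8.0
    min_days: int = 7
    n_bootstrap: int = 10_000
    matching_tolerance_years: float = 2.0
    generator: dict = field(default_factory=dict)
    hyperparams: dict = field(default_factory=dict)

    def validate(self) -> None:
        hw = self.healthy_window_days or self.window_days
        pw = self.patient_window_days or self.window_days
        if hw != pw:
            raise ValueError(
                f"healthy ({hw} d) and patient ({pw} d) accumulation windows must match"
            )
        if hw not in (90, 180):
            raise ValueError(f"window_days must be 90 or 180, got {hw}")

    @property
    def resolved_window(self) -> int:
        return self.healthy_window_days or self.window_days

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1f s", name, time.time() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis and return the run directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    window = config.resolved_window

    @_stage("simulate")
    def simulate():
        healthy_cfg = syn_mod.GeneratorConfig(
            n_subjects=config.n_healthy, seed=config.seed, **config.generator
        )
        patient_cfg = syn_mod.patient_config(
            syn_mod.GeneratorConfig(n_subjects=config.n_patients, **config.generator),
            acceleration_years=config.acceleration_years,
            seed=config.seed + 1,
        )
        h_streams, h_records = syn_mod.generate_cohort(healthy_cfg)
        p_streams, p_records = syn_mod.generate_cohort(patient_cfg)
        syn_mod.write_cohort(h_streams, h_records, out / "cohort" / "healthy")
        syn_mod.write_cohort(p_streams, p_records, out / "cohort" / "patient")
        return (h_streams, h_records), (p_streams, p_records)

    @_stage("featurize")
    def featurize(h, p):
        h_streams, h_records = io_mod.apply_inclusion_filter(h[1], h[0], config.min_days)
        p_streams, p_records = io_mod.apply_inclusion_filter(p[1], p[0], config.min_days)
        feats = out / "features"
        feats.mkdir(exist_ok=True)
        h_table = feat_mod.build_feature_table(h_streams, h_records, window)
        p_table = feat_mod.build_feature_table(p_streams, p_records, window)
        h_table.to_csv(feats / "healthy_features.csv")
        p_table.to_csv(feats / "patient_features.csv")
        return h_table, p_table, h_streams, h_records

    @_stage("train")
    def train(h_table):
        folds = model_mod.make_folds(h_table, k=10, seed=config.seed)
        hp = model_mod.ModelHyperparams(**config.hyperparams)
        bundle = model_mod.train_normative(h_table, folds, hp, seed=config.seed)
        model_mod.save_bundle(bundle, out / "bundle")
        return bundle

    @_stage("attribute")
    def attribute(bundle, h_table, p_table):
        adir = out / "attribution"
        adir.mkdir(exist_ok=True)
        centers = feat_mod.grid_centers()
        for label, table, oof in (("healthy", h_table, True), ("patient", p_table, False)):
            amap = attr_mod.attribute(bundle, table, out_of_fold=oof)
            pop = attr_mod.aggregate_population(amap)
            np.savetxt(adir / f"{label}_positive.csv", pop.positive, delimiter=",")
            np.savetxt(adir / f"{label}_negative.csv", pop.negative, delimiter=",")
            pop.covariate_summary.to_csv(adir / f"{label}_covariates.csv", index=False)
            attr_mod.plot_attribution_maps(
                pop, centers, str(adir / f"{label}_maps.png"), title=f"{label} cohort"
            )

    @_stage("deviate")
    def deviate(bundle, h_table, p_table):
        healthy_oof = model_mod.predict_out_of_fold(bundle, h_table)
        healthy_oof.to_csv(out / "healthy_oof.csv", index=False)
        patient_preds = model_mod.predict_cohort(bundle, p_table)
        patient_preds.to_csv(out / "patient_predictions.csv", index=False)
        report = dev_mod.analyze_deviation(
            patient_preds,
            healthy_oof,
            window_days=window,
            n_iter=config.n_bootstrap,
            matching_tolerance_years=config.matching_tolerance_years,
            seed=config.seed,
        )
        report.to_json(out / "deviation_report.json")
        return healthy_oof, report

    h, p = simulate()
    h_table, p_table, h_streams, h_records = featurize(h, p)
    bundle = train(h_table)
    attribute(bundle, h_table, p_table)
    healthy_oof, report = deviate(bundle, h_table, p_table)

    metrics = model_mod.performance_metrics(healthy_oof)
    summary = {
        "n_healthy": len(h_table),
        "n_patients": len(p_table),
        "window_days": window,
        "healthy_ME_years": metrics["ME"],
        "healthy_MAE_years": metrics["MAE"],
        "healthy_R2": metrics["R2"],
        "patient_gap_years": report.gap_years,
        "gap_t_statistic": report.t_statistic,
        "gap_p_value": report.p_value,
        "patient_MAE_years": report.patient_mae,
        "robust_slope": report.robust_fit.slope,
        "robust_R2": report.robust_fit.r2,
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    lines = ["tapage run summary", "==================="]
    lines += [f"{k}: {v:.4g}" if isinstance(v, float) else f"{k}: {v}" for k, v in summary.items()]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    logger.info("run complete: %s", out)
    return out
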