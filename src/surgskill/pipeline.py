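"""Pipeline orchestration: simulate -> preprocess -> features -> select ->
train -> report.

Every stage writes plain-text artifacts plus a provenance record (stage
name, derived seed, configuration hash, package version) into the output
directory, so any output can be regenerated from its provenance.  Stage
seeds derive deterministically from the single global seed, so
independent stage re-runs agree with full-pipeline runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import MODEL_NAMES, SplitSpec, evaluate_muscle_sets, PRECISION_NOTE
from .emg_features import emg_features_from_envelope
from .features_table import INDEX_COLS, feature_columns
from .nonlinear import NonlinearParams, acc_feature_vector
from .preprocessing import preprocess_emg
from .selection import reduce_dimension
from .synth import CohortConfig, generate_cohort, read_dataset, write_dataset
from .types import EMGEnvelope, InvalidArgumentError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "select", "train", "report")


class MissingStageError(FileNotFoundError):
    """An upstream stage's artifacts are absent."""


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable configuration for a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    nonlinear: NonlinearParams = field(default_factory=NonlinearParams)
    selection_method: str = "cfs+rfe"
    rho_threshold: float = 0.9
    n_keep: int = 10
    train_fraction: float = 0.7
    grouping: str = "subject"
    muscle_sets: tuple[tuple[str, ...], ...] | None = None  # default: singletons
    models: tuple[str, ...] = MODEL_NAMES
    seed: int = 0

    def resolved_muscle_sets(self) -> list[tuple[str, ...]]:
        if self.muscle_sets is not None:
            return [tuple(ms) for ms in self.muscle_sets]
        return [(m,) for m in self.cohort.muscles]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=_jsonable))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .types import MovementComplexityProfile, MuscleActivationProfile

        cohort = d.get("cohort", {})
        if cohort:
            cohort = dict(cohort)
            if "activation_templates" in cohort:
                cohort["activation_templates"] = {
                    k: MuscleActivationProfile(**v)
                    for k, v in cohort["activation_templates"].items()
                }
            if "complexity_templates" in cohort:
                cohort["complexity_templates"] = {
                    k: MovementComplexityProfile(**v)
                    for k, v in cohort["complexity_templates"].items()
                }
            for key in ("tasks", "muscles", "sides", "informative_muscles"):
                if cohort.get(key) is not None:
                    cohort[key] = tuple(cohort[key])
            cohort = CohortConfig(**cohort)
        else:
            cohort = CohortConfig()
        nl = d.get("nonlinear", {})
        if nl:
            nl = dict(nl)
            if "scales" in nl:
                nl["scales"] = tuple(nl["scales"])
            if "radius_quantiles" in nl:
                nl["radius_quantiles"] = tuple(nl["radius_quantiles"])
            nl = NonlinearParams(**nl)
        else:
            nl = NonlinearParams()
        rest = {
            k: d[k]
            for k in (
                "selection_method", "rho_threshold", "n_keep", "train_fraction",
                "grouping", "seed",
            )
            if k in d
        }
        ms = d.get("muscle_sets")
        if ms is not None:
            ms = tuple(tuple(x) for x in ms)
        models = tuple(d.get("models", MODEL_NAMES))
        return cls(cohort=cohort, nonlinear=nl, muscle_sets=ms, models=models, **rest)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of '<seed>:<stage>' mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_provenance(out_dir: Path, stage: str, config: PipelineConfig) -> None:
    record = {
        "stage": stage,
        "seed": stage_seed(config.seed, stage),
        "global_seed": config.seed,
        "config_hash": config_hash(config),
        "version": __version__,
    }
    with open(out_dir / f"{stage}_provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise MissingStageError(
            f"stage '{needed_by}' requires artifacts of stage '{stage}' "
            f"(missing: {path}); run '{stage}' first"
        )
    return path


# -- stages ---------------------------------------------------------------


def run_simulate(config: PipelineConfig, out_dir: Path) -> Path:
    cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, "simulate"))
    recordings = generate_cohort(cohort_cfg)
    dataset_dir = out_dir / "dataset"
    write_dataset(recordings, dataset_dir)
    logger.info("simulate: wrote %d recordings to %s", len(recordings), dataset_dir)
    return dataset_dir


def run_preprocess(config: PipelineConfig, out_dir: Path) -> Path:
    dataset_dir = _require(out_dir / "dataset", "simulate", "preprocess")
    recordings = read_dataset(dataset_dir)
    env_dir = out_dir / "envelopes"
    env_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        env = preprocess_emg(rec.emg, rec.mvc_value)
        base = preprocess_emg(rec.baseline_emg, rec.mvc_value)
        stem = f"{rec.subject_id}_{rec.task}_{rec.trial}_{rec.muscle}_{rec.side}"
        pd.DataFrame({"time_s": env.times, "envelope_mvc": env.samples}).to_csv(
            env_dir / f"{stem}_envelope.csv", index=False, float_format="%.9g"
        )
        pd.DataFrame({"time_s": base.times, "envelope_mvc": base.samples}).to_csv(
            env_dir / f"{stem}_baseline_envelope.csv", index=False, float_format="%.9g"
        )
    logger.info("preprocess: wrote envelopes for %d recordings", len(recordings))
    return env_dir


def run_features(config: PipelineConfig, out_dir: Path) -> Path:
    dataset_dir = _require(out_dir / "dataset", "simulate", "features")
    env_dir = _require(out_dir / "envelopes", "preprocess", "features")
    recordings = read_dataset(dataset_dir)
    rows = []
    for rec in recordings:
        stem = f"{rec.subject_id}_{rec.task}_{rec.trial}_{rec.muscle}_{rec.side}"
        env_df = pd.read_csv(_require(env_dir / f"{stem}_envelope.csv", "preprocess", "features"))
        base_df = pd.read_csv(env_dir / f"{stem}_baseline_envelope.csv")
        env = EMGEnvelope(env_df["envelope_mvc"].to_numpy(), rec.emg.fs,
                          provenance=("mvc_normalize:stored",))
        base = EMGEnvelope(base_df["envelope_mvc"].to_numpy(), rec.emg.fs,
                           provenance=("mvc_normalize:stored",))
        row = {
            "subject_id": rec.subject_id, "skill": rec.skill, "task": rec.task,
            "trial": rec.trial, "muscle": rec.muscle, "side": rec.side,
        }
        row.update(emg_features_from_envelope(env, base, raw_emg=rec.emg).as_dict())
        row.update(acc_feature_vector(rec, config.nonlinear))
        rows.append(row)
    table = pd.DataFrame(rows)
    path = out_dir / "features.csv"
    table.to_csv(path, index=False, float_format="%.9g")
    logger.info("features: wrote %d rows x %d columns", *table.shape)
    return path


def run_select(config: PipelineConfig, out_dir: Path) -> Path:
    features_path = _require(out_dir / "features.csv", "features", "select")
    table = pd.read_csv(features_path)
    seed = stage_seed(config.seed, "select")
    reduced, result = reduce_dimension(
        table,
        method=config.selection_method,
        rho_threshold=config.rho_threshold,
        n_keep=config.n_keep,
        seed=seed,
    )
    sel_dir = out_dir / "selection"
    sel_dir.mkdir(parents=True, exist_ok=True)
    result.report().to_csv(sel_dir / "selection_report.csv", index=False,
                           float_format="%.6g")
    with open(sel_dir / "kept_features.json", "w") as fh:
        json.dump(result.kept_features, fh, indent=2)
    if result.correlation_matrix is not None:
        result.correlation_matrix.to_csv(sel_dir / "correlation_matrix.csv",
                                         float_format="%.6g")
    if result.dropped_pairs:
        pd.DataFrame(result.dropped_pairs,
                     columns=["kept", "dropped", "abs_rho"]).to_csv(
            sel_dir / "dropped_pairs.csv", index=False, float_format="%.6g")
    return sel_dir


def run_train(config: PipelineConfig, out_dir: Path) -> Path:
    features_path = _require(out_dir / "features.csv", "features", "train")
    table = pd.read_csv(features_path)
    kept_path = out_dir / "selection" / "kept_features.json"
    if kept_path.exists():
        with open(kept_path) as fh:
            kept = json.load(fh)
        cols = [c for c in table.columns if c in INDEX_COLS or c in kept]
        table = table[cols]
    else:
        logger.info("train: no selection artifacts found, using all features")
    seed = stage_seed(config.seed, "train")
    spec = SplitSpec(train_fraction=config.train_fraction, seed=seed,
                     grouping=config.grouping)
    report = evaluate_muscle_sets(
        table, config.resolved_muscle_sets(), spec, config.models, seed=seed
    )
    train_dir = out_dir / "train"
    train_dir.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(train_dir / "metrics.csv", index=False, float_format="%.6g")
    for (set_name, model), mset in report.confusions.items():
        cm = pd.DataFrame(mset.counts.matrix, index=mset.counts.classes,
                          columns=mset.counts.classes)
        cm.to_csv(train_dir / f"confusion_{set_name}_{model}.csv")
    for (set_name, model), bundle in report.rocs.items():
        for cls, curve in (bundle or {}).items():
            if curve is None:
                continue
            pd.DataFrame({"fpr": curve["fpr"], "tpr": curve["tpr"]}).to_csv(
                train_dir / f"roc_{set_name}_{model}_{cls}.csv",
                index=False, float_format="%.6g")
    with open(train_dir / "config_echo.json", "w") as fh:
        json.dump(report.config, fh, indent=2, sort_keys=True)
    return train_dir


def run_report(config: PipelineConfig, out_dir: Path) -> Path:
    features_path = _require(out_dir / "features.csv", "features", "report")
    train_dir = _require(out_dir / "train", "train", "report")
    metrics = pd.read_csv(_require(train_dir / "metrics.csv", "train", "report"))
    table = pd.read_csv(features_path)
    report_dir = out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    # per-model accuracy table shaped muscle_set x (model metrics)
    wide = metrics.pivot_table(
        index="muscle_set", columns="model",
        values=["accuracy", "precision", "recall", "f1"], sort=True,
    )
    wide.columns = [f"{model}_{metric}" for metric, model in wide.columns]
    wide = wide.reindex(sorted(wide.columns), axis=1)
    wide.to_csv(report_dir / "report.csv", float_format="%.6g")
    summary, directions = summarize_group_differences(table)
    summary.to_csv(report_dir / "group_summary.csv", index=False, float_format="%.6g")
    if not directions.empty:
        directions.to_csv(report_dir / "group_directions.csv", index=False)
    with open(report_dir / "NOTES.txt", "w") as fh:
        fh.write(PRECISION_NOTE + "\n")
    return report_dir


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "features": run_features,
    "select": run_select,
    "train": run_train,
    "report": run_report,
}


def run_stage(stage: str, config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run one named stage, writing artifacts and provenance to out_dir."""
    if stage not in _STAGE_FUNCS:
        raise InvalidArgumentError(f"unknown stage {stage!r}; stages are {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = _STAGE_FUNCS[stage](config, out_dir)
    _write_provenance(out_dir, stage, config)
    return result


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage in order; returns the report directory."""
    out_dir = Path(out_dir)
    for stage in STAGES:
        run_stage(stage, config, out_dir)
    config.to_yaml(out_dir / "config.yaml")
    return out_dir / "report"


def summarize_group_differences(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive per-(skill, task) summaries of every feature.

    Returns ``(summary, directions)``: per-group mean/SD/n, and — when
    more than one skill group is present — the ordering of group means
    for each (feature, task), e.g. ``novice>intermediate>expert``.
    Features with no defined values are excluded with a log entry.
    """
    from .types import SKILLS

    feats = feature_columns(table)
    rows = []
    dir_rows = []
    skills_present = [s for s in SKILLS if s in set(table["skill"])]
    for feat in feats:
        if table[feat].notna().sum() == 0:
            logger.warning("feature %s has no defined values; excluded from summary", feat)
            continue
        for task in sorted(table["task"].unique()):
            sub = table[table["task"] == task]
            means = {}
            for skill in skills_present:
                vals = sub.loc[sub["skill"] == skill, feat].dropna()
                if vals.empty:
                    continue
                means[skill] = float(vals.mean())
                rows.append(
                    {
                        "feature": feat, "task": task, "skill": skill,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                        "n": int(len(vals)),
                    }
                )
            if len(means) > 1:
                order = sorted(means, key=means.get, reverse=True)
                dir_rows.append(
                    {"feature": feat, "task": task, "ordering": ">".join(order)}
                )
    return pd.DataFrame(rows), pd.DataFrame(dir_rows)
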