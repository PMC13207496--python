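"""Experiment orchestration: configuration, matrices, seeding, reports.

``run_experiment`` executes generate -> split -> task view -> partition ->
federate -> evaluate for every cell of a (task x algorithm x seed) matrix,
caching each completed cell as JSON so reruns are free. All randomness
derives from per-cell child seeds of the master seed, so adding cells never
perturbs existing ones and identical configs reproduce identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import child_seed
from .errors import ConfigurationError
from .evaluation import evaluate_predictions
from .federation import FLConfig, run_federation
from .models import (ModelSpec, cost_table, extract_features, feature_stats,
                     pool_features)
from .partition import (PartitionConfig, apply_augmentation,
                        load_reference_partition, partition_training_set,
                        summarize_partition)
from .privacy import DPConfig, budget_table
from .synthdata import (DatasetSpec, apply_split, construct_task,
                        generate_dataset, split_dataset, task_labels)

logger = logging.getLogger("fedusim")

TASK_NAMES = ("screen", "diagnose", "threeclass")

#: Column name -> allowed python types for one result record.
RESULT_SCHEMA = {
    "task": str, "algorithm": str, "model_family": str, "seed": int,
    "dp_enabled": bool, "C": float, "eta": float,
    "n_train": int, "n_test": int, "accuracy": float,
    "macro_precision": float, "macro_recall": float, "macro_f1": float,
    "eps_basic": float, "eps_sublinear": float,
}


def validate_record(record: dict) -> dict:
    """Check one result record against the published schema."""
    for key, typ in RESULT_SCHEMA.items():
        if key not in record:
            raise ConfigurationError(f"record: missing field {key!r}")
        value = record[key]
        if typ is float and isinstance(value, (int, float)):
            continue
        if not isinstance(value, typ):
            raise ConfigurationError(
                f"record: field {key!r} has type {type(value).__name__}, "
                f"expected {typ.__name__}")
    return record


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment matrix needs.

    The defaults are a desk-scale profile (N=1200 synthetic images at 64x64,
    8 non-IID clients, logistic model on 8x8 pooled features, 30 rounds) that
    runs the full 3-task x 3-algorithm matrix in minutes on one CPU. The
    emulated full-scale profile remains expressible through the same fields.
    """

    dataset: DatasetSpec = field(default_factory=DatasetSpec)
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    fl: FLConfig = field(default_factory=lambda: FLConfig(
        rounds=30, local_epochs=2, batch_size=16, client_lr=0.05,
        allow_small_client=True))
    dp: DPConfig = field(default_factory=lambda: DPConfig(enabled=False))
    model_family: str = "multinomial_logistic"
    hidden_dim: int | None = None
    pool_grid: int = 8
    init_scale: float = 0.1
    tasks: tuple = ("screen",)
    algorithms: tuple = ("fedavg",)
    seeds: tuple = (0,)
    outdir: str | None = None

    def __post_init__(self):
        if not self.seeds:
            raise ConfigurationError("seeds: list must be nonempty")
        for task in self.tasks:
            if task not in TASK_NAMES:
                raise ConfigurationError(f"tasks: unknown task {task!r}")

    def model_spec(self, n_classes: int) -> ModelSpec:
        return ModelSpec(family=self.model_family,
                         input_dim=self.pool_grid * self.pool_grid,
                         hidden_dim=self.hidden_dim, n_classes=n_classes,
                         init_scale=self.init_scale)


# ---------------------------------------------------------------------------
# Single-cell execution
# ---------------------------------------------------------------------------

def _client_features(samples_by_id, manifest, grid, stats):
    """Feature/label arrays for one client, applying its fixed augmentation."""
    X_rows, samples = [], []
    aug = manifest.augmentation_spec
    for sid in manifest.sample_ids:
        s = samples_by_id[sid]
        pixels = s.pixels if aug.is_identity else apply_augmentation(s.pixels, aug)
        X_rows.append(pool_features(pixels, grid))
        samples.append(s)
    mean, sd = stats
    return (np.stack(X_rows) - mean) / sd, samples


def run_cell(config: ExperimentConfig, task: str, algorithm: str,
             seed: int, dp: DPConfig | None = None) -> dict:
    """Run one (task, algorithm, seed) cell from scratch and return its record."""
    dp = dp if dp is not None else config.dp
    spec = replace(config.dataset, seed=child_seed(seed, "data"))
    samples = generate_dataset(spec)
    assignment = split_dataset(samples, seed=child_seed(seed, "split"))
    apply_split(samples, assignment)

    view = construct_task(samples, task)
    members = {sid: True for sid in view.sample_ids}
    train = [s for s in samples if s.split_tag == "train" and s.sample_id in members]
    test = [s for s in samples if s.split_tag == "test" and s.sample_id in members]

    X_train_all = extract_features(train, config.pool_grid)
    stats = feature_stats(X_train_all)
    Xt = extract_features(test, config.pool_grid, standardize_stats=stats)
    yt = task_labels(view, test)

    part_cfg = replace(config.partition, seed=child_seed(seed, "part"))
    manifests = partition_training_set(train, part_cfg)
    samples_by_id = {s.sample_id: s for s in train}
    train_sets = []
    for m in manifests:
        Xk, client_samples = _client_features(samples_by_id, m,
                                              config.pool_grid, stats)
        yk = task_labels(view, client_samples)
        train_sets.append((Xk, yk))

    model_spec = config.model_spec(len(view.class_names))
    fl = replace(config.fl, algorithm=algorithm,
                 seed=child_seed(seed, "fed", task, algorithm,
                                 dp.eta if dp.enabled else "off",
                                 dp.C if dp.enabled else "off"))
    result = run_federation(train_sets, (Xt, yt), model_spec, fl, dp)

    from .models import predict_proba
    pred = predict_proba(model_spec, result.weights, Xt).argmax(axis=1)
    report = evaluate_predictions(yt, pred, model_spec.n_classes)
    last = result.log.iloc[-1]
    record = {
        "task": task, "algorithm": algorithm,
        "model_family": config.model_family, "seed": int(seed),
        "dp_enabled": bool(dp.enabled),
        "C": float(dp.C) if dp.enabled else float("nan"),
        "eta": float(dp.eta) if dp.enabled else float("nan"),
        "n_train": int(sum(len(y) for _, y in train_sets)),
        "n_test": int(len(yt)),
        "accuracy": report.accuracy,
        "macro_precision": report.macro_precision,
        "macro_recall": report.macro_recall,
        "macro_f1": report.macro_f1,
        "eps_basic": float(last.get("eps_basic", float("nan"))),
        "eps_sublinear": float(last.get("eps_sublinear", float("nan"))),
    }
    return validate_record(record)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def _cell_key(task, algorithm, seed, dp: DPConfig) -> str:
    if dp.enabled:
        return f"{task}-{algorithm}-s{seed}-C{dp.C}-eta{dp.eta}"
    return f"{task}-{algorithm}-s{seed}-nodp"


def _run_matrix(config: ExperimentConfig, cells) -> pd.DataFrame:
    """Execute cells, caching each result by key under outdir/cells/."""
    cache = None
    if config.outdir is not None:
        cache = Path(config.outdir) / "cells"
        cache.mkdir(parents=True, exist_ok=True)
    records = []
    for task, algorithm, seed, dp in cells:
        key = _cell_key(task, algorithm, seed, dp)
        path = cache / f"{key}.json" if cache else None
        if path is not None and path.exists():
            records.append(json.loads(path.read_text()))
            continue
        try:
            record = run_cell(config, task, algorithm, seed, dp)
        except Exception as exc:  # record the failure, keep going
            logger.error("cell %s failed: %s", key, exc)
            continue
        if path is not None:
            path.write_text(json.dumps(record, sort_keys=True))
        records.append(record)
    frame = pd.DataFrame(records)
    if not frame.empty:
        frame = frame.sort_values(
            ["task", "algorithm", "seed", "C", "eta"]).reset_index(drop=True)
    if config.outdir is not None and not frame.empty:
        frame.to_csv(Path(config.outdir) / "results.csv", index=False)
    return frame


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """The (task x algorithm x seed) matrix with the config's DP setting."""
    cells = [(task, alg, seed, config.dp)
             for task in config.tasks
             for alg in config.algorithms
             for seed in config.seeds]
    return _run_matrix(config, cells)


def run_dp_ablation(config: ExperimentConfig, C_list, eta_list,
                    task: str = "screen") -> pd.DataFrame:
    """DP grid (clipping bound x noise multiplier), FedAvg only."""
    if not C_list or not eta_list:
        raise ConfigurationError("run_dp_ablation: empty grid")
    cells = [(task, "fedavg", seed,
              replace(config.dp, enabled=True, C=float(C), eta=float(eta)))
             for C in C_list for eta in eta_list for seed in config.seeds]
    return _run_matrix(config, cells)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def render_reports(table: pd.DataFrame, outdir: str | Path,
                   eta_list=(0.5, 1.0, 1.5, 2.0, 3.0), K: int = 8) -> list[Path]:
    """Emit the standard report files (CSV + rendered text) from a results table.

    Reports: privacy-budget table, reference partition summary, communication
    cost table, per-task metric grids, and (when DP rows exist) the
    clip x noise ablation grid. Empty subsets are skipped with a notice.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, stem: str):
        csv_path = outdir / f"{stem}.csv"
        frame.to_csv(csv_path, index=False)
        (outdir / f"{stem}.txt").write_text(frame.to_string(index=False) + "\n")
        written.append(csv_path)

    emit(budget_table(eta_list), "budget_table")
    manifests, labels = load_reference_partition()
    emit(summarize_partition(manifests, labels).table, "partition_summary")
    emit(cost_table(K), "cost_table")

    if table is None or table.empty:
        logger.info("render_reports: empty results table; metric grids skipped")
        return written
    nodp = table[~table["dp_enabled"]]
    if nodp.empty:
        logger.info("render_reports: no non-DP rows; metric grid skipped")
    else:
        grid = nodp.pivot_table(index="algorithm", columns="task",
                                values="accuracy", aggfunc="mean")
        emit(grid.reset_index(), "metric_grid")
    dp_rows = table[table["dp_enabled"]]
    if dp_rows.empty:
        logger.info("render_reports: no DP rows; ablation grid skipped")
    else:
        grid = dp_rows.pivot_table(index="C", columns="eta",
                                   values="accuracy", aggfunc="mean")
        emit(grid.reset_index(), "ablation_grid")
    return written


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config)))


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    from .partition import FeatureSkewRanges

    def tup(d, *keys):
        for k in keys:
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])

    ds = raw.pop("dataset", {})
    tup(ds, "benign_axis_range", "malignant_axis_range", "spicule_count_range")
    part = raw.pop("partition", {})
    fsr = part.pop("feature_skew_ranges", None)
    if fsr:
        tup(fsr, "brightness", "contrast", "rotation")
        part["feature_skew_ranges"] = FeatureSkewRanges(**fsr)
    fl = raw.pop("fl", {})
    tup(fl, "lr_decay_rounds")
    dp = raw.pop("dp", {})
    tup(raw, "tasks", "algorithms", "seeds")
    return ExperimentConfig(dataset=DatasetSpec(**ds),
                            partition=PartitionConfig(**part),
                            fl=FLConfig(**fl), dp=DPConfig(**dp), **raw)
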