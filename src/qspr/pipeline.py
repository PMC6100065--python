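"""End-to-end workflow: filter -> split -> descriptors -> prefilter ->
heuristic MLR -> RBFNN goal scan -> evaluation, driven by one config.

Each stage logs one structured line (shapes in, shapes out, elapsed time).
Every produced file is listed in a manifest with its SHA-256 hash, so an
identical config and seed reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from qspr.datamodel import (
    TRAIN,
    VALIDATION,
    Dataset,
    DescriptorMatrix,
    filter_by_uncertainty,
    read_compound_table,
    read_descriptor_matrix,
    split_train_validation,
    write_descriptor_matrix,
    write_split,
)
from qspr.descriptors import DescriptorConfig, build_descriptor_matrix, prefilter_descriptors
from qspr.evaluation import evaluate, report_to_dict
from qspr.mlr import HeuristicConfig, heuristic_search
from qspr.rbf import RBFTrainConfig, optimize_goal, rbf_predict
from qspr.serialize import write_model

log = logging.getLogger("qspr.pipeline")

TARGETS = ("tc", "pc", "omega")


@dataclass
class WorkflowConfig:
    """One run: input tables, the target property and stage settings."""

    compounds: str | None = None
    descriptors: str | None = None  # precomputed matrix CSV; else engine runs
    target: str = "tc"
    n_train: int = 215
    seed: int = 0
    apply_uncertainty_filter: bool = False
    max_rel_err_tc: float = 0.01
    max_rel_err_pc: float = 0.03
    descriptor_config: DescriptorConfig = field(default_factory=DescriptorConfig)
    heuristic: HeuristicConfig = field(default_factory=HeuristicConfig)
    rbf: RBFTrainConfig = field(default_factory=RBFTrainConfig)
    out_dir: str = "qspr_out"

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {self.target!r}")

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "descriptor_config" in kwargs:
            kwargs["descriptor_config"] = DescriptorConfig(**kwargs["descriptor_config"])
        if "heuristic" in kwargs:
            kwargs["heuristic"] = HeuristicConfig(**kwargs["heuristic"])
        if "rbf" in kwargs:
            kwargs["rbf"] = RBFTrainConfig(**kwargs["rbf"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            log.info("stage=%s elapsed=%.2fs", self.name, dt)
        else:
            log.error("stage=%s failed after %.2fs: %s", self.name, dt, exc)
        return False


def run_workflow(
    cfg: WorkflowConfig,
    dataset: Dataset | None = None,
    descriptor_matrix: DescriptorMatrix | None = None,
    y=None,
) -> dict:
    """Execute the full workflow; returns the artifact manifest.

    Inputs may be passed in memory (``dataset``/``descriptor_matrix``/``y``)
    or read from the paths in the config.  ``y`` overrides the target
    column of the compound table (used by synthetic workflows).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    with _Stage("load"):
        if dataset is None and cfg.compounds is not None:
            dataset = read_compound_table(cfg.compounds)
        if descriptor_matrix is None:
            if cfg.descriptors is not None:
                descriptor_matrix = read_descriptor_matrix(cfg.descriptors)
            elif dataset is not None:
                with _Stage("descriptor-engine"):
                    descriptor_matrix = build_descriptor_matrix(dataset, cfg.descriptor_config)
        if descriptor_matrix is None:
            raise ValueError("no descriptor source: give descriptors, compounds or a matrix")

    if dataset is not None and cfg.apply_uncertainty_filter:
        with _Stage("uncertainty-filter"):
            n0 = len(dataset)
            dataset = filter_by_uncertainty(dataset, cfg.max_rel_err_tc, cfg.max_rel_err_pc)
            log.info("uncertainty filter kept %d/%d", len(dataset), n0)
            descriptor_matrix = descriptor_matrix.rows(dataset.ids)

    ids = descriptor_matrix.compound_ids
    if y is None:
        if dataset is None:
            raise ValueError("no property source: give y or a compound table")
        y_series = dataset.property_vector(cfg.target)
        if y_series.isna().any():
            keep = [i for i in ids if not np.isnan(y_series[i])]
            descriptor_matrix = descriptor_matrix.rows(keep)
            ids = keep
        y = y_series.loc[ids].to_numpy()
    else:
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(ids):
            raise ValueError("y length does not match descriptor matrix rows")

    with _Stage("prefilter"):
        filtered, dropped = prefilter_descriptors(descriptor_matrix)
        log.info(
            "prefilter kept %d/%d descriptors",
            len(filtered.descriptor_names),
            len(descriptor_matrix.descriptor_names),
        )
        files["descriptors_prefiltered"] = out / "descriptors_prefiltered.csv"
        write_descriptor_matrix(filtered, files["descriptors_prefiltered"])

    with _Stage("split"):
        if dataset is None:
            from qspr.datamodel import CompoundRecord

            dataset = Dataset(records=[CompoundRecord(id=i) for i in ids])
        dataset = split_train_validation(dataset, cfg.n_train, cfg.seed)
        files["split"] = out / "split.json"
        write_split(dataset, files["split"])
        role_by_id = {rec.id: role for rec, role in zip(dataset.records, dataset.roles)}
        train_ids = [i for i in ids if role_by_id[i] == TRAIN]
        val_ids = [i for i in ids if role_by_id[i] == VALIDATION]
        y_by_id = dict(zip(ids, y))

    Xtr = filtered.rows(train_ids).values
    Xval = filtered.rows(val_ids).values
    ytr = np.array([y_by_id[i] for i in train_ids])
    yval = np.array([y_by_id[i] for i in val_ids])

    with _Stage("heuristic-mlr"):
        train_matrix = filtered.rows(train_ids)
        mlr_model, trace = heuristic_search(train_matrix, ytr, cfg.heuristic)
        log.info(
            "mlr selected %d descriptors, R2=%.4f", len(mlr_model.descriptor_names), mlr_model.r2
        )
        files["mlr_model"] = out / "mlr_model.json"
        write_model(mlr_model, files["mlr_model"])
        files["mlr_trace"] = out / "mlr_trace.json"
        with open(files["mlr_trace"], "w") as fh:
            json.dump(
                {
                    "seeds": trace.seeds,
                    "eliminated": trace.eliminated,
                    "per_size": {str(k): v for k, v in trace.per_size.items()},
                    "best_by_r2": trace.best_by_r2,
                    "best_by_f": trace.best_by_f,
                },
                fh,
                indent=1,
            )

    sel = mlr_model.descriptor_names
    Xtr_sel = filtered.rows(train_ids).select(sel).values
    Xval_sel = filtered.rows(val_ids).select(sel).values

    with _Stage("rbfnn"):
        net, chosen_goal, goal_report = optimize_goal(Xtr_sel, ytr, Xval_sel, yval, cfg.rbf)
        log.info("rbfnn chose goal=%.3g with %d neurons", chosen_goal, net.n_neurons)
        files["rbfnn_model"] = out / "rbfnn_model.json"
        write_model(net, files["rbfnn_model"])
        files["goal_scan"] = out / "goal_scan.json"
        with open(files["goal_scan"], "w") as fh:
            json.dump({"chosen_goal": chosen_goal, "scan": goal_report}, fh, indent=1)

    with _Stage("evaluate"):
        reports = {}
        for label, model_pred_tr, model_pred_val in (
            ("mlr", mlr_model.predict(Xtr_sel), mlr_model.predict(Xval_sel)),
            ("rbfnn", rbf_predict(net, Xtr_sel), rbf_predict(net, Xval_sel)),
        ):
            rep_tr = evaluate(model_pred_tr, ytr, ids=train_ids, roles=[TRAIN] * len(train_ids))
            rep_val = evaluate(model_pred_val, yval, ids=val_ids, roles=[VALIDATION] * len(val_ids))
            reports[label] = {"train": rep_tr, "validation": rep_val}
            files[f"{label}_report"] = out / f"{label}_report.json"
            with open(files[f"{label}_report"], "w") as fh:
                json.dump(
                    {"train": report_to_dict(rep_tr), "validation": report_to_dict(rep_val)},
                    fh,
                    indent=1,
                )
            files[f"{label}_parity"] = out / f"{label}_parity.csv"
            combined = pd.concat([rep_tr.per_compound, rep_val.per_compound], ignore_index=True)
            combined[["id", "experimental", "predicted", "role"]].to_csv(
                files[f"{label}_parity"], index=False
            )

    manifest = {
        "target": cfg.target,
        "seed": cfg.seed,
        "n_train": len(train_ids),
        "n_validation": len(val_ids),
        "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(files.items())},
        "summary": {
            label: {
                split: {
                    "aad_percent": reports[label][split].aad_percent,
                    "rmse": reports[label][split].rmse,
                }
                for split in ("train", "validation")
            }
            for label in reports
        },
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
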