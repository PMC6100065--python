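"""JSON serialization of fitted models.

Schema: ``{"schema_version": 1, "model_type": "mlr"|"rbfnn", "payload": ...}``.
Floats round-trip exactly (Python's JSON writer emits shortest-repr doubles),
so a reloaded model reproduces predictions bit-for-bit.
"""

from __future__ import annotations

import json

import numpy as np

from qspr.mlr import MLRModel
from qspr.rbf import RBFNetwork

SCHEMA_VERSION = 1


def _mlr_payload(m: MLRModel) -> dict:
    return {
        "descriptor_names": m.descriptor_names,
        "intercept": m.intercept,
        "coefficients": m.coefficients.tolist(),
        "r2": m.r2,
        "f_stat": m.f_stat,
        "t_stats": m.t_stats.tolist(),
        "se_coefficients": m.se_coefficients.tolist(),
        "rmse_train": m.rmse_train,
        "n_train": m.n_train,
    }


def _rbf_payload(net: RBFNetwork) -> dict:
    return {
        "centers": net.centers.tolist(),
        "widths": net.widths.tolist(),
        "output_weights": net.output_weights.tolist(),
        "output_bias": net.output_bias,
        "input_means": net.input_means.tolist(),
        "input_scales": net.input_scales.tolist(),
        "target_mean": net.target_mean,
        "target_scale": net.target_scale,
    }


def write_model(model, path) -> None:
    if isinstance(model, MLRModel):
        doc = {"schema_version": SCHEMA_VERSION, "model_type": "mlr", "payload": _mlr_payload(model)}
    elif isinstance(model, RBFNetwork):
        doc = {"schema_version": SCHEMA_VERSION, "model_type": "rbfnn", "payload": _rbf_payload(model)}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model(path):
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "schema_version" not in doc or "model_type" not in doc:
        raise ValueError(f"{path}: not a model file (missing schema tag)")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {doc['schema_version']} unsupported (expected {SCHEMA_VERSION})"
        )
    p = doc["payload"]
    if doc["model_type"] == "mlr":
        return MLRModel(
            descriptor_names=list(p["descriptor_names"]),
            intercept=float(p["intercept"]),
            coefficients=np.array(p["coefficients"], dtype=float),
            r2=float(p["r2"]),
            f_stat=float(p["f_stat"]),
            t_stats=np.array(p["t_stats"], dtype=float),
            se_coefficients=np.array(p["se_coefficients"], dtype=float),
            rmse_train=float(p["rmse_train"]),
            n_train=int(p["n_train"]),
        )
    if doc["model_type"] == "rbfnn":
        return RBFNetwork(
            centers=np.array(p["centers"], dtype=float),
            widths=np.array(p["widths"], dtype=float),
            output_weights=np.array(p["output_weights"], dtype=float),
            output_bias=float(p["output_bias"]),
            input_means=np.array(p["input_means"], dtype=float),
            input_scales=np.array(p["input_scales"], dtype=float),
            target_mean=float(p["target_mean"]),
            target_scale=float(p["target_scale"]),
        )
    raise ValueError(f"{path}: unknown model_type {doc['model_type']!r}")
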