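"""Plain-text input/output: trajectory tables, state sequences, configs.

All tables are tab-separated UTF-8 with LF line endings and '.' decimal
separators; floats are printed with 6 significant digits so repeated runs
diff bit-stably.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierThresholds, StateSequence
from .synthetic import (
    TRAJECTORY_COLUMNS,
    EmissionParams,
    GeneratorConfig,
    PathSegment,
    StatePath,
    TruncatedDist,
)

__all__ = [
    "write_tsv",
    "read_trajectory",
    "write_trajectory",
    "write_state_path",
    "read_state_path",
    "write_labeled_trajectory",
    "load_generator_config",
    "dump_generator_config",
    "file_digest",
    "write_json",
]

FLOAT_FORMAT = "%.6g"


def write_tsv(df: pd.DataFrame, path, float_format: str = FLOAT_FORMAT) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format, lineterminator="\n")
    return path


def write_trajectory(df: pd.DataFrame, path) -> Path:
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table lacks columns {sorted(missing)}")
    return write_tsv(df[TRAJECTORY_COLUMNS], path)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_state_path(path_obj: StatePath, path) -> Path:
    # ground truth needs more digits than report tables: dwells are ps-scale
    # offsets on a microsecond axis
    return write_tsv(path_obj.to_frame(), path, float_format="%.12g")


def read_state_path(path) -> StatePath:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    segments = []
    t = 0.0  # rebuild starts cumulatively so contiguity is exact after rounding
    for row in df.itertuples():
        segments.append(
            PathSegment(
                state=row.state,
                start_ns=t,
                duration_ns=float(row.duration_ns),
                origin=row.origin or None,
                destination=row.destination or None,
            )
        )
        t += float(row.duration_ns)
    return StatePath(segments, t)


def write_labeled_trajectory(df: pd.DataFrame, seq: StateSequence, path) -> Path:
    """Feature table with the per-frame state label appended."""
    if len(df) != seq.n_frames:
        raise ValueError("label count does not match frame count")
    out = df.copy()
    out["state"] = seq.labels
    return write_tsv(out, path)


def _dist_to_dict(d: TruncatedDist) -> dict:
    return {k: v for k, v in dataclasses.asdict(d).items() if v is not None}


def dump_generator_config(config: GeneratorConfig, path) -> Path:
    """Write the full generator configuration as nested YAML."""
    data = {
        "temperatures_K": list(config.temperatures_K),
        "dH_kcal_mol": config.dH_kcal_mol,
        "dS_eu": config.dS_eu,
        "tau_assoc_ref_ns": config.tau_assoc_ref_ns,
        "T_ref_K": config.T_ref_K,
        "assoc_lifetime_activation": config.assoc_lifetime_activation,
        "tau_tp_ns": config.tau_tp_ns,
        "p_fail": config.p_fail,
        "frame_dt_ps": config.frame_dt_ps,
        "total_time_ns": config.total_time_ns,
        "seed": config.seed,
        "emission": {
            f.name: {
                state: _dist_to_dict(dist)
                for state, dist in getattr(config.emission, f.name).items()
            }
            for f in dataclasses.fields(config.emission)
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
    return path


def load_generator_config(path) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    emission = data.pop("emission", None)
    if emission is not None:
        data["emission"] = EmissionParams(
            **{
                feat: {state: TruncatedDist(**dist) for state, dist in dists.items()}
                for feat, dists in emission.items()
            }
        )
    if "temperatures_K" in data:
        data["temperatures_K"] = tuple(data["temperatures_K"])
    return GeneratorConfig(**data)


def load_thresholds(data: dict | None) -> ClassifierThresholds:
    if not data:
        return ClassifierThresholds()
    if "zeta_closed" in data:
        data = dict(data)
        data["zeta_closed"] = tuple(data["zeta_closed"])
        data["zeta_open"] = tuple(data["zeta_open"])
    return ClassifierThresholds(**data)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
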