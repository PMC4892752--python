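"""Cohort table and configuration I/O, plus the run manifest.

CSV is canonical (TSV accepted, decimal-comma dialects supported); the
missing-value tokens '', '-', '–' and 'NA' all parse as missing, matching
the convention of clinical score tables where a dash marks a test not
performed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .battery import TASK_IDS
from .cohort import CohortConfig, TaskModel

__all__ = ["read_cohort", "write_cohort", "load_config", "validate_config",
           "config_hash", "RunManifest", "MISSING_TOKENS"]

MISSING_TOKENS = ["", "-", "–", "NA", "NaN"]

REQUIRED_COLUMNS = ("subject_id", "group")
VALID_GROUPS = {"control", "SV", "NFV", "LV"}


def read_cohort(path, sep: str | None = None, decimal: str = ".") -> pd.DataFrame:
    """Read a cohort table from delimited text.

    Separator is sniffed from the extension unless given ('.tsv' -> tab).
    Outcome columns are validated as numeric; a non-numeric cell raises
    with its row index. Unknown columns are preserved.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, decimal=decimal, na_values=MISSING_TOKENS,
                     keep_default_na=True)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file missing required column {col!r}")
    bad_groups = set(df["group"].dropna()) - VALID_GROUPS
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    for task in TASK_IDS:
        if task not in df.columns:
            continue
        coerced = pd.to_numeric(df[task], errors="coerce")
        newly_bad = coerced.isna() & df[task].notna()
        if newly_bad.any():
            row = int(np.where(newly_bad)[0][0])
            raise ValueError(
                f"non-numeric value {df[task].iloc[row]!r} in column {task!r}, row {row}")
        df[task] = coerced
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def validate_config(obj: dict) -> list[str]:
    """Validate a JSON run configuration; returns error messages with
    JSON-pointer-style paths (empty list when valid)."""
    errors = []
    if not isinstance(obj, dict):
        return ["/: configuration must be a JSON object"]
    known = {"n_controls", "subgroups", "task_models", "deficit_profiles",
             "latent_shifts", "cpm_p2_corr", "sequence_f2_coupling",
             "observer_slope", "observer_slope_fixed", "observer_lapse",
             "age_mean_controls", "age_mean_patients", "age_sd", "seed"}
    for key in obj:
        if key not in known:
            errors.append(f"/{key}: unknown configuration key")
    if "n_controls" in obj and (not isinstance(obj["n_controls"], int)
                                or obj["n_controls"] < 0):
        errors.append("/n_controls: must be a non-negative integer")
    if "subgroups" in obj:
        if not isinstance(obj["subgroups"], dict):
            errors.append("/subgroups: must be an object of group -> size")
        else:
            for g, v in obj["subgroups"].items():
                if g not in VALID_GROUPS - {"control"}:
                    errors.append(f"/subgroups/{g}: unknown subtype")
                elif not isinstance(v, int) or v < 0:
                    errors.append(f"/subgroups/{g}: size must be a non-negative integer")
    if "task_models" in obj:
        if not isinstance(obj["task_models"], dict):
            errors.append("/task_models: must be an object of task -> model")
        else:
            for t, m in obj["task_models"].items():
                if t not in TASK_IDS:
                    errors.append(f"/task_models/{t}: unknown task id")
                elif not (isinstance(m, dict) and {"loc", "scale", "log"} <= set(m)):
                    errors.append(f"/task_models/{t}: needs loc, scale, log")
    if "cpm_p2_corr" in obj:
        v = obj["cpm_p2_corr"]
        if not isinstance(v, (int, float)) or not -1 < v < 1:
            errors.append("/cpm_p2_corr: must be a number in (-1, 1)")
    for key in ("observer_slope", "observer_slope_fixed"):
        if key in obj and (not isinstance(obj[key], (int, float)) or obj[key] <= 0):
            errors.append(f"/{key}: must be a positive number")
    if "observer_lapse" in obj:
        v = obj["observer_lapse"]
        if not isinstance(v, (int, float)) or not 0 <= v <= 0.1:
            errors.append("/observer_lapse: must lie in [0, 0.1]")
    return errors


def load_config(path) -> tuple[CohortConfig, int | None]:
    """Load and validate a JSON config; returns (CohortConfig, seed|None)."""
    with open(path) as fh:
        obj = json.load(fh)
    errors = validate_config(obj)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    seed = obj.pop("seed", None)
    if "task_models" in obj:
        base = CohortConfig().task_models
        base.update({t: TaskModel(**m) for t, m in obj["task_models"].items()})
        obj["task_models"] = base
    if "latent_shifts" in obj:
        obj["latent_shifts"] = {g: tuple(v) for g, v in obj["latent_shifts"].items()}
    return CohortConfig(**obj), seed


def config_hash(config: CohortConfig | dict) -> str:
    """Stable SHA-256 of a configuration (canonical JSON)."""
    obj = asdict(config) if is_dataclass(config) else config
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


class RunManifest:
    """Self-describing record of one pipeline run."""

    def __init__(self, config, seed: int):
        from . import __version__

        self.data = {
            "config_hash": config_hash(config),
            "seed": int(seed),
            "software_version": __version__,
            "stages": [],
            "outputs": [],
        }

    def add_stage(self, name: str, **info) -> None:
        self.data["stages"].append({"name": name, "timestamp": time.strftime(
            "%Y-%m-%dT%H:%M:%S"), **info})

    def add_output(self, path) -> None:
        self.data["outputs"].append(str(path))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2)
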