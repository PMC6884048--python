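"""Table schemas, loading/validation, and report serialization.

``admissions.csv`` carries one row per ICU episode (identifiers, covariates,
ventilation interval pairs, exclusion flags, length of stay, ICU death);
``blood_gas.csv`` is the long table of arterial samples (episode_id, t_h,
pao2_kpa, hours since ICU admission).  Loading validates the schema
(missing required columns are a hard error naming the column) and collects
row-level failures — non-numeric or non-positive PaO2, negative or
non-numeric times — into a rejects report while valid rows proceed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import REQUIRED_ADMISSION_COLUMNS, SchemaError

BLOOD_GAS_COLUMNS = ("episode_id", "t_h", "pao2_kpa")


@dataclass
class RejectsReport:
    """Row-level validation failures collected during loading."""

    admissions: pd.DataFrame = field(default_factory=pd.DataFrame)
    blood_gas: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n(self) -> int:
        return len(self.admissions) + len(self.blood_gas)


def load_tables(
    admissions_path: str | Path, blood_gas_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, RejectsReport]:
    """Load and validate the two input tables.

    Returns ``(admissions, blood_gas, rejects)``; rows failing row-level
    validation are moved to the rejects report with a ``reject_reason``
    column rather than aborting the run.
    """
    admissions = pd.read_csv(admissions_path)
    blood_gas = pd.read_csv(blood_gas_path)

    missing = [c for c in REQUIRED_ADMISSION_COLUMNS if c not in admissions]
    if missing:
        raise SchemaError(f"admissions table missing columns: {missing}")
    missing = [c for c in BLOOD_GAS_COLUMNS if c not in blood_gas]
    if missing:
        raise SchemaError(f"blood_gas table missing columns: {missing}")

    rejects = RejectsReport()

    for col in ("los_h", "age_years", "weight_kg", "apache_ii"):
        admissions[col] = pd.to_numeric(admissions[col], errors="coerce")
    bad_adm = admissions["los_h"].isna() | (admissions["los_h"] <= 0)
    if bad_adm.any():
        rej = admissions.loc[bad_adm].copy()
        rej["reject_reason"] = "invalid los_h"
        rejects.admissions = rej
        admissions = admissions.loc[~bad_adm].reset_index(drop=True)

    t = pd.to_numeric(blood_gas["t_h"], errors="coerce")
    p = pd.to_numeric(blood_gas["pao2_kpa"], errors="coerce")
    bad_bg = t.isna() | (t < 0) | p.isna() | (p <= 0)
    if bad_bg.any():
        rej = blood_gas.loc[bad_bg].copy()
        rej["reject_reason"] = np.where(
            p.isna() | (p <= 0), "invalid pao2_kpa", "invalid t_h"
        )[bad_bg]
        rejects.blood_gas = rej
    blood_gas = blood_gas.loc[~bad_bg].reset_index(drop=True)
    blood_gas["t_h"] = t[~bad_bg].to_numpy()
    blood_gas["pao2_kpa"] = p[~bad_bg].to_numpy()
    blood_gas = blood_gas.sort_values(
        ["episode_id", "t_h"], kind="mergesort"
    ).reset_index(drop=True)

    return admissions, blood_gas, rejects


def write_tables(
    admissions: pd.DataFrame,
    blood_gas: pd.DataFrame,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ap = out / "admissions.csv"
    bp = out / "blood_gas.csv"
    admissions.to_csv(ap, index=False)
    blood_gas.to_csv(bp, index=False)
    return ap, bp


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
    return path


def load_config_file(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline/generator config mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError("config file must contain a mapping")
    return data
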