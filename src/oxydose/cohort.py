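"""Cohort construction: exclusions, window covariates, nested subsets.

Inclusion requires an adult (>=18 y) index ICU admission with a stay
strictly longer than 24 h, no treatment-limitation order, no CPR in the 24 h
before admission, passing data-quality checks, and complete model
covariates (complete-case analysis).  Episodes are then nested into
progressively longer potential-exposure windows (default 24/72/120/168 h),
each subset restricted to stays of at least the window length so the
exposure period is free of informative censoring by discharge or death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import (
    DEFAULT_GAP_LIMIT_H,
    DEFAULT_THRESHOLD_KPA,
    DEFAULT_WINDOWS_H,
    compute_exposure_table,
)

#: covariates that must be non-missing for the complete-case analysis
MODEL_COVARIATES = (
    "age_years",
    "weight_kg",
    "sex",
    "apache_ii",
    "respiratory_dx",
    "prior_dependency",
    "patient_type",
)

REQUIRED_ADMISSION_COLUMNS = (
    "patient_id",
    "episode_id",
    "admission_seq",
    "los_h",
    "icu_death",
    "treatment_limitation",
    "cpr_pre_24h",
    "qc_fail",
) + MODEL_COVARIATES

#: CONSORT-style attribution order: each episode is counted against the
#: first criterion it fails.
EXCLUSION_ORDER = (
    "age_under_18",
    "los_24h_or_less",
    "treatment_limitation",
    "cpr_pre_24h",
    "qc_fail",
    "readmission",
    "missing_covariate",
)


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


@dataclass
class NestedCohort:
    """One censoring-free exposure-window subset with its exposure summary."""

    window_h: float
    table: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.table)


def apply_exclusions(
    admissions: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter admissions to the analysis cohort; log per-criterion counts.

    Returns ``(cohort, log)`` where ``log`` maps each criterion to the
    number of episodes it removed (first-matching attribution) plus
    ``input`` and ``retained`` totals, so counts always partition:
    ``input == retained + sum(exclusions)``.
    """
    missing_cols = [c for c in REQUIRED_ADMISSION_COLUMNS if c not in admissions]
    if missing_cols:
        raise SchemaError(f"admissions table missing columns: {missing_cols}")

    df = admissions
    fails = {
        "age_under_18": df["age_years"] < 18,
        "los_24h_or_less": df["los_h"] <= 24.0,  # inclusion needs a stay > 24 h
        "treatment_limitation": df["treatment_limitation"].astype(bool),
        "cpr_pre_24h": df["cpr_pre_24h"].astype(bool),
        "qc_fail": df["qc_fail"].astype(bool),
        "readmission": df["admission_seq"] != 1,
        "missing_covariate": df[list(MODEL_COVARIATES)].isna().any(axis=1),
    }
    log: dict[str, int] = {"input": len(df)}
    removed = np.zeros(len(df), dtype=bool)
    for crit in EXCLUSION_ORDER:
        hit = np.asarray(fails[crit].fillna(True)) & ~removed
        log[crit] = int(hit.sum())
        removed |= hit
    cohort = df.loc[~removed].reset_index(drop=True)
    log["retained"] = len(cohort)
    return cohort, log


def merge_intervals(
    intervals: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Union of closed intervals; touching endpoints merge."""
    ivs = sorted((float(a), float(b)) for a, b in intervals if b > a)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def derive_window_covariables(
    ventilation_intervals: list[tuple[float, float]], window_h: float
) -> dict[str, bool]:
    """Window covariates from raw ventilation intervals.

    ``continuous_mv`` is true iff the closed-interval union of ventilation
    episodes covers [0, window_h] with no interior gap.
    """
    merged = merge_intervals(ventilation_intervals)
    covered = any(a <= 0.0 and b >= window_h for a, b in merged)
    return {"continuous_mv": covered}


def _ventilation_intervals(row: pd.Series) -> list[tuple[float, float]]:
    out = []
    for k in (1, 2):
        a, b = row.get(f"vent_{k}_start_h"), row.get(f"vent_{k}_end_h")
        if a is not None and b is not None and pd.notna(a) and pd.notna(b):
            out.append((float(a), float(b)))
    return out


def _continuous_mv_column(cohort: pd.DataFrame, window_h: float) -> np.ndarray:
    v1s = cohort.get("vent_1_start_h", pd.Series(np.nan, index=cohort.index))
    v1e = cohort.get("vent_1_end_h", pd.Series(np.nan, index=cohort.index))
    v2s = cohort.get("vent_2_start_h", pd.Series(np.nan, index=cohort.index))
    v2e = cohort.get("vent_2_end_h", pd.Series(np.nan, index=cohort.index))
    v1s, v1e = v1s.to_numpy(float), v1e.to_numpy(float)
    v2s, v2e = v2s.to_numpy(float), v2e.to_numpy(float)
    one = np.nan_to_num(v1s, nan=np.inf) <= 0.0
    direct = one & (v1e >= window_h)
    chained = (
        one
        & (np.nan_to_num(v2s, nan=np.inf) <= v1e)
        & (np.fmax(v1e, v2e) >= window_h)
    )
    return direct | chained


def build_nested_subsets(
    cohort: pd.DataFrame,
    blood_gas: pd.DataFrame,
    windows=DEFAULT_WINDOWS_H,
    threshold_kpa: float = DEFAULT_THRESHOLD_KPA,
    gap_limit_h: float = DEFAULT_GAP_LIMIT_H,
) -> list[NestedCohort]:
    """Censoring-free nested subsets with window-specific exposure.

    For each window w the subset keeps episodes with ``los_h >= w`` (present
    and alive throughout the potential exposure period) and joins the
    exposure summary computed with ``window_h = w`` plus the window
    covariate ``continuous_mv``.  Longer-window subsets are subsets of
    shorter-window ones by construction.
    """
    subsets: list[NestedCohort] = []
    for w in windows:
        sub = cohort[cohort["los_h"] >= float(w)].reset_index(drop=True)
        expo = compute_exposure_table(
            blood_gas,
            sub["episode_id"].tolist(),
            float(w),
            threshold_kpa=threshold_kpa,
            gap_limit_h=gap_limit_h,
        )
        merged = sub.merge(
            expo.drop(columns=["window_h", "threshold_kpa"]),
            on="episode_id",
            how="left",
        )
        merged["any_exposure"] = merged["any_exposure"].astype(float)
        merged["continuous_mv"] = _continuous_mv_column(merged, float(w)).astype(
            float
        )
        subsets.append(NestedCohort(window_h=float(w), table=merged))
    return subsets
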