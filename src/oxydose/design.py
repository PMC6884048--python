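"""Model-matrix assembly for the mortality models.

The outcome model pairs a continuous hyperoxemia dose with a binary
any-exposure indicator (the spike-at-zero coding), adds the clinical
covariates — respiratory diagnosis, sex, prior dependency, admission type,
continuous mechanical ventilation — and models age, weight and APACHE II
with restricted cubic splines.  Optional exposure x respiratory-diagnosis
and exposure x ventilation interaction columns are flagged for penalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .splines import SplineSpec, place_knots, rcs_basis

#: covariates entered linearly (all binary here)
DEFAULT_LINEAR_TERMS = (
    "respiratory_dx",
    "sex_male",
    "prior_dependency",
    "medical",
    "continuous_mv",
)

#: continuous covariates -> restricted-cubic-spline knot count
DEFAULT_SPLINE_TERMS: Mapping[str, int] = {
    "age_years": 4,
    "weight_kg": 4,
    "apache_ii": 4,
}

EXPOSURE_TERMS = ("dose_kpa", "any_exposure")

#: flags the exposure terms interact with when interactions are requested
INTERACTION_FLAGS = ("respiratory_dx", "continuous_mv")


@dataclass(frozen=True)
class ModelDefinition:
    """What goes into the design matrix and how the model is fitted."""

    linear_terms: tuple[str, ...] = DEFAULT_LINEAR_TERMS
    spline_terms: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPLINE_TERMS)
    )
    exposure: bool = True
    interactions: bool = False
    link: str = "logit"
    lambda_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
    dose_spline: bool = False  # diagnostic: spline instead of linear dose


@dataclass
class Design:
    """A realised design matrix with term bookkeeping."""

    X: np.ndarray
    names: list[str]
    penalized_mask: np.ndarray  # bool per column
    spline_specs: dict[str, SplineSpec]
    dropped: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]


def _derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Map raw table encodings onto model covariates."""
    out = df.copy()
    if "sex_male" not in out and "sex" in out:
        out["sex_male"] = (out["sex"].astype(str).str.upper() == "M").astype(float)
    if "medical" not in out and "patient_type" in out:
        out["medical"] = (
            out["patient_type"].astype(str).str.lower() == "medical"
        ).astype(float)
    return out


def build_design(
    cohort: pd.DataFrame,
    definition: ModelDefinition = ModelDefinition(),
    spline_specs: Mapping[str, SplineSpec] | None = None,
    drop_constant_indicator: bool = True,
) -> Design:
    """Assemble the design matrix (intercept first) from a cohort table.

    Spline knots are placed from the data at hand unless ``spline_specs``
    provides them (used to hold knots fixed when predicting on new rows).
    A constant any-exposure indicator (every episode exposed) is dropped
    with a warning, together with its interactions, so the dose-only model
    still fits instead of failing on rank deficiency.
    """
    df = _derived_columns(cohort)
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    penalized: list[bool] = [False]
    specs: dict[str, SplineSpec] = {}
    dropped: list[str] = []

    def need(name: str) -> np.ndarray:
        if name not in df:
            raise KeyError(f"cohort table is missing required column {name!r}")
        return df[name].to_numpy(dtype=float)

    exposure_cols: list[str] = []
    if definition.exposure:
        dose = need("dose_kpa")
        any_exp = need("any_exposure")
        if definition.dose_spline:
            spec = (
                spline_specs.get("dose_kpa")
                if spline_specs and "dose_kpa" in spline_specs
                else place_knots(dose[any_exp > 0], 4, name="dose_kpa")
            )
            specs["dose_kpa"] = spec
            basis = rcs_basis(dose, spec)
            for j, cname in enumerate(spec.column_names):
                cols.append(basis[:, j])
                names.append(cname)
                penalized.append(False)
            exposure_cols.extend(spec.column_names)
        else:
            cols.append(dose)
            names.append("dose_kpa")
            penalized.append(False)
            exposure_cols.append("dose_kpa")
        if drop_constant_indicator and np.all(any_exp == any_exp[0]):
            warnings.warn(
                "any_exposure is constant; dropping the indicator "
                "(dose-only spike-at-zero model)",
                stacklevel=2,
            )
            dropped.append("any_exposure")
        else:
            cols.append(any_exp)
            names.append("any_exposure")
            penalized.append(False)
            exposure_cols.append("any_exposure")

    for term in definition.linear_terms:
        cols.append(need(term))
        names.append(term)
        penalized.append(False)

    for term, k in definition.spline_terms.items():
        spec = (
            spline_specs[term]
            if spline_specs and term in spline_specs
            else place_knots(df[term], k, name=term)
        )
        specs[term] = spec
        basis = rcs_basis(need(term), spec)
        for j, cname in enumerate(spec.column_names):
            cols.append(basis[:, j])
            names.append(cname)
            penalized.append(False)

    if definition.interactions and definition.exposure:
        for flag in INTERACTION_FLAGS:
            fvals = need(flag)
            for exp_name in exposure_cols:
                if exp_name.endswith(tuple(f"_rcs{j}" for j in range(1, 8))):
                    continue  # interactions use the linear exposure terms only
                cols.append(cols[names.index(exp_name)] * fvals)
                names.append(f"{exp_name}:{flag}")
                penalized.append(True)

    X = np.column_stack(cols)
    return Design(
        X=X,
        names=names,
        penalized_mask=np.asarray(penalized, dtype=bool),
        spline_specs=specs,
        dropped=dropped,
    )
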