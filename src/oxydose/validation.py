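"""Apparent and bootstrap optimism-corrected model performance.

Discrimination (c-index / AUROC, precision-recall), accuracy (Brier score)
and calibration (recalibration slope and intercept, decile curve plus a
lowess smooth) are computed apparently and corrected by the standard
optimism bootstrap: the whole fitting procedure is repeated on each of B
resamples, the performance gap between the resample (training) and the
original data (test) estimates the optimism, and corrected = apparent -
mean optimism.  Resamples that hit perfect separation are skipped and
counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import logit as _logit
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve
from statsmodels.nonparametric.smoothers_lowess import lowess

from .design import Design, ModelDefinition, build_design
from .model import FittedModel, SeparationError, fit_penalized, select_penalty


class UndefinedMetricError(ValueError):
    """Metric undefined (e.g. single-class outcome)."""


def c_index(predicted, outcome) -> float:
    """Concordance probability (equals AUROC); ties count one half.

    The probability that a randomly chosen event case receives a higher
    prediction than a randomly chosen non-case.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcome).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("c-index needs both outcome classes")
    r = rankdata(p)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def brier_score(predicted, outcome) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcome, dtype=float)
    return float(np.mean((p - y) ** 2))


def precision_recall(predicted, outcome) -> dict:
    """Precision-recall curve and average precision (step integration)."""
    y = np.asarray(outcome).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("precision-recall needs both outcome classes")
    precision, recall, thresholds = precision_recall_curve(y, predicted)
    ap = float(average_precision_score(y, predicted))
    return {
        "precision": precision,
        "recall": recall,
        "thresholds": thresholds,
        "average_precision": ap,
    }


def calibration_slope_intercept(predicted, outcome) -> tuple[float, float]:
    """Logistic recalibration of the outcome on the linear predictor.

    Slope from ``y ~ a + b * logit(p)``; intercept (calibration in the
    large) from ``y ~ a`` with ``logit(p)`` as a fixed offset.  A perfectly
    calibrated predictor has slope 1 and intercept 0.
    """
    p = np.clip(np.asarray(predicted, dtype=float), 1e-10, 1 - 1e-10)
    lp = _logit(p)
    X = np.column_stack([np.ones_like(lp), lp])
    slope_fit = fit_penalized(X, outcome)
    slope = float(slope_fit.params[1])
    int_fit = fit_penalized(np.ones((lp.size, 1)), outcome, offset=lp)
    intercept = float(int_fit.params[0])
    return slope, intercept


def calibration_curve_points(
    predicted, outcome, n_bins: int = 10, smooth_frac: float = 0.5
) -> pd.DataFrame:
    """Decile-bin calibration points plus a lowess smooth.

    Returns rows of (kind, predicted, observed): kind 'bin' for the decile
    points, 'smooth' for the local-linear curve.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcome, dtype=float)
    q = np.quantile(p, np.linspace(0, 1, n_bins + 1))
    q[0], q[-1] = -np.inf, np.inf
    bins = np.digitize(p, q[1:-1])
    rows = []
    for b in range(n_bins):
        m = bins == b
        if m.any():
            rows.append(("bin", float(p[m].mean()), float(y[m].mean())))
    sm = lowess(y, p, frac=smooth_frac, return_sorted=True)
    for px, ox in sm[:: max(1, len(sm) // 200)]:
        rows.append(("smooth", float(px), float(ox)))
    return pd.DataFrame(rows, columns=["kind", "predicted", "observed"])


@dataclass
class ValidationReport:
    """Apparent and optimism-corrected performance of one model."""

    apparent: dict[str, float]
    optimism: dict[str, float]
    corrected: dict[str, float]
    calibration_curve: pd.DataFrame
    average_precision: float
    aic: float
    n_resamples: int
    n_skipped: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "apparent": self.apparent,
            "optimism": self.optimism,
            "corrected": self.corrected,
            "average_precision": self.average_precision,
            "aic": self.aic,
            "n_resamples": self.n_resamples,
            "n_skipped": self.n_skipped,
            "seed": self.seed,
        }


_METRICS = ("c_index", "brier", "calibration_slope", "calibration_intercept")


def _performance(predicted, outcome) -> dict[str, float]:
    slope, intercept = calibration_slope_intercept(predicted, outcome)
    return {
        "c_index": c_index(predicted, outcome),
        "brier": brier_score(predicted, outcome),
        "calibration_slope": slope,
        "calibration_intercept": intercept,
    }


def default_fitter(
    definition: ModelDefinition,
) -> Callable[[pd.DataFrame], tuple[FittedModel, Design]]:
    """The full fitting procedure (design assembly included) as a callable.

    The optimism bootstrap must repeat every data-driven step, so knot
    placement and penalty selection happen inside the returned function.
    """

    def fit(df: pd.DataFrame) -> tuple[FittedModel, Design]:
        design = build_design(df, definition)
        if definition.interactions:
            _, fitted = select_penalty(
                design,
                df["icu_death"].to_numpy(float),
                lambda_grid=definition.lambda_grid,
                link=definition.link,
            )
        else:
            fitted = fit_penalized(
                design, df["icu_death"].to_numpy(float), link=definition.link
            )
        return fitted, design

    return fit


def bootstrap_validate(
    data: pd.DataFrame,
    definition: ModelDefinition = ModelDefinition(),
    B: int = 500,
    seed: int = 0,
    fitter: Callable[[pd.DataFrame], tuple[FittedModel, Design]] | None = None,
    outcome_col: str = "icu_death",
) -> ValidationReport:
    """Optimism-bootstrap validation of the modelling procedure.

    Refits the full procedure on each of ``B`` resamples drawn with
    replacement, evaluates each refit on its own resample and on the
    original data, and subtracts the mean train-test gap from the apparent
    performance.  Deterministic in ``seed``; separated resamples are
    skipped and counted in the report.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    fit = fitter if fitter is not None else default_fitter(definition)
    y = data[outcome_col].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    fitted, design = fit(data)
    p_app = fitted.predict(design.X)
    apparent = _performance(p_app, y)

    gaps = {m: [] for m in _METRICS}
    skipped = 0
    n = len(data)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            bfit, bdesign = fit(boot)
            p_train = bfit.predict(bdesign.X)
            train = _performance(p_train, y[idx])
            # evaluate the resample's model on the original data; the
            # original design is rebuilt under the resample's knots
            test_design = build_design(
                data, definition, spline_specs=bfit.spline_specs
            ) if bfit.spline_specs else bdesign
            if bfit.spline_specs:
                Xtest = _align_columns(test_design, bfit.names)
            else:
                Xtest = _align_columns(design, bfit.names)
            p_test = bfit.predict(Xtest)
            test = _performance(p_test, y)
        except (SeparationError, UndefinedMetricError):
            skipped += 1
            continue
        for m in _METRICS:
            gaps[m].append(train[m] - test[m])

    if not any(gaps[m] for m in _METRICS):
        raise RuntimeError("every bootstrap resample failed; cannot correct")
    optimism = {m: float(np.mean(gaps[m])) for m in _METRICS}
    corrected = {m: apparent[m] - optimism[m] for m in _METRICS}

    # corrected-style calibration curve: shrink the linear predictor by the
    # corrected slope/intercept before binning
    lp = _logit(np.clip(p_app, 1e-10, 1 - 1e-10))
    lp_corr = corrected["calibration_intercept"] + corrected["calibration_slope"] * lp
    p_corr = 1.0 / (1.0 + np.exp(-lp_corr))
    curve = calibration_curve_points(p_corr, y)

    return ValidationReport(
        apparent=apparent,
        optimism=optimism,
        corrected=corrected,
        calibration_curve=curve,
        average_precision=precision_recall(p_app, y)["average_precision"],
        aic=fitted.aic,
        n_resamples=B,
        n_skipped=skipped,
        seed=seed,
    )


def _align_columns(design: Design, names: list[str]) -> np.ndarray:
    """Columns of ``design`` reordered/subset to a fitted model's terms."""
    if design.names == names:
        return design.X
    idx = [design.names.index(nm) for nm in names]
    return design.X[:, idx]
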