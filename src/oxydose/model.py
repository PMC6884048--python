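"""Binary-outcome GLMs with ridge-penalized interaction terms.

Fitting is Fisher-scoring / iteratively reweighted least squares for the
logit, probit and complementary log-log links.  A quadratic (ridge) penalty
``(lambda/2) * sum_{j in mask} beta_j^2`` may be applied to a subset of
columns (here: exposure x covariate interactions), with the masked columns
standardized internally so lambda is scale-free.  The effective degrees of
freedom of a penalized fit is ``tr[(H + P)^-1 H]`` with ``H`` the Fisher
information at the optimum and ``P`` the diagonal penalty; AIC uses the
unpenalized log-likelihood at the penalized estimate together with that
effective dimension, and the penalty strength is chosen by minimizing it.
Coefficient covariance is the sandwich ``(H+P)^-1 H (H+P)^-1`` (equal to
``H^-1`` when lambda = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg, stats
from scipy.special import expit, logit as _logit

from .design import Design

SEPARATION_BOUND = 15.0
MAX_ITER = 25
TOL = 1e-8
_EPS = 1e-10


class SeparationError(RuntimeError):
    """Perfect separation: a coefficient diverged during fitting."""


class NotNestedError(ValueError):
    """Likelihood-ratio test requested for non-nested models."""


@dataclass(frozen=True)
class Link:
    name: str
    inverse: Callable[[np.ndarray], np.ndarray]
    forward: Callable[[np.ndarray], np.ndarray]
    dmu_deta: Callable[[np.ndarray, np.ndarray], np.ndarray]


def _cloglog_inv(eta):
    return -np.expm1(-np.exp(np.clip(eta, -30, 3.5)))


LINKS: dict[str, Link] = {
    "logit": Link(
        "logit",
        inverse=expit,
        forward=_logit,
        dmu_deta=lambda eta, mu: mu * (1.0 - mu),
    ),
    "probit": Link(
        "probit",
        inverse=lambda eta: stats.norm.cdf(eta),
        forward=lambda mu: stats.norm.ppf(mu),
        dmu_deta=lambda eta, mu: stats.norm.pdf(eta),
    ),
    "cloglog": Link(
        "cloglog",
        inverse=_cloglog_inv,
        forward=lambda mu: np.log(-np.log1p(-mu)),
        dmu_deta=lambda eta, mu: np.exp(
            np.clip(eta, -30, 3.5) - np.exp(np.clip(eta, -30, 3.5))
        ),
    ),
}


@dataclass
class FittedModel:
    """Coefficients, covariance and fit metrics for one model."""

    names: list[str]
    params: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    effective_df: float
    aic: float
    n: int
    converged: bool
    link: str
    lam: float = 0.0
    penalized_mask: np.ndarray | None = None
    spline_specs: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Event probabilities for a design matrix with matching columns."""
        return LINKS[self.link].inverse(np.asarray(X) @ self.params)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.params


def _as_matrix(design) -> tuple[np.ndarray, list[str], np.ndarray | None, dict]:
    if isinstance(design, Design):
        return design.X, design.names, design.penalized_mask, design.spline_specs
    if hasattr(design, "columns"):  # DataFrame: keep its column names
        return (
            design.to_numpy(dtype=float),
            [str(c) for c in design.columns],
            None,
            {},
        )
    X = np.asarray(design, dtype=float)
    names = [f"x{j}" for j in range(X.shape[1])]
    return X, names, None, {}


def fit_penalized(
    design,
    outcome,
    lam: float = 0.0,
    penalized_mask: np.ndarray | None = None,
    link: str = "logit",
    offset: np.ndarray | None = None,
) -> FittedModel:
    """Penalized maximum likelihood by Fisher scoring.

    ``lam`` is the ridge strength applied (after internal standardization)
    to the columns flagged in ``penalized_mask``; ``lam = 0`` is ordinary
    maximum likelihood.  Convergence when the largest coefficient update
    falls below 1e-8, at most 25 iterations; non-convergence is flagged on
    the result and warned about, never silent.  A non-intercept coefficient
    beyond +-15 raises :class:`SeparationError`.
    """
    X, names, design_mask, spline_specs = _as_matrix(design)
    y = np.asarray(outcome, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("outcome length does not match design rows")
    if link not in LINKS:
        raise ValueError(f"unknown link {link!r}; choose from {sorted(LINKS)}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    lk = LINKS[link]
    if penalized_mask is None:
        penalized_mask = (
            design_mask if design_mask is not None else np.zeros(p, dtype=bool)
        )
    penalized_mask = np.asarray(penalized_mask, dtype=bool)

    # standardize penalized columns so lambda is scale-free
    scale = np.ones(p)
    if lam > 0 and penalized_mask.any():
        sd = X[:, penalized_mask].std(axis=0)
        sd[sd == 0] = 1.0
        scale[penalized_mask] = sd
    Xs = X / scale
    P = np.zeros(p)
    P[penalized_mask] = lam
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(p)
    converged = False
    for _ in range(MAX_ITER):
        eta = Xs @ beta + off
        mu = np.clip(lk.inverse(eta), _EPS, 1.0 - _EPS)
        d = np.maximum(lk.dmu_deta(eta, mu), _EPS)
        w = d * d / (mu * (1.0 - mu))
        z = (eta - off) + (y - mu) / d
        XtW = Xs.T * w
        A = XtW @ Xs + np.diag(P)
        b = XtW @ z - 0.0
        try:
            beta_new = linalg.solve(A, b, assume_a="pos")
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError("design matrix is rank deficient") from exc
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        intercept_free = np.array([nm != "intercept" for nm in names])
        if np.any(np.abs(beta[intercept_free]) > SEPARATION_BOUND):
            raise SeparationError(
                "coefficient diverged beyond +-15; outcome is (quasi-)separated"
            )
        if step < TOL:
            converged = True
            break
    if not converged:
        warnings.warn("IRLS did not converge within 25 iterations", stacklevel=2)

    eta = Xs @ beta + off
    mu = np.clip(lk.inverse(eta), _EPS, 1.0 - _EPS)
    d = np.maximum(lk.dmu_deta(eta, mu), _EPS)
    w = d * d / (mu * (1.0 - mu))
    H = (Xs.T * w) @ Xs
    Ainv = linalg.inv(H + np.diag(P))
    if lam > 0 and penalized_mask.any():
        edf = float(np.trace(Ainv @ H))
        cov_s = Ainv @ H @ Ainv
    else:
        edf = float(p)
        cov_s = Ainv
    ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))

    # back-transform out of the standardized parameterisation
    beta_raw = beta / scale
    cov_raw = cov_s / np.outer(scale, scale)
    return FittedModel(
        names=list(names),
        params=beta_raw,
        cov=cov_raw,
        log_likelihood=ll,
        effective_df=edf,
        aic=-2.0 * ll + 2.0 * edf,
        n=n,
        converged=converged,
        link=link,
        lam=float(lam),
        penalized_mask=penalized_mask,
        spline_specs=dict(spline_specs),
        meta={"aic_variant": "unpenalized loglik at penalized estimate"},
    )


def fit_glm(design, outcome, link: str = "logit") -> FittedModel:
    """Unpenalized maximum-likelihood fit (IRLS)."""
    return fit_penalized(design, outcome, lam=0.0, link=link)


def select_penalty(
    design,
    outcome,
    penalized_mask: np.ndarray | None = None,
    lambda_grid=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0),
    link: str = "logit",
) -> tuple[float, FittedModel]:
    """Choose the ridge strength minimizing AIC over a grid.

    AIC here is -2 x (unpenalized log-likelihood at the penalized estimate)
    + 2 x effective df.  Ties go to the smallest lambda (the grid is scanned
    in ascending order with a strict improvement rule).
    """
    grid = sorted(float(l) for l in lambda_grid)
    if not grid:
        raise ValueError("lambda_grid must be non-empty")
    best: tuple[float, FittedModel] | None = None
    for lam in grid:
        fit = fit_penalized(
            design, outcome, lam=lam, penalized_mask=penalized_mask, link=link
        )
        if best is None or fit.aic < best[1].aic:
            best = (lam, fit)
    return best


def lr_test(reduced: FittedModel, full: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested unpenalized fits.

    Returns (chi2, df, p) with chi2 = 2(ll_full - ll_reduced) and df the
    column-count difference.  Requires the reduced model's columns to be a
    strict subset of the full model's, same data size and link, and both
    fits unpenalized (lambda = 0) so the chi-square calibration is exact.
    """
    if reduced.lam != 0.0 or full.lam != 0.0:
        raise ValueError("lr_test requires unpenalized (lambda = 0) fits")
    if reduced.link != full.link or reduced.n != full.n:
        raise NotNestedError("models fitted on different data or links")
    if not set(reduced.names) <= set(full.names):
        raise NotNestedError("reduced model columns are not a subset of the full model")
    df = len(full.names) - len(reduced.names)
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df == 0:
        chi2 = 0.0
    return chi2, df, p


def term_odds_ratio(
    model: FittedModel, term: str, level: float = 0.95
) -> dict[str, float]:
    """Odds ratio, compatibility interval and Wald test for one linear term.

    Valid for single columns (dose, the any-exposure indicator, binary
    covariates).  Spline-expanded terms have no single odds ratio; ask for
    contrast-based effects instead.
    """
    if term in model.spline_specs or any(
        nm.startswith(f"{term}_rcs") for nm in model.names
    ):
        raise ValueError(
            f"{term!r} is spline-coded; a single odds ratio is not defined — "
            "use predicted-risk contrasts"
        )
    if term not in model.names:
        raise KeyError(f"term {term!r} not in model")
    beta = model.coef(term)
    se = model.se(term)
    z = stats.norm.ppf(0.5 + level / 2.0)
    wald = (beta / se) ** 2 if se > 0 else np.inf
    return {
        "term": term,
        "odds_ratio": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - z * se)),
        "ci_high": float(np.exp(beta + z * se)),
        "wald_chi2": float(wald),
        "df": 1,
        "p_value": float(stats.chi2.sf(wald, 1)),
    }
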