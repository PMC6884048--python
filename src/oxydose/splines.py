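"""Restricted cubic spline (natural cubic, truncated-power form) design columns.

A restricted cubic spline with k knots t_1 < ... < t_k is a cubic spline
constrained to be linear below t_1 and above t_k.  In the truncated-power
parameterisation the basis has k-1 columns: the identity x plus k-2
nonlinear terms

    C_j(x) = [ (x-t_j)_+^3
               - (x-t_{k-1})_+^3 (t_k - t_j)/(t_k - t_{k-1})
               + (x-t_k)_+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}) ] / (t_k - t_1)^2

for j = 1..k-2.  The (t_k - t_1)^2 normalisation puts the nonlinear columns
on roughly the scale of x, which keeps penalized fits well conditioned.
Knots default to conventional sample quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# conventional quantile positions per knot count
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


class DegenerateInputError(ValueError):
    """Raised when knots cannot be placed (too few distinct values)."""


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations for one predictor; yields ``n_knots - 1`` columns."""

    name: str
    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.size < 3:
            raise ValueError("restricted cubic splines need at least 3 knots")
        if np.any(np.diff(k) <= 0):
            raise ValueError("knots must be strictly increasing")

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1

    @property
    def column_names(self) -> list[str]:
        return [self.name] + [
            f"{self.name}_rcs{j}" for j in range(1, self.n_knots - 1)
        ]


def place_knots(x, n_knots: int = 4, name: str = "x") -> SplineSpec:
    """Place knots at conventional quantiles of ``x``.

    For knot counts without a tabulated convention the quantiles are spread
    evenly over [0.05, 0.95].  Raises :class:`DegenerateInputError` when the
    data carry fewer distinct quantile values than knots.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    q = _KNOT_QUANTILES.get(n_knots, tuple(np.linspace(0.05, 0.95, n_knots)))
    knots = np.quantile(x, q) if x.size else np.array([])
    if knots.size < n_knots or np.any(np.diff(knots) <= 0):
        raise DegenerateInputError(
            f"cannot place {n_knots} distinct knots for {name!r}; "
            "too few distinct values"
        )
    return SplineSpec(name=name, knots=tuple(float(k) for k in knots))


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic basis: columns [x, C_1(x), ..., C_{k-2}(x)].

    Linear beyond the boundary knots by construction; extrapolation is
    therefore safe.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(spec.knots, dtype=float)
    k = t.size
    tau = (t[-1] - t[0]) ** 2

    def cube(u: np.ndarray) -> np.ndarray:
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
            + cube(x - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        ) / tau
        cols.append(term)
    return np.column_stack(cols)
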