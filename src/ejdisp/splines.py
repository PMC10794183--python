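"""Spline bases for smooth predictor effects.

Two basis families are provided:

* :class:`NaturalSplineBasis` — a natural cubic spline (linear beyond its
  boundary knots) in the truncated-power construction, with interior knots at
  equally spaced quantiles of the data and columns centered so that the
  fitted curve is exactly zero at a chosen reference value. Used for the
  final, unpenalized refits of nonlinear associations.

* :class:`PenalizedSplineBasis` — a cubic B-spline basis with a second-order
  difference penalty, with the sum-to-zero identifiability constraint
  absorbed by reparameterization. The penalty null space, after the
  constraint, is one-dimensional (the linear trend), so as the smoothing
  parameter grows the smooth collapses to a straight line and its effective
  degrees of freedom approach 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = ["NaturalSplineBasis", "PenalizedSplineBasis", "natural_spline_basis"]


@dataclass
class NaturalSplineBasis:
    """Natural cubic spline basis with ``df`` columns, centered at ``reference``.

    Knots: boundary knots at the observed min/max, ``df − 1`` interior knots
    at equally spaced quantiles. Basis functions (before centering) are
    x together with the ``d_k − d_{K−1}`` differences of scaled truncated
    cubes, which are linear for x outside the boundary knots.
    """

    knots: np.ndarray  # all K = df + 1 knots, increasing
    reference: float

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xi = self.knots
        K = len(xi)

        def d(k: int) -> np.ndarray:
            # scaled truncated cubic difference, linear beyond xi[K-1]
            return (
                np.maximum(x - xi[k], 0.0) ** 3 - np.maximum(x - xi[K - 1], 0.0) ** 3
            ) / (xi[K - 1] - xi[k])

        cols = [x]
        dK2 = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dK2)
        return np.column_stack(cols)

    def evaluate(self, x) -> np.ndarray:
        """Centered design matrix: rows are exactly zero at the reference."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        ref_row = self._raw(np.array([self.reference]))
        return self._raw(x) - ref_row


def natural_spline_basis(x, df: int = 4, reference: float | None = None) -> NaturalSplineBasis:
    """Build a natural cubic spline basis from observed predictor values.

    Parameters
    ----------
    x
        Observed predictor values; at least ``df + 2`` distinct values.
    df
        Number of basis columns (≥ 2).
    reference
        Centering point of the fitted curve; defaults to ``mean(x)``.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("df must be at least 2")
    distinct = np.unique(x)
    if distinct.size < df + 2:
        raise ValueError(
            f"need at least {df + 2} distinct values for a df={df} natural spline, "
            f"got {distinct.size}"
        )
    # boundary knots at min/max, df-1 interior knots at equally spaced quantiles
    probs = np.linspace(0, 100, df + 1)
    knots = np.percentile(x, probs)
    knots[0], knots[-1] = distinct[0], distinct[-1]
    knots = np.unique(knots)
    if knots.size < df + 1:
        raise ValueError("degenerate quantile knots; too many ties in x")
    if reference is None:
        reference = float(np.mean(x))
    return NaturalSplineBasis(knots=knots, reference=float(reference))


@dataclass
class PenalizedSplineBasis:
    """Constrained cubic B-spline basis with difference penalty.

    ``transform`` maps the raw B-spline coefficient space (dim ``m``) to the
    constrained space (dim ``m − 1``) orthogonal to the sum-to-zero
    constraint over the fitting data, so the constrained smooth is
    identifiable next to an intercept. ``penalty`` is the constrained
    second-order difference penalty; its null space is the linear trend.
    """

    t: np.ndarray  # full B-spline knot vector
    transform: np.ndarray  # m × (m-1)
    penalty: np.ndarray  # (m-1) × (m-1)
    reference: float
    x_min: float
    x_max: float

    @property
    def dim(self) -> int:
        return self.transform.shape[1]

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        return BSpline.design_matrix(x, self.t, 3).toarray()

    def evaluate(self, x) -> np.ndarray:
        """Constrained basis matrix at ``x`` (values clipped to the data range)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self._raw(x) @ self.transform

    def evaluate_centered(self, x, reference: float | None = None) -> np.ndarray:
        """Constrained basis minus its row at the reference value."""
        ref = self.reference if reference is None else float(reference)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self.evaluate(x) - self.evaluate(np.array([ref]))

    @classmethod
    def from_data(cls, x, dim: int = 10, reference: float | None = None) -> "PenalizedSplineBasis":
        """Construct from observed values: ``dim`` cubic B-splines on quantile
        breakpoints, second-order difference penalty, sum-to-zero constraint.
        """
        x = np.asarray(x, dtype=float)
        if np.unique(x).size < dim:
            raise ValueError(f"need at least {dim} distinct values, got {np.unique(x).size}")
        a, b = float(x.min()), float(x.max())
        # uniform knots extended past the data range (Eilers–Marx P-spline):
        # with equal spacing the second-order coefficient-difference penalty
        # has exactly the linear functions in its null space
        inner = np.linspace(a, b, dim - 2)  # hits a and b exactly
        h = inner[1] - inner[0]
        t = np.concatenate(
            [a - h * np.array([3.0, 2.0, 1.0]), inner, b + h * np.array([1.0, 2.0, 3.0])]
        )
        m = dim
        B = BSpline.design_matrix(np.clip(x, a, b), t, 3).toarray()
        c = B.mean(axis=0, keepdims=True)  # sum-to-zero constraint over the data
        Q = null_space(c)  # m × (m-1)
        D = np.diff(np.eye(m), n=2, axis=0)  # second-order differences
        S = D.T @ D
        return cls(
            t=t,
            transform=Q,
            penalty=Q.T @ S @ Q,
            reference=float(np.mean(x)) if reference is None else float(reference),
            x_min=a,
            x_max=b,
        )
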