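"""Penalized B-spline log baseline hazard.

The log baseline hazard is log h0(t) = sum_l gamma_l B_l(t) on a cubic
B-spline basis over the observed time range.  Smoothness is imposed through
a Bayesian P-spline prior: an improper Gaussian on the r-th order
differences of the coefficients with precision-like smoothing parameter
tau_h in (0, 1),

    log p(gamma | tau_h) = (rank/2) log tau_h
                           - (tau_h/2) gamma' D_r' D_r gamma + const,

where D_r is the r-th difference matrix and rank = L - r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


def equal_knots(lo: float, hi: float, basis_count: int, degree: int) -> np.ndarray:
    """Full (clamped) knot vector with equally spaced interior knots."""
    n_interior = basis_count - degree - 1
    if n_interior < 0:
        raise ValueError(
            f"basis_count={basis_count} requires degree+1={degree + 1} or more bases"
        )
    if hi <= lo:
        raise ValueError("knot span must have positive length")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )


def difference_matrix(size: int, order: int) -> np.ndarray:
    """r-th order difference matrix D_r with shape (size - order, size)."""
    if order >= size:
        raise ValueError(f"difference order {order} must be below basis size {size}")
    return np.diff(np.eye(size), n=order, axis=0)


@dataclass
class BaselineHazardSpline:
    """B-spline representation of the log baseline hazard.

    Times outside the knot span are clamped to its boundary, so the log
    baseline hazard extrapolates as a constant.
    """

    knots: np.ndarray
    degree: int = 3
    coefficients: np.ndarray | None = None
    diff_order: int = 2
    tau_h: float = 0.5
    _penalty: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.basis_count < self.degree + 1:
            raise ValueError("too few knots for the requested degree")
        if self.diff_order >= self.basis_count:
            raise ValueError("difference order must be below the basis size")
        if self.coefficients is not None:
            self.coefficients = np.asarray(self.coefficients, dtype=float)
            if self.coefficients.size != self.basis_count:
                raise ValueError(
                    f"expected {self.basis_count} coefficients, "
                    f"got {self.coefficients.size}"
                )
        self._penalty = None

    @classmethod
    def with_equal_knots(
        cls,
        time_range: tuple[float, float],
        basis_count: int = 6,
        degree: int = 3,
        diff_order: int = 2,
        coefficients: np.ndarray | None = None,
        tau_h: float = 0.5,
    ) -> "BaselineHazardSpline":
        knots = equal_knots(time_range[0], time_range[1], basis_count, degree)
        return cls(
            knots=knots,
            degree=degree,
            coefficients=coefficients,
            diff_order=diff_order,
            tau_h=tau_h,
        )

    @property
    def basis_count(self) -> int:
        return self.knots.size - self.degree - 1

    @property
    def span(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    @property
    def pen_rank(self) -> int:
        """Rank of D_r' D_r, i.e. basis_count - diff_order."""
        return self.basis_count - self.diff_order

    def basis(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the basis: one row per time, one column per basis."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.span
        t = np.clip(t, lo, hi)
        return BSpline.design_matrix(t, self.knots, self.degree).toarray()

    def penalty_matrix(self) -> np.ndarray:
        """D_r' D_r, cached."""
        if self._penalty is None:
            d = difference_matrix(self.basis_count, self.diff_order)
            self._penalty = d.T @ d
        return self._penalty

    def log_baseline(self, times: np.ndarray) -> np.ndarray:
        if self.coefficients is None:
            raise ValueError("spline coefficients are not set")
        return self.basis(times) @ self.coefficients


def bspline_basis(times: np.ndarray, spline: BaselineHazardSpline) -> np.ndarray:
    """Basis matrix of a spline at the given times (clamped to the span)."""
    return spline.basis(times)


def pspline_log_prior(
    spline: BaselineHazardSpline,
    coefficients: np.ndarray | None = None,
    tau_h: float | None = None,
) -> float:
    """Unnormalised Bayesian P-spline log prior of the spline coefficients."""
    gamma = spline.coefficients if coefficients is None else np.asarray(coefficients)
    th = spline.tau_h if tau_h is None else float(tau_h)
    if gamma is None:
        raise ValueError("spline coefficients are not set")
    if not th > 0:
        raise ValueError("tau_h must be positive")
    pen = spline.penalty_matrix()
    return 0.5 * spline.pen_rank * np.log(th) - 0.5 * th * float(gamma @ pen @ gamma)
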