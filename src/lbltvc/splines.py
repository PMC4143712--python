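"""Clamped B-spline basis over age for time-varying haplotype effects.

A haplotype's log-odds effect is expanded as beta_h(t) = sum_l beta_hl B_l(t),
where the B_l are B-spline basis functions of a given order on a clamped knot
vector.  With ``L`` interior knots and order ``k`` (cubic: k = 4) the basis has
``L + k`` functions; the default configuration (interior knots (40, 60),
boundary knots (20, 100), cubic) gives 6.  The clamped basis forms a partition
of unity on the closed boundary interval, so a constant coefficient vector
yields a constant effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineBasis:
    """Clamped B-spline basis on ``[boundary[0], boundary[1]]``.

    Parameters
    ----------
    interior_knots : tuple of float
        Strictly increasing knots strictly inside the boundary interval.
    boundary_knots : tuple (low, high)
        Ends of the age range; repeated ``order`` times in the knot vector.
    order : int
        Spline order (degree + 1); 4 is cubic.
    """

    interior_knots: tuple[float, ...] = (40.0, 60.0)
    boundary_knots: tuple[float, float] = (20.0, 100.0)
    order: int = 4
    knots: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary knots must satisfy low < high")
        interior = np.asarray(self.interior_knots, dtype=float)
        if interior.size and not (np.all(np.diff(interior) > 0)
                                  and interior[0] > lo and interior[-1] < hi):
            raise ValueError("interior knots must be strictly increasing and "
                             "strictly inside the boundary knots")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        knots = np.concatenate([np.full(self.order, lo), interior,
                                np.full(self.order, hi)])
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.order

    def evaluate(self, t) -> np.ndarray:
        """Basis matrix at ages ``t``.

        Returns an array of shape ``(len(t), n_basis)`` (or ``(n_basis,)`` for
        scalar ``t``); rows are nonnegative and sum to 1.  Ages outside the
        boundary interval raise ``ValueError``.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.boundary_knots
        if np.any(t_arr < lo) or np.any(t_arr > hi):
            raise ValueError(
                f"age outside spline boundary [{lo}, {hi}]: "
                f"{t_arr[(t_arr < lo) | (t_arr > hi)][:5]}")
        mat = BSpline.design_matrix(t_arr, self.knots, self.order - 1,
                                    extrapolate=False).toarray()
        if np.isscalar(t) or np.ndim(t) == 0:
            return mat[0]
        return mat

    def effect(self, coeffs, t):
        """Evaluate ``sum_l coeffs_l B_l(t)`` at age(s) ``t``."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape[-1] != self.n_basis:
            raise ValueError(
                f"expected {self.n_basis} coefficients, got {coeffs.shape[-1]}")
        return self.evaluate(t) @ coeffs
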