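"""B-spline basis construction for log-rate smoothing.

A clamped (open-uniform) cubic B-spline basis over the calendar-year grid.
Rows of the basis matrix sum to one everywhere on the knot span (partition
of unity), which keeps the penalized regression's intercept interpretable
as a local log-rate level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from u5m.data_model import ConfigError


@dataclass
class SplineBasis:
    years: np.ndarray          # evaluation grid (decimal years)
    knots: np.ndarray          # full clamped knot vector
    degree: int
    matrix: np.ndarray         # (len(years), n_basis)

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[1]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at arbitrary points inside the knot span."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError("evaluation points outside the knot span")
        # clip to just inside the right endpoint so the last basis function
        # evaluates to 1 there instead of 0
        xc = np.minimum(x, hi - 1e-9 * max(1.0, abs(hi)))
        return BSpline.design_matrix(
            xc, self.knots, self.degree
        ).toarray()


def build_basis(
    years: np.ndarray,
    knot_spacing: float = 2.5,
    degree: int = 3,
) -> SplineBasis:
    """Build a clamped B-spline basis with equally spaced knots over ``years``.

    The knot span covers ``[min(years), max(years)]``.  If ``knot_spacing``
    is at least the span, the basis degenerates to a single polynomial
    segment of the given degree.
    """
    years = np.asarray(years, dtype=float)
    if years.size < 2:
        raise ConfigError("need at least 2 grid years to build a basis")
    if knot_spacing <= 0:
        raise ConfigError("knot spacing must be positive")
    lo, hi = float(years.min()), float(years.max())
    if hi <= lo:
        raise ConfigError("degenerate year grid")
    span = hi - lo
    n_seg = max(1, int(np.ceil(span / knot_spacing - 1e-9)))
    breaks = np.linspace(lo, hi, n_seg + 1)
    knots = np.concatenate([
        np.full(degree, lo), breaks, np.full(degree, hi)
    ])
    basis = SplineBasis(years=years, knots=knots, degree=degree,
                        matrix=np.empty((0, 0)))
    basis.matrix = basis.evaluate(years)
    return basis
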