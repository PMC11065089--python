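"""M-spline and I-spline bases for the two monotone/free baseline functions.

M-splines (Ramsay) are nonnegative spline basis functions normalized to
integrate to one over their support; I-splines are their running integrals,
rising from 0 to a plateau of 1.  A linear combination of M-splines with free
coefficients models the longitudinal baseline mean ``mu(t)``; an intercept plus
a nonnegative combination of I-splines models the nondecreasing survival
baseline ``alpha(t)``.

Both families are realized through :class:`scipy.interpolate.BSpline`:
``M_h = B_h * (d+1) / (t_{h+d+1} - t_h)`` for the B-splines on the same knot
sequence, and each I-spline is the antiderivative of its M-spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["KnotVector", "BasisMatrix", "place_knots", "mspline_eval", "ispline_eval"]

# relative padding applied to the data range so every datum is strictly interior
_BOUNDARY_PAD = 1e-8


@dataclass(frozen=True)
class KnotVector:
    """Interior knots plus boundary knots and spline degree.

    The number of basis functions is ``K = J + degree + 1`` where ``J`` is the
    number of interior knots.
    """

    interior_knots: np.ndarray
    boundary_lo: float
    boundary_hi: float
    degree: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "interior_knots", np.asarray(self.interior_knots, dtype=float)
        )
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")
        ik = self.interior_knots
        if ik.size and not (np.all(np.diff(ik) >= 0)):
            raise ValueError("interior knots must be nondecreasing")
        if ik.size and (ik[0] <= self.boundary_lo or ik[-1] >= self.boundary_hi):
            raise ValueError("interior knots must lie strictly inside the boundaries")
        if not self.boundary_lo < self.boundary_hi:
            raise ValueError("boundary_lo must be < boundary_hi")

    @property
    def n_basis(self) -> int:
        """Number of basis functions K = J + degree + 1."""
        return self.interior_knots.size + self.degree + 1

    @property
    def full_knots(self) -> np.ndarray:
        """Knot sequence with boundary knots repeated ``degree + 1`` times."""
        d = self.degree
        return np.concatenate(
            [
                np.full(d + 1, self.boundary_lo),
                self.interior_knots,
                np.full(d + 1, self.boundary_hi),
            ]
        )


@dataclass(frozen=True)
class BasisMatrix:
    """Evaluated basis: rows are evaluation points, columns basis functions."""

    values: np.ndarray
    kind: str  # "M" or "I"

    def __post_init__(self) -> None:
        if self.kind not in ("M", "I"):
            raise ValueError("kind must be 'M' or 'I'")


def place_knots(times, J: int, degree: int = 3) -> KnotVector:
    """Place ``J`` interior knots at the empirical quantiles of ``times``.

    Interior knots sit at the j/(J+1) quantiles (linear interpolation),
    j = 1..J; boundary knots at the data min/max expanded by a tiny symmetric
    margin so every observation evaluates strictly in-support.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")
    lo, hi = float(times.min()), float(times.max())
    if lo == hi:
        raise ValueError("degenerate knot range: all times identical")
    if J < 0:
        raise ValueError("J must be >= 0")
    pad = _BOUNDARY_PAD * (hi - lo)
    if J > 0:
        probs = np.arange(1, J + 1) / (J + 1)
        interior = np.quantile(times, probs)
    else:
        interior = np.empty(0)
    return KnotVector(interior, lo - pad, hi + pad, degree)


def _mspline_objects(knots: KnotVector) -> list[BSpline]:
    """One BSpline object per M-spline basis function."""
    t = knots.full_knots
    d = knots.degree
    K = knots.n_basis
    out = []
    for h in range(K):
        c = np.zeros(K)
        span = t[h + d + 1] - t[h]
        c[h] = (d + 1) / span
        out.append(BSpline(t, c, d, extrapolate=False))
    return out


def mspline_eval(t, knots: KnotVector) -> BasisMatrix:
    """Evaluate all M-spline basis functions at the points ``t``.

    Every entry is nonnegative and each basis function integrates to one over
    its support.  Points outside ``[boundary_lo, boundary_hi]`` raise.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < knots.boundary_lo) or np.any(t > knots.boundary_hi):
        raise ValueError("evaluation point outside spline boundaries")
    tk = knots.full_knots
    d = knots.degree
    # design_matrix requires points in [t[d], t[-d-1]]; boundary points are fine
    dm = BSpline.design_matrix(t, tk, d, extrapolate=False).toarray()
    span = tk[d + 1 : d + 1 + knots.n_basis] - tk[: knots.n_basis]
    vals = dm * ((d + 1) / span)
    return BasisMatrix(vals, "M")


def ispline_eval(t, knots: KnotVector) -> BasisMatrix:
    """Evaluate all I-spline basis functions (integrated M-splines) at ``t``.

    Values lie in [0, 1], are 0 at the lower boundary and plateau at 1 from the
    upper boundary onward; ``+inf`` is accepted and maps to the plateau.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < knots.boundary_lo):
        raise ValueError("evaluation point below spline boundaries")
    inside = t <= knots.boundary_hi
    tc = np.clip(t, knots.boundary_lo, knots.boundary_hi)
    K = knots.n_basis
    vals = np.empty((t.size, K))
    for h, ms in enumerate(_mspline_objects(knots)):
        anti = ms.antiderivative()
        col = anti(tc) - anti(knots.boundary_lo)
        vals[:, h] = col
    vals[~inside] = 1.0
    np.clip(vals, 0.0, 1.0, out=vals)
    return BasisMatrix(vals, "I")
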