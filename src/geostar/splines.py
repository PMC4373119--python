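"""Equidistant-knot B-spline bases and random-walk difference penalties.

A smooth f(x) is expanded as sum_m xi_m B_m(x) over d = s + l B-spline
basis functions of degree l on s equidistant interior segments.  The knot
sequence is extended beyond each boundary by l further equally spaced
knots (spacing repetition, not knot multiplicity), which is the extension
under which a first/second-order random walk on the coefficients is the
stochastic analogue of a first/second-order difference penalty: the prior
p(xi | tau^2) ∝ exp(-xi' K xi / (2 tau^2)) with K = D' D, D the
difference operator.  K is rank d − order; polynomials of degree < order
in the coefficient index are unpenalised, and the variance tau^2 sets the
flexibility/smoothness trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class KnotVector:
    """Equidistant knots on [x_min, x_max] with l-fold boundary extension."""

    x_min: float
    x_max: float
    segments: int
    degree: int
    knots: np.ndarray

    @property
    def d(self) -> int:
        """Number of basis functions, d = s + l."""
        return self.segments + self.degree


@dataclass
class SplineBlock:
    """One smooth term: basis matrix, penalty matrix, RW order."""

    name: str
    knots: KnotVector
    basis: np.ndarray       # n × d
    penalty: np.ndarray     # d × d, symmetric PSD, rank d − order
    rw_order: int

    @property
    def d(self) -> int:
        return self.knots.d


def equidistant_knots(x_min: float, x_max: float, s: int, l: int) -> KnotVector:
    """Equally spaced knots: s interior segments, l extra beyond each end."""
    if x_max <= x_min:
        raise ValueError("x_max must exceed x_min")
    if s < 1:
        raise ValueError("need at least one interior segment")
    if l < 0:
        raise ValueError("degree must be non-negative")
    h = (x_max - x_min) / s
    interior = np.linspace(x_min, x_max, s + 1)  # exact endpoints
    left = x_min - h * np.arange(l, 0, -1)
    right = x_max + h * np.arange(1, l + 1)
    knots = np.concatenate([left, interior, right])
    return KnotVector(x_min=float(x_min), x_max=float(x_max),
                      segments=int(s), degree=int(l), knots=knots)


def evaluate_basis(x: np.ndarray, knots: KnotVector) -> np.ndarray:
    """Evaluate all d basis functions at x (n × d matrix).

    Points must lie inside [x_min, x_max]; there is no extrapolation.
    Rows sum to one (partition of unity) and each basis function is
    supported on at most l + 1 consecutive segments.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if (x < knots.x_min).any() or (x > knots.x_max).any():
        raise ValueError(
            f"x outside the knot domain [{knots.x_min}, {knots.x_max}]"
        )
    B = BSpline.design_matrix(x, knots.knots, knots.degree,
                              extrapolate=False).toarray()
    assert B.shape[1] == knots.d
    return B


def difference_penalty(d: int, order: int) -> np.ndarray:
    """Random-walk penalty matrix K = D'D for RW(order), order in {1, 2}."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if d <= order:
        raise ValueError(f"need d > order (got d={d}, order={order})")
    D = np.diff(np.eye(d), n=order, axis=0)
    return D.T @ D


def rw_prior_logdensity(xi: np.ndarray, K: np.ndarray, tau2: float) -> float:
    """Unnormalised random-walk prior log density −xi'K xi / (2 tau^2)."""
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    xi = np.asarray(xi, dtype=float)
    return float(-(xi @ K @ xi) / (2.0 * tau2))


def make_spline_block(
    name: str,
    x: np.ndarray,
    segments: int = 20,
    degree: int = 3,
    rw_order: int = 2,
) -> SplineBlock:
    """Convenience constructor: knots on the observed [min, max] of x."""
    x = np.asarray(x, dtype=float)
    kv = equidistant_knots(float(x.min()), float(x.max()), segments, degree)
    return SplineBlock(
        name=name,
        knots=kv,
        basis=evaluate_basis(x, kv),
        penalty=difference_penalty(kv.d, rw_order),
        rw_order=rw_order,
    )
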