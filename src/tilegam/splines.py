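"""Cubic B-spline bases over genomic intervals and difference penalties.

A smooth occupancy function over an interval is represented in a cubic
B-spline basis with uniformly spaced knots.  The basis matrix ``X_k`` has
one row per base pair and one column per basis function; at most four
basis functions are nonzero at any interior position (five closed
supports overlap each point), so ``X_k`` is banded and very sparse.
Roughness is penalized through squared second-order differences of
adjacent spline coefficients (the P-spline device), giving a banded
positive semi-definite penalty matrix ``S = DᵀD`` whose null space is
spanned by constant and linear coefficient vectors.

Coordinates are 0-based half-open throughout, matching BAM/BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline

from ._errors import InvalidArgumentError, OutOfDomainError

#: cubic splines
DEGREE = 3

#: basis values smaller than this are stored as structural zeros, keeping
#: the declared sparsity pattern (<= 4 nonzeros per interior row) exact
STRUCTURAL_ZERO = 1e-14

#: default distance between adjacent inner knots, in bp
DEFAULT_KNOT_SPACING = 20.0


@dataclass(frozen=True)
class KnotVector:
    """Uniform knot vector for one smooth over ``[interval_start, interval_end)``.

    ``knots`` holds the full vector including three uniformly extended
    knots beyond each boundary, so the number of cubic basis functions is
    ``len(knots) - 4``.
    """

    interval_start: float
    interval_end: float
    spacing: float
    knots: np.ndarray = field(repr=False)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - DEGREE - 1

    @property
    def inner_knots(self) -> np.ndarray:
        return self.knots[DEGREE:-DEGREE]

    @property
    def inner_start(self) -> float:
        return float(self.knots[DEGREE])

    @property
    def inner_end(self) -> float:
        return float(self.knots[-DEGREE - 1])


def place_knots(interval_start: float, interval_end: float,
                spacing: float = DEFAULT_KNOT_SPACING) -> KnotVector:
    """Place uniformly spaced knots covering ``[interval_start, interval_end]``.

    Inner knots sit at ``start, start+spacing, ...``; the last inner knot is
    the first multiple of ``spacing`` at or beyond ``interval_end``.  Three
    extra knots continue the uniform grid on each side so that every inner
    position is covered by a full complement of cubic basis functions.
    """
    if spacing <= 0:
        raise InvalidArgumentError(f"knot spacing must be positive, got {spacing}")
    if interval_end - interval_start < spacing:
        raise InvalidArgumentError(
            f"interval [{interval_start}, {interval_end}) shorter than one knot "
            f"spacing ({spacing})")
    n_inner = int(np.ceil((interval_end - interval_start) / spacing)) + 1
    first = interval_start - DEGREE * spacing
    knots = first + spacing * np.arange(n_inner + 2 * DEGREE)
    return KnotVector(interval_start=float(interval_start),
                      interval_end=float(interval_end),
                      spacing=float(spacing), knots=knots)


def evaluate_basis(knots: KnotVector, positions: np.ndarray) -> sp.csr_matrix:
    """Evaluate all cubic B-splines at ``positions``.

    Returns the sparse basis matrix with entry ``(i, r) = b_r(x_i)``.  Rows
    form a partition of unity; entries below :data:`STRUCTURAL_ZERO` are
    dropped so every interior row has at most 4 stored nonzeros.
    """
    x = np.asarray(positions, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("positions must be one-dimensional")
    if x.size and (x.min() < knots.inner_start or x.max() > knots.inner_end):
        raise OutOfDomainError(
            f"positions must lie within the inner knot range "
            f"[{knots.inner_start}, {knots.inner_end}]")
    design = BSpline.design_matrix(x, knots.knots, DEGREE).tocsr()
    design.data[np.abs(design.data) < STRUCTURAL_ZERO] = 0.0
    design.eliminate_zeros()
    return design


def evaluate_basis_derivative(knots: KnotVector, positions: np.ndarray,
                              order: int = 1) -> sp.csr_matrix:
    """First-derivative basis matrix, entry ``(i, r) = b'_r(x_i)``.

    Uses the standard recurrence expressing the derivative of a cubic
    B-spline as a scaled difference of two quadratic B-splines on the same
    knot sequence.  Only ``order=1`` is supported.
    """
    if order != 1:
        raise InvalidArgumentError("only first-order derivatives are supported")
    x = np.asarray(positions, dtype=float)
    if x.size and (x.min() < knots.inner_start or x.max() > knots.inner_end):
        raise OutOfDomainError("positions outside the inner knot range")
    t = knots.knots
    p = knots.n_basis
    # quadratic splines on the same knot vector; columns r = 0 .. p
    quad = BSpline.design_matrix(x, t, DEGREE - 1).tocsc()[:, :p + 1]
    left_scale = DEGREE / (t[DEGREE:DEGREE + p] - t[:p])
    right_scale = DEGREE / (t[DEGREE + 1:DEGREE + p + 1] - t[1:p + 1])
    deriv = (quad[:, :p] @ sp.diags(left_scale)
             - quad[:, 1:p + 1] @ sp.diags(right_scale))
    deriv = deriv.tocsr()
    deriv.data[np.abs(deriv.data) < STRUCTURAL_ZERO] = 0.0
    deriv.eliminate_zeros()
    return deriv


def second_difference_operator(p_k: int) -> sp.csr_matrix:
    """The ``(p_k - 2) x p_k`` second-order difference operator ``D``."""
    if p_k < 3:
        raise InvalidArgumentError(f"need at least 3 coefficients, got {p_k}")
    return sp.diags([np.ones(p_k - 2), -2.0 * np.ones(p_k - 2), np.ones(p_k - 2)],
                    offsets=[0, 1, 2], shape=(p_k - 2, p_k)).tocsr()


def build_penalty(p_k: int) -> sp.csc_matrix:
    """Second-order difference penalty ``S = DᵀD`` for one smooth.

    ``S`` is symmetric positive semi-definite with at most five nonzeros
    per row and annihilates constant and linear coefficient vectors, so
    the penalty approximates an integrated squared second derivative.
    """
    d = second_difference_operator(p_k)
    return (d.T @ d).tocsc()
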