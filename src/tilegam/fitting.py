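"""Penalized negative-binomial likelihood and sparse Newton-Raphson
fitting of one tile.

The model: counts ``y_i ~ NB(mu_i, theta)`` with ``log mu_i = o_i +
(X beta)_i`` and variance ``mu + mu^2 / theta``.  Coefficients maximize

    l_NB(beta; y, theta)  -  lambda * beta' (S + eps I) beta

where ``S`` is the block-diagonal second-difference penalty (one block
per smooth) and the ridge ``eps I`` stabilizes regions of all-zero
counts.  For fixed ``theta`` the objective is concave, so undamped
Newton steps with a step-halving safeguard converge; each step solves
the sparse banded system ``H d = grad`` with a direct sparse LU solver —
the Hessian inverse is never formed.

Derivatives with respect to the linear predictor ``eta = log mu``:

    dl/deta    = y - (y + theta) mu / (mu + theta)
    d2l/deta2  = -theta mu (y + theta) / (mu + theta)^2

The curvature row vector is the *full* Newton weight (it involves the
observed ``y``), not its expectation (the Fisher weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.special import gammaln

from ._errors import InvalidArgumentError, NumericalError
from .design import FullDesign
from .splines import build_penalty

#: linear predictors are clipped here before exponentiation
ETA_CLIP = 50.0

DEFAULT_EPSILON = 1e-3
DEFAULT_GRAD_TOL = 1e-6
DEFAULT_OBJ_TOL = 1e-8
DEFAULT_MAX_ITER = 50
MAX_HALVINGS = 20


@dataclass(frozen=True)
class Hyperparams:
    """Smoothing weight ``lam``, NB dispersion ``theta``, ridge ``epsilon``."""

    lam: float
    theta: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if self.theta <= 0:
            raise InvalidArgumentError(f"theta must be positive, got {self.theta}")
        if self.lam < 0 or self.epsilon < 0:
            raise InvalidArgumentError("lambda and epsilon must be non-negative")


@dataclass
class TileModel:
    """All fixed quantities needed to fit one tile."""

    y: np.ndarray                  # counts, sample-major
    offsets: np.ndarray            # log size factors, same layout
    design: FullDesign
    hyper: Hyperparams
    S_full: sp.csc_matrix = field(default=None)  # block-diagonal penalty

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.offsets = np.asarray(self.offsets, dtype=float).ravel()
        n_rows, p = self.design.X.shape
        if self.y.size != n_rows or self.offsets.size != n_rows:
            raise InvalidArgumentError(
                f"y and offsets must have {n_rows} entries (design rows)")
        if self.S_full is None:
            self.S_full = sp.block_diag(
                [build_penalty(self.design.p_k)] * self.design.n_smooths,
                format="csc")
        if self.S_full.shape != (p, p):
            raise InvalidArgumentError("penalty dimension mismatch")

    @property
    def n_params(self) -> int:
        return self.design.X.shape[1]

    def penalty_matrix(self) -> sp.csc_matrix:
        """``lam * (S + eps I)`` — the quadratic penalty actually applied."""
        p = self.n_params
        return (self.hyper.lam * (self.S_full + self.hyper.epsilon * sp.eye(p))).tocsc()


@dataclass
class FitState:
    """Result of a Newton-Raphson fit."""

    beta: np.ndarray
    mu: np.ndarray
    weights: np.ndarray            # d2 loglik / d eta^2, diagonal of W
    loglik: float                  # penalized objective at beta
    grad_norm: float
    iterations: int
    converged: bool


def _linear_predictor(model: TileModel, beta: np.ndarray) -> np.ndarray:
    eta = model.offsets + model.design.X @ beta
    if np.abs(eta).max(initial=0.0) > ETA_CLIP:
        warnings.warn("linear predictor clipped at +/-%g" % ETA_CLIP,
                      RuntimeWarning, stacklevel=3)
        eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    return eta


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Negative-binomial log-likelihood, variance ``mu + mu^2/theta``.

    The ``y * log(mu)`` term is taken as 0 for ``y == 0`` so that tiny
    fitted means never produce ``0 * -inf``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
                 + theta * (np.log(theta) - np.log(theta + mu))
                 + np.where(y > 0, y * (np.log(mu) - np.log(theta + mu)), 0.0))
    return float(terms.sum())


def penalized_loglik(model: TileModel, beta: np.ndarray) -> float:
    """Objective: NB log-likelihood minus ``lam * beta'(S + eps I)beta``."""
    beta = np.asarray(beta, dtype=float)
    if not np.isfinite(beta).all():
        raise InvalidArgumentError("beta must be finite")
    mu = np.exp(_linear_predictor(model, beta))
    pen = beta @ (model.penalty_matrix() @ beta)
    return nb_loglik(model.y, mu, model.hyper.theta) - float(pen)


def gradient(model: TileModel, beta: np.ndarray) -> np.ndarray:
    """Gradient of the penalized objective: ``X'u - 2 lam (S + eps I) beta``
    with ``u_i = y_i - (y_i + theta) mu_i / (mu_i + theta)``."""
    beta = np.asarray(beta, dtype=float)
    mu = np.exp(_linear_predictor(model, beta))
    theta = model.hyper.theta
    u = model.y - (model.y + theta) * mu / (mu + theta)
    return model.design.X.T @ u - 2.0 * (model.penalty_matrix() @ beta)


def curvature_weights(model: TileModel, mu: np.ndarray) -> np.ndarray:
    """Diagonal of ``W``: second derivative of the NB log-likelihood with
    respect to the linear predictor (full Newton, observed ``y``)."""
    theta = model.hyper.theta
    return -theta * mu * (model.y + theta) / (mu + theta) ** 2


def hessian(model: TileModel, beta: np.ndarray) -> sp.csc_matrix:
    """Sparse Hessian ``H = X' W X - 2 lam (S + eps I)``; banded and
    negative definite whenever ``lam`` and ``epsilon`` are positive."""
    beta = np.asarray(beta, dtype=float)
    mu = np.exp(_linear_predictor(model, beta))
    w = curvature_weights(model, mu)
    x = model.design.X
    h = (x.T @ sp.diags(w) @ x) - 2.0 * model.penalty_matrix()
    return h.tocsc()


def initial_beta(model: TileModel) -> np.ndarray:
    """Penalized least squares of ``log(y + 1) - o`` onto the design —
    a cheap starting point inside the concave region."""
    x = model.design.X
    target = np.log(model.y + 1.0) - model.offsets
    a = (x.T @ x + 2.0 * model.penalty_matrix()
         + 1e-6 * sp.eye(model.n_params)).tocsc()
    try:
        return splu(a).solve(x.T @ target)
    except RuntimeError as exc:     # pragma: no cover - splu failure is rare
        raise NumericalError(f"initialization solve failed: {exc}") from exc


def newton_raphson_fit(model: TileModel, beta0: np.ndarray | None = None,
                       grad_tol: float = DEFAULT_GRAD_TOL,
                       obj_tol: float = DEFAULT_OBJ_TOL,
                       max_iter: int = DEFAULT_MAX_ITER) -> FitState:
    """Maximize the penalized NB log-likelihood by Newton-Raphson.

    Each iteration factorizes the sparse Hessian with a direct LU solver
    and applies the full Newton step, halving it (at most
    :data:`MAX_HALVINGS` times) if the objective would decrease.  The
    iteration stops when the gradient max-norm drops below ``grad_tol``
    or the relative objective change drops below ``obj_tol``.
    """
    if grad_tol <= 0:
        raise InvalidArgumentError("tolerance must be positive")
    beta = initial_beta(model) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    obj = penalized_loglik(model, beta)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        g = gradient(model, beta)
        grad_norm = float(np.abs(g).max(initial=0.0))
        if grad_norm <= grad_tol:
            converged = True
            iterations -= 1
            break
        h = hessian(model, beta)
        try:
            delta = splu(h).solve(g)
        except RuntimeError as exc:
            raise NumericalError(
                f"Newton step failed: Hessian factorization error ({exc}); "
                "consider lam, epsilon > 0") from exc
        step = 1.0
        for _ in range(MAX_HALVINGS + 1):
            candidate = beta - step * delta
            new_obj = penalized_loglik(model, candidate)
            if new_obj >= obj - 1e-12 * (1.0 + abs(obj)):
                break
            step *= 0.5
        else:
            break   # no acceptable step: stagnation
        beta = candidate
        rel_change = abs(new_obj - obj) / (1.0 + abs(obj))
        obj = new_obj
        if rel_change < obj_tol:
            converged = True
            break
    g = gradient(model, beta)
    mu = np.exp(_linear_predictor(model, beta))
    return FitState(beta=beta, mu=mu, weights=curvature_weights(model, mu),
                    loglik=obj, grad_norm=float(np.abs(g).max(initial=0.0)),
                    iterations=iterations, converged=converged)


def smooth_values(design: FullDesign, basis: sp.spmatrix, beta: np.ndarray) -> np.ndarray:
    """Evaluate every fitted smooth at every position: column ``k`` is
    ``X_k beta^(k)``, an (n_positions x K) array."""
    p_k = design.p_k
    return np.column_stack([
        basis @ beta[k * p_k:(k + 1) * p_k] for k in range(design.n_smooths)])
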