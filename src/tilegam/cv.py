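"""Hyperparameter selection by k-fold cross-validation on representative
tiles.

The smoothing weight ``lambda`` and the NB dispersion ``theta`` are
global hyperparameters.  They are chosen to maximize the out-of-fold NB
log-likelihood over a small set of tiles sampled with probability
proportional to their total counts.  Held-out positions come in short
consecutive blocks (default 20 bp) so the fit must interpolate them from
flanking data — a direct test of the smoothing assumption rather than of
memorization.  The search is derivative-free (Nelder-Mead) over
``(log10 lambda, log10 theta)`` from a few seeded starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._errors import InvalidArgumentError, NoSignalError, OptimizationError
from .design import FullDesign
from .fitting import Hyperparams, TileModel, nb_loglik, newton_raphson_fit
from .ingest import TileLayout

DEFAULT_N_TILES = 20
DEFAULT_N_FOLDS = 10
DEFAULT_BLOCK_BP = 20


def select_cv_tiles(layout: TileLayout, counts: np.ndarray, n_tiles: int,
                    seed: int) -> list[int]:
    """Sample ``n_tiles`` tile indices without replacement, with
    probability proportional to each tile's total count.

    ``counts`` is the (samples x length) per-base matrix for the
    chromosome described by ``layout``.
    """
    if n_tiles > layout.n_tiles:
        raise InvalidArgumentError(
            f"requested {n_tiles} tiles but layout has {layout.n_tiles}")
    totals = np.array([
        np.atleast_2d(counts)[:, s:e].sum() for s, e in layout.tiles], dtype=float)
    if totals.sum() == 0:
        raise NoSignalError("all tiles have zero counts; cannot select "
                            "representative tiles")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    weights = totals.copy()
    for _ in range(n_tiles):
        p = weights / weights.sum()
        pick = int(rng.choice(len(weights), p=p))
        chosen.append(pick)
        weights[pick] = 0.0
        if weights.sum() == 0 and len(chosen) < n_tiles:
            # remaining tiles are all empty: take them in index order
            rest = [i for i in range(layout.n_tiles) if i not in chosen]
            chosen.extend(rest[:n_tiles - len(chosen)])
            break
    return chosen


@dataclass(frozen=True)
class FoldAssignment:
    """Per-position fold labels (0-based), built from consecutive blocks."""

    labels: np.ndarray
    n_folds: int
    block_bp: int
    seed: int


def make_folds(n: int, n_folds: int = DEFAULT_N_FOLDS,
               block_bp: int = DEFAULT_BLOCK_BP, seed: int = 0) -> FoldAssignment:
    """Assign positions to folds in consecutive blocks of ``block_bp``,
    distributing blocks round-robin after a seeded shuffle of the fold
    order."""
    if n_folds < 2 or block_bp < 1:
        raise InvalidArgumentError("need n_folds >= 2 and block_bp >= 1")
    if n < n_folds * block_bp:
        raise InvalidArgumentError(
            f"tile of {n} positions cannot host {n_folds} folds of "
            f"{block_bp} bp blocks")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_folds)
    n_blocks = int(np.ceil(n / block_bp))
    block_labels = order[np.arange(n_blocks) % n_folds]
    labels = np.repeat(block_labels, block_bp)[:n]
    return FoldAssignment(labels=labels, n_folds=n_folds,
                          block_bp=block_bp, seed=seed)


def _restrict_model(model: TileModel, position_mask: np.ndarray) -> TileModel:
    """Sub-model keeping only rows at masked positions (all samples)."""
    n_samples = model.design.n_samples
    row_mask = np.tile(position_mask, n_samples)
    x = model.design.X[row_mask]
    design = FullDesign(X=x.tocsr(), Z=model.design.Z,
                        n_positions=int(position_mask.sum()),
                        p_k=model.design.p_k)
    return TileModel(y=model.y[row_mask], offsets=model.offsets[row_mask],
                     design=design, hyper=model.hyper, S_full=model.S_full)


def cv_objective(model: TileModel, folds: FoldAssignment,
                 lam: float, theta: float) -> float:
    """Out-of-fold NB log-likelihood of ``(lam, theta)`` on one tile.

    For each fold, coefficients are fitted on the remaining positions
    (held-out rows dropped, not zeroed) and the *unpenalized* NB
    log-likelihood is evaluated on the held-out rows; fold scores are
    summed.  A non-converged fold makes the objective ``-inf``.
    """
    hyper = Hyperparams(lam=lam, theta=theta, epsilon=model.hyper.epsilon)
    model = replace_hyper(model, hyper)
    n_samples = model.design.n_samples
    total = 0.0
    for fold in range(folds.n_folds):
        held = folds.labels == fold
        if held.all() or not held.any():
            raise InvalidArgumentError("each fold must be a proper subset")
        fit = newton_raphson_fit(_restrict_model(model, ~held))
        if not fit.converged:
            warnings.warn(f"fold {fold} did not converge at lam={lam:g}, "
                          f"theta={theta:g}", RuntimeWarning)
            return -np.inf
        row_mask = np.tile(held, n_samples)
        eta = model.offsets[row_mask] + model.design.X[row_mask] @ fit.beta
        total += nb_loglik(model.y[row_mask], np.exp(eta), theta)
    return total


def replace_hyper(model: TileModel, hyper: Hyperparams) -> TileModel:
    """Copy of a tile model with different hyperparameters."""
    return TileModel(y=model.y, offsets=model.offsets, design=model.design,
                     hyper=hyper, S_full=model.S_full)


@dataclass
class CVResult:
    """Outcome of the hyperparameter search."""

    lam: float
    theta: float
    objective: float
    evaluations: list[tuple[float, float, float]] = field(default_factory=list)
    tile_indices: list[int] | None = None


def optimize_hyperparams(models: list[TileModel], n_folds: int = DEFAULT_N_FOLDS,
                         block_bp: int = DEFAULT_BLOCK_BP, seed: int = 0,
                         n_starts: int = 3, max_evals: int = 50,
                         lam_bounds: tuple[float, float] = (1e-1, 1e6),
                         theta_bounds: tuple[float, float] = (1e-2, 1e4)
                         ) -> CVResult:
    """Joint Nelder-Mead search for ``(lambda, theta)`` maximizing the
    summed out-of-fold log-likelihood over the given tiles.

    Starts are drawn from a seeded log-uniform grid inside the bounds;
    each start runs at most ``max_evals`` objective evaluations.  Fold
    assignments are fixed per tile (seeded) so the objective is
    deterministic.
    """
    if not models:
        raise InvalidArgumentError("need at least one tile model")
    folds = [make_folds(m.design.n_positions, n_folds, block_bp, seed=seed + t)
             for t, m in enumerate(models)]
    log = []

    def objective(x: np.ndarray) -> float:
        lam, theta = 10.0 ** x[0], 10.0 ** x[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            val = sum(cv_objective(m, f, lam, theta)
                      for m, f in zip(models, folds))
        log.append((lam, theta, val))
        return -val if np.isfinite(val) else 1e300

    rng = np.random.default_rng(seed)
    lo = np.log10([lam_bounds[0], theta_bounds[0]])
    hi = np.log10([lam_bounds[1], theta_bounds[1]])
    if np.allclose(lo, hi):     # degenerate search space: evaluate the point
        val = objective(lo)
        if val >= 1e300:
            raise OptimizationError("the single candidate point failed")
        return CVResult(lam=float(10.0 ** lo[0]), theta=float(10.0 ** lo[1]),
                        objective=float(-val), evaluations=log)
    starts = lo + (hi - lo) * rng.random((n_starts, 2))
    best_x, best_val = None, np.inf
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options=dict(maxfev=max_evals, xatol=0.05, fatol=0.5))
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    if best_x is None or best_val >= 1e300:
        raise OptimizationError("every hyperparameter candidate failed")
    return CVResult(lam=float(10.0 ** best_x[0]), theta=float(10.0 ** best_x[1]),
                    objective=float(-best_val), evaluations=log)
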