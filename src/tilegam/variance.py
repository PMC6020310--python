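"""Pointwise standard errors via the sparse inverse subset (Takahashi)
algorithm.

The covariance of the penalized coefficient estimate is ``(-H)^{-1}``
where ``H`` is the (negative definite) Hessian of the penalized NB
log-likelihood.  ``H`` is banded but its inverse is dense — yet the
pointwise variance

    Var f_k(x_i) = diag(X_k (-H_k)^{-1} X_k')_i

only touches entries ``(l, j)`` of the inverse for which some basis row
has both ``X_il`` and ``X_ij`` nonzero.  Every such pair is a nonzero of
``X'X`` and hence of ``H`` itself, so the entries of the inverse on the
sparsity pattern of the Cholesky factor suffice.  Those entries are
produced exactly by the Takahashi recursion run backwards over the
factor's fill pattern, in time linear in the number of coefficients for
banded problems.

Two independent routes to the same variances are provided:

* :func:`takahashi_inverse_subset` + :func:`smooth_variances` — the
  default, linear-time path;
* :func:`indirect_variances` — row-batched triangular solves
  ``sigma^2_i = sum_j ((X P' L^{-1})_{ij})^2``, quadratic-time, used as a
  cross-check and fallback.

Because Cholesky needs a positive definite input, all routines factor
``A = -H`` and the sign is restored where the inverse of ``H`` itself is
requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve_triangular
from scipy.stats import norm

from ._errors import FactorizationError, InvalidArgumentError, PatternError


@dataclass(frozen=True)
class CholeskyFactorization:
    """Sparse Cholesky ``A[perm][:, perm] = L L'`` of an SPD matrix.

    ``perm`` is the fill-reducing permutation as an index vector: row/column
    ``i`` of the permuted matrix is row/column ``perm[i]`` of ``A``.
    """

    L: sp.csc_matrix
    perm: np.ndarray

    @property
    def n(self) -> int:
        return self.L.shape[0]


def sparse_cholesky(a: sp.spmatrix, ordering: str = "fill_reducing") -> CholeskyFactorization:
    """Cholesky factorization of a sparse SPD matrix via SuperLU.

    With symmetric mode and no diagonal pivoting the LU factorization of
    an SPD matrix satisfies ``U = D L'`` with ``D = diag(U) > 0``, so the
    Cholesky factor is ``L sqrt(D)``.  ``ordering`` is either
    ``"fill_reducing"`` (minimum degree on ``A' + A``) or ``"natural"``.
    """
    a = sp.csc_matrix(a)
    if a.shape[0] != a.shape[1]:
        raise InvalidArgumentError("matrix must be square")
    if abs(a - a.T).max() > 1e-10 * max(1.0, abs(a).max()):
        raise InvalidArgumentError("matrix must be symmetric")
    spec = {"fill_reducing": "MMD_AT_PLUS_A", "natural": "NATURAL"}.get(ordering)
    if spec is None:
        raise InvalidArgumentError(f"unknown ordering {ordering!r}")
    try:
        lu = splu(a, permc_spec=spec, diag_pivot_thresh=0.0,
                  options=dict(SymmetricMode=True))
    except RuntimeError as exc:
        raise FactorizationError(f"sparse LU failed: {exc}") from exc
    if not np.array_equal(lu.perm_r, lu.perm_c):
        raise FactorizationError("unsymmetric pivoting occurred; matrix not SPD?")
    d = lu.U.diagonal()
    if (d <= 0).any() or not np.isfinite(d).all():
        raise FactorizationError("matrix is not positive definite")
    factor = (lu.L @ sp.diags(np.sqrt(d))).tocsc()
    factor.sort_indices()
    return CholeskyFactorization(L=factor, perm=np.argsort(lu.perm_c))


@dataclass(frozen=True)
class InverseSubset:
    """Entries of a matrix inverse on the Cholesky fill pattern.

    ``matrix`` is sparse, symmetric, in the *original* (unpermuted)
    ordering; its stored entries equal the corresponding entries of the
    full inverse exactly, and its pattern contains every nonzero position
    of the factored matrix.  ``op_count`` tallies the multiply-adds spent
    in the Takahashi recursion (used to verify linear scaling).
    """

    matrix: sp.csc_matrix
    op_count: int

    def get(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])


def takahashi_inverse_subset(chol: CholeskyFactorization) -> InverseSubset:
    """Values of ``A^{-1}`` on the fill pattern of ``L + L'``.

    Writing ``A_perm = L~ D L~'`` (unit lower factor, ``D = diag(L)^2``),
    the recursion over columns ``j = n-1 .. 0`` is

        Z_jj = 1/D_j - sum_k  L~_kj Z_kj
        Z_ij = -sum_k L~_kj Z_ik        (i > j, (i, j) in pattern)

    with ``k`` running over the below-diagonal pattern of column ``j``.
    Cholesky fill patterns are closed under the elimination tree, so
    every ``Z_ik`` needed has been computed by a later column.
    """
    lmat = chol.L
    n = lmat.shape[0]
    indptr, indices, data = lmat.indptr, lmat.indices, lmat.data
    z: dict[tuple[int, int], float] = {}
    ops = 0
    for j in range(n - 1, -1, -1):
        lo, hi = indptr[j], indptr[j + 1]
        rows = indices[lo:hi]
        vals = data[lo:hi]
        # csc with sorted indices: diagonal first
        dj = vals[0]
        sub = rows[1:]
        lt = vals[1:] / dj                      # unit-factor column
        m = len(sub)
        for a in range(m):
            i = sub[a]
            s = 0.0
            for b in range(m):
                k = sub[b]
                s += lt[b] * (z[(i, k)] if i >= k else z[(k, i)])
            ops += m
            z[(i, j)] = -s
        s = 0.0
        for b in range(m):
            s += lt[b] * z[(sub[b], j)]
        ops += m
        z[(j, j)] = 1.0 / (dj * dj) - s
    if z:
        keys = np.array(list(z.keys()), dtype=np.int64)
        values = np.fromiter(z.values(), dtype=float, count=len(z))
    else:                                        # pragma: no cover
        keys = np.zeros((0, 2), dtype=np.int64)
        values = np.zeros(0)
    # map back to the original ordering and symmetrize
    rows = chol.perm[keys[:, 0]]
    cols = chol.perm[keys[:, 1]]
    off = keys[:, 0] != keys[:, 1]
    mat = sp.coo_matrix(
        (np.concatenate([values, values[off]]),
         (np.concatenate([rows, cols[off]]), np.concatenate([cols, rows[off]]))),
        shape=(n, n)).tocsc()
    return InverseSubset(matrix=mat, op_count=ops)


def hessian_inverse_subset(h: sp.spmatrix,
                           ordering: str = "fill_reducing") -> InverseSubset:
    """Inverse subset of a negative definite Hessian: factor ``A = -H``
    and negate, so stored entries equal those of ``H^{-1}`` (negative on
    the diagonal)."""
    subset = takahashi_inverse_subset(sparse_cholesky(-sp.csc_matrix(h), ordering))
    return InverseSubset(matrix=(-subset.matrix).tocsc(), op_count=subset.op_count)


def _check_pattern_sufficiency(pattern: sp.spmatrix, basis: sp.spmatrix) -> None:
    """Verify every pair ``(l, j)`` with ``X_il X_ij != 0`` for some row i
    lies in the inverse-subset pattern."""
    needed = ((abs(basis).T @ abs(basis)) > 0).astype(np.int8)
    have = (abs(pattern) > 0).astype(np.int8)
    missing = needed - needed.multiply(have)
    if missing.nnz:
        i, j = missing.nonzero()
        raise PatternError(
            f"inverse-subset pattern is missing required entries, e.g. "
            f"({i[0]}, {j[0]}); this contradicts the Hessian-pattern "
            f"sufficiency argument and indicates a bug")


def smooth_variances(subset: InverseSubset, basis: sp.spmatrix) -> np.ndarray:
    """Pointwise variances ``diag(X_k Cov X_k')`` from an inverse subset.

    ``subset`` must hold the inverse of the *negated* per-smooth Hessian
    block (i.e. the coefficient covariance; see
    :func:`hessian_inverse_subset` for the signed variant).  Only the
    first sparse product is formed, multiplied elementwise with the basis
    and summed over columns — no dense matrix ever appears.
    """
    basis = sp.csr_matrix(basis)
    cov = subset.matrix
    if (cov.diagonal() < 0).all():       # an H^{-1} subset: flip to covariance
        cov = -cov
    _check_pattern_sufficiency(cov, basis)
    first = basis @ cov
    var = np.asarray(first.multiply(basis).sum(axis=1)).ravel()
    if (var <= 0).any():
        raise InvalidArgumentError("non-positive variance computed; "
                                   "is the Hessian negative definite?")
    return var


def indirect_variances(chol: CholeskyFactorization, basis: sp.spmatrix,
                       batch_size: int = 256) -> np.ndarray:
    """Variances by triangular solves: ``sigma^2_i = ||L^{-1} x_i||^2``
    with ``x_i`` the permuted i-th basis row; computed in row batches to
    bound memory.  Quadratic-time oracle / fallback for
    :func:`smooth_variances`."""
    basis = sp.csr_matrix(basis)
    xperm = basis[:, chol.perm].tocsr()
    lcsr = chol.L.tocsr()
    n = basis.shape[0]
    out = np.empty(n)
    for start in range(0, n, batch_size):
        block = xperm[start:start + batch_size].toarray()
        g = spsolve_triangular(lcsr, block.T, lower=True)
        out[start:start + batch_size] = (g * g).sum(axis=0)
    return out


def tile_standard_errors(h: sp.spmatrix, basis: sp.spmatrix, n_smooths: int,
                         ordering: str = "fill_reducing",
                         derivative_basis: sp.spmatrix | None = None) -> np.ndarray:
    """Per-position standard errors of every smooth from the full tile
    Hessian.

    The per-smooth Hessian block ``H_k`` is extracted from ``H``, negated,
    factorized, run through the Takahashi recursion, and contracted with
    the basis rows.  Returns an (n_positions x K) array of standard
    errors, or of the standard errors of the first derivative when
    ``derivative_basis`` is given.
    """
    h = sp.csc_matrix(h)
    p = h.shape[0] // n_smooths
    rows = (derivative_basis if derivative_basis is not None else basis)
    out = np.empty((rows.shape[0], n_smooths))
    for k in range(n_smooths):
        block = h[k * p:(k + 1) * p, k * p:(k + 1) * p]
        chol = sparse_cholesky(-block, ordering)
        subset = takahashi_inverse_subset(chol)
        out[:, k] = np.sqrt(smooth_variances(subset, rows))
    return out


def pointwise_pvalues(values: np.ndarray, variances: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Gaussian z-test per base: ``z = f / sigma``,
    ``p = 2 Phi(-|z|)``."""
    variances = np.asarray(variances, dtype=float)
    if (variances <= 0).any():
        raise InvalidArgumentError("variances must be strictly positive")
    z = np.asarray(values, dtype=float) / np.sqrt(variances)
    return z, 2.0 * norm.sf(np.abs(z))
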