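"""Exception hierarchy.

All user-facing errors derive from :class:`TileGamError` so callers can
catch one type at the CLI boundary.
"""


class TileGamError(Exception):
    """Base class for all tilegam errors."""


class InvalidArgumentError(TileGamError, ValueError):
    """A parameter violates a documented precondition."""


class OutOfDomainError(TileGamError, ValueError):
    """A genomic position falls outside the inner knot range of a basis."""


class InvalidDesignError(TileGamError, ValueError):
    """The experimental design matrix is degenerate (e.g. an all-zero smooth)."""


class NormalizationError(TileGamError, ValueError):
    """Size factors are undefined (no bin with positive counts in all samples)."""


class NumericalError(TileGamError, ArithmeticError):
    """A linear solve or factorization failed."""


class FactorizationError(NumericalError):
    """Sparse Cholesky factorization failed (matrix not positive definite)."""


class PatternError(TileGamError, AssertionError):
    """An index pair required by the variance computation is missing from the
    computed sparse-inverse pattern.  This indicates an internal bug: the
    nonzero pattern of the Hessian provably covers every pair needed."""


class NoSignalError(TileGamError, ValueError):
    """The coverage track contains no counts at all."""


class AssemblyError(TileGamError, RuntimeError):
    """A chunk-owning tile fit is missing or did not converge."""


class OptimizationError(TileGamError, RuntimeError):
    """Hyperparameter search failed on every candidate."""
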