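"""Experimental design: the indicator matrix Z, the full tile design
X = Z ⊗ X_k, and sequencing-depth offsets.

Each ChIP-seq sample is a row of the binary matrix ``Z``; each column
selects the samples to which one smooth function contributes.  The
classical two-condition comparison uses ``Z = [[1, 0], [1, 1]]``: a
background smooth shared by both samples plus a log fold-change smooth
active only in the treatment.  The full design for one tile is the
Kronecker product of ``Z`` with the per-position spline basis, laid out
sample-major (all positions of sample 1, then sample 2, ...).

Sequencing depth is absorbed into known offsets: per-sample size factors
estimated by the median-of-ratios rule on genome bins, geometric-mean
centered, and entered as ``log`` size factor constants in the linear
predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._errors import InvalidArgumentError, InvalidDesignError, NormalizationError

#: default genome bin width (bp) on which size factors are estimated
DEFAULT_SIZE_FACTOR_BIN = 1000


@dataclass(frozen=True)
class SampleTable:
    """Sample sheet: one row per sample, one indicator column per smooth."""

    sample_ids: list[str]
    Z: np.ndarray                # (n_samples, K) binary
    smooth_names: list[str]
    bam_paths: list[str] | None = None

    def __post_init__(self):
        z = np.asarray(self.Z)
        if z.ndim != 2 or z.shape[0] < 1 or z.shape[1] < 1:
            raise InvalidDesignError("need at least one sample and one smooth")
        if not np.isin(z, (0, 1)).all():
            raise InvalidDesignError("design indicators must be 0 or 1")
        if (z.sum(axis=0) == 0).any():
            dead = [self.smooth_names[k] for k in np.flatnonzero(z.sum(axis=0) == 0)]
            raise InvalidDesignError(f"smooth(s) {dead} apply to no sample")

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_smooths(self) -> int:
        return self.Z.shape[1]


def read_sample_table(path) -> SampleTable:
    """Read a tab-separated sample sheet.

    Expected header: ``sample_id``, ``bam``, then one 0/1 column per smooth.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise InvalidArgumentError("sample table must have a 'sample_id' column")
    smooth_cols = [c for c in df.columns if c not in ("sample_id", "bam")]
    if not smooth_cols:
        raise InvalidDesignError("sample table declares no smooth columns")
    return SampleTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        Z=df[smooth_cols].to_numpy(dtype=float),
        smooth_names=smooth_cols,
        bam_paths=df["bam"].astype(str).tolist() if "bam" in df.columns else None,
    )


@dataclass(frozen=True)
class FullDesign:
    """Full tile design ``X = Z ⊗ X_k``, sample-major row order.

    Row ``j * n_positions + i`` corresponds to sample ``j`` at position
    ``i``; column ``k * p_k + r`` to coefficient ``r`` of smooth ``k``.
    """

    X: sp.csr_matrix
    Z: np.ndarray
    n_positions: int
    p_k: int

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_smooths(self) -> int:
        return self.Z.shape[1]


def build_design(samples: SampleTable | np.ndarray, basis: sp.spmatrix) -> FullDesign:
    """Form the full design ``X = Z ⊗ X_k`` as a sparse matrix."""
    z = samples.Z if isinstance(samples, SampleTable) else np.asarray(samples, dtype=float)
    if z.ndim != 2:
        raise InvalidDesignError("Z must be a 2-d indicator matrix")
    if (z.sum(axis=0) == 0).any():
        raise InvalidDesignError("every smooth needs at least one active sample")
    basis = sp.csr_matrix(basis)
    x = sp.kron(sp.csr_matrix(z), basis, format="csr")
    return FullDesign(X=x, Z=z, n_positions=basis.shape[0], p_k=basis.shape[1])


def compute_size_factors(binned_counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors from a (bins x samples) count matrix.

    For each bin the geometric mean across samples is the pseudo-reference;
    a sample's factor is the median over bins of its count over the
    reference, computed on bins where every sample has a positive count.
    Factors are geometric-mean centered so their log offsets sum to zero.
    """
    counts = np.asarray(binned_counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    if counts.shape[1] == 1:
        return np.ones(1)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no genome bin has positive counts in every sample; "
            "size factors are undefined")
    logc = np.log(counts[positive])
    log_ref = logc.mean(axis=1, keepdims=True)
    log_factors = np.median(logc - log_ref, axis=0)
    log_factors -= log_factors.mean()      # geometric-mean centering
    return np.exp(log_factors)


def bin_counts(coverage: np.ndarray, bin_size: int = DEFAULT_SIZE_FACTOR_BIN) -> np.ndarray:
    """Sum a (samples x length) per-base count matrix into genome bins.

    Returns a (bins x samples) matrix suitable for
    :func:`compute_size_factors`.  A trailing partial bin is kept.
    """
    cov = np.atleast_2d(np.asarray(coverage))
    n = cov.shape[1]
    edges = np.arange(0, n + bin_size, bin_size)
    edges[-1] = n
    return np.add.reduceat(cov, edges[:-1], axis=1).T


def offsets_for_samples(size_factors: np.ndarray, n_positions: int) -> np.ndarray:
    """Expand per-sample log size factors to the sample-major data layout."""
    sf = np.asarray(size_factors, dtype=float)
    if not np.isfinite(np.log(sf)).all():
        raise InvalidArgumentError("size factors must be positive and finite")
    return np.repeat(np.log(sf), n_positions)
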