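"""Genome-wide orchestration: fit every tile, join at overlap midpoints,
persist chunked tracks.

Tiles are fitted independently (they share no mutable state, so the work
parallelizes trivially); the final per-base value of every smooth and
its standard error are taken from the single tile whose *chunk* contains
the base — hard ownership at the overlap midpoint, no blending.  Results
live either in memory (small genomes) or in pre-initialized HDF5
datasets written chunk-by-chunk, one writer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from ._errors import AssemblyError, InvalidArgumentError
from .design import SampleTable, build_design, offsets_for_samples
from .fitting import Hyperparams, TileModel, newton_raphson_fit, hessian, smooth_values
from .ingest import TileLayout, make_tiles, DEFAULT_TILE_SIZE, DEFAULT_OVERLAP
from .splines import place_knots, evaluate_basis, DEFAULT_KNOT_SPACING
from .variance import tile_standard_errors, pointwise_pvalues


@dataclass
class TileFitResult:
    """One tile's contribution: per-position smooth values and standard
    errors over the whole tile span, plus diagnostics."""

    tile_index: int
    start: int
    end: int
    values: np.ndarray | None       # (tile_len x K)
    se: np.ndarray | None           # (tile_len x K)
    converged: bool
    iterations: int
    grad_norm: float


@dataclass
class GenomeFit:
    """Assembled per-base tracks for one chromosome.

    ``values[k][x]`` is the fitted log-occupancy (or log fold-change) of
    smooth ``k`` at base ``x``; ``se`` its standard error.  Non-converged
    chunks are NaN-masked and listed in ``diagnostics``.
    """

    chrom: str
    smooth_names: list[str]
    values: np.ndarray | None       # (K x length); None if left on disk
    se: np.ndarray | None           # (K x length)
    layout: TileLayout
    hyper: Hyperparams
    diagnostics: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_smooths(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]

    @property
    def all_converged(self) -> bool:
        return bool(self.diagnostics["converged"].all())


def fit_tile(counts: np.ndarray, offsets_per_sample: np.ndarray, Z: np.ndarray,
             start: int, end: int, hyper: Hyperparams,
             knot_spacing: float = DEFAULT_KNOT_SPACING) -> tuple:
    """Fit one tile and return (values, se, fit_state).

    ``counts`` is the (samples x tile_len) slice for this tile;
    positions are absolute genomic coordinates so adjacent tiles place
    identical knots over their shared overlap.
    """
    knots = place_knots(start, end - 1, knot_spacing)
    positions = np.arange(start, end, dtype=float)
    basis = evaluate_basis(knots, positions)
    design = build_design(Z, basis)
    offsets = offsets_for_samples(np.exp(offsets_per_sample), end - start)
    model = TileModel(y=counts.ravel(), offsets=offsets, design=design,
                      hyper=hyper)
    fit = newton_raphson_fit(model)
    values = smooth_values(design, basis, fit.beta)
    h = hessian(model, fit.beta)
    se = tile_standard_errors(h, basis, design.n_smooths)
    return values, se, fit


def _fit_one(args) -> TileFitResult:
    (idx, start, end, counts, log_sf, z, hyper, knot_spacing) = args
    try:
        values, se, fit = fit_tile(counts, log_sf, z, start, end, hyper,
                                   knot_spacing)
        return TileFitResult(idx, start, end, values, se, fit.converged,
                             fit.iterations, fit.grad_norm)
    except Exception as exc:      # a failed tile masks its chunk, not the run
        warnings.warn(f"tile {idx} [{start}, {end}) failed: {exc}",
                      RuntimeWarning)
        return TileFitResult(idx, start, end, None, None, False, 0, np.nan)


def fit_genome(counts: np.ndarray, samples: SampleTable | np.ndarray,
               hyper: Hyperparams, chrom: str = "chr",
               size_factors: np.ndarray | None = None,
               tile_size: int = DEFAULT_TILE_SIZE, overlap: int = DEFAULT_OVERLAP,
               knot_spacing: float = DEFAULT_KNOT_SPACING,
               workers: int = 1, smooth_names: list[str] | None = None,
               backend: str = "memory", h5_path: str | None = None,
               materialize: bool = True) -> GenomeFit:
    """Fit all tiles of one chromosome and assemble chunk-owned tracks.

    ``counts`` is the (samples x length) per-base count matrix.  Tile
    computations are pure functions of their inputs, so any worker count
    yields bit-identical output; with ``workers > 1`` tiles are fitted in
    parallel processes and writing stays in the calling process (single
    writer).

    With ``backend="hdf5"`` the output datasets are created on disk at
    full genome size up front and each tile's chunk is written as soon
    as it is fitted, so peak memory stays proportional to one tile, not
    the genome.  ``materialize=False`` then leaves ``values``/``se`` of
    the returned object as ``None`` (the data lives in ``h5_path``).
    """
    counts = np.atleast_2d(np.asarray(counts))
    z = samples.Z if isinstance(samples, SampleTable) else np.asarray(samples, float)
    names = (samples.smooth_names if isinstance(samples, SampleTable)
             else smooth_names or [f"f{k}" for k in range(z.shape[1])])
    if counts.shape[0] != z.shape[0]:
        raise InvalidArgumentError("one count row per sample required")
    if backend == "hdf5" and h5_path is None:
        raise InvalidArgumentError("hdf5 backend requires h5_path")
    if backend not in ("memory", "hdf5"):
        raise InvalidArgumentError(f"unknown backend {backend!r}")
    length = counts.shape[1]
    layout = make_tiles(length, tile_size, overlap)
    sf = np.ones(z.shape[0]) if size_factors is None else np.asarray(size_factors)
    log_sf = np.log(sf)
    provenance = dict(package="tilegam", version=__version__,
                      tile_size=tile_size, overlap=overlap,
                      knot_spacing=knot_spacing, size_factors=sf.tolist(),
                      lam=hyper.lam, theta=hyper.theta, epsilon=hyper.epsilon)

    # lazy: one tile's counts are sliced only when its job is dispatched
    jobs = ((i, s, e, counts[:, s:e], log_sf, z, hyper, knot_spacing)
            for i, (s, e) in enumerate(layout.tiles))

    def results_in_order():
        if workers > 1:
            from joblib import Parallel, delayed
            # generator backend yields tiles as they finish; submission
            # order is preserved, so writes land deterministically
            yield from Parallel(n_jobs=workers, return_as="generator")(
                delayed(_fit_one)(j) for j in jobs)
        else:
            for j in jobs:
                yield _fit_one(j)

    k = z.shape[1]
    diag_rows = []
    if backend == "hdf5":
        import h5py

        chunk_len = min(max(ce - cs for cs, ce in layout.chunks), length)
        with h5py.File(h5_path, "w") as h5:
            h5.attrs["chrom"] = chrom
            h5.attrs["length"] = length
            for key, val in provenance.items():
                h5.attrs[f"provenance/{key}"] = val
            dsets = []
            for name in names:
                grp = h5.create_group(name)
                dsets.append((
                    grp.create_dataset("fit", shape=(length,), dtype="f8",
                                       chunks=(chunk_len,), fillvalue=np.nan),
                    grp.create_dataset("se", shape=(length,), dtype="f8",
                                       chunks=(chunk_len,), fillvalue=np.nan)))
            for r in results_in_order():
                cs, ce = layout.chunks[r.tile_index]
                if r.values is not None and r.converged:
                    sl = slice(cs - r.start, ce - r.start)
                    for kk, (dfit, dse) in enumerate(dsets):
                        dfit[cs:ce] = r.values[sl, kk]
                        dse[cs:ce] = r.se[sl, kk]
                diag_rows.append(dict(tile=r.tile_index, start=r.start,
                                      end=r.end, converged=r.converged,
                                      iterations=r.iterations,
                                      grad_norm=r.grad_norm))
        values = se = None
        if materialize:
            tracks = read_tracks_h5(h5_path)
            values = np.vstack([tracks[n]["fit"] for n in names])
            se = np.vstack([tracks[n]["se"] for n in names])
    else:
        results = sorted(results_in_order(), key=lambda r: r.tile_index)
        values, se = join_tiles(results, layout, k)
        diag_rows = [dict(tile=r.tile_index, start=r.start, end=r.end,
                          converged=r.converged, iterations=r.iterations,
                          grad_norm=r.grad_norm) for r in results]
    diagnostics = pd.DataFrame(sorted(diag_rows, key=lambda d: d["tile"]))
    return GenomeFit(chrom=chrom, smooth_names=list(names), values=values,
                     se=se, layout=layout, hyper=hyper,
                     diagnostics=diagnostics, provenance=provenance)


def join_tiles(results: list[TileFitResult], layout: TileLayout,
               n_smooths: int) -> tuple[np.ndarray, np.ndarray]:
    """Assemble per-base tracks, each base owned by exactly one chunk.

    Returns (values, se) of shape (K x length); chunks of non-converged
    tiles are NaN.
    """
    if len(results) != layout.n_tiles:
        raise AssemblyError(
            f"expected {layout.n_tiles} tile fits, got {len(results)}")
    length = layout.chrom_length
    values = np.full((n_smooths, length), np.nan)
    se = np.full((n_smooths, length), np.nan)
    for r, (cs, ce) in zip(results, layout.chunks):
        if r.values is None or not r.converged:
            continue
        sl = slice(cs - r.start, ce - r.start)
        values[:, cs:ce] = r.values[sl].T
        se[:, cs:ce] = r.se[sl].T
    return values, se


def export_tracks(fit: GenomeFit, fmt: str, path,
                  pvalue_threshold: float = 0.05) -> None:
    """Persist assembled tracks.

    ``hdf5``: one group per smooth with ``fit`` and ``se`` datasets,
    chunked by chunk length (bit-exact round trip).  ``tsv``: dense
    per-base table.  ``bigwig``: one file pair per smooth
    (``<path>.<name>.{fit,se}.bw``).  ``bed``: merged runs of bases whose
    pointwise two-sided p-value is below ``pvalue_threshold``.
    """
    if fmt == "hdf5":
        import h5py

        chunk_len = min(max(ce - cs for cs, ce in fit.layout.chunks),
                        fit.length)
        with h5py.File(path, "w") as h5:
            h5.attrs["chrom"] = fit.chrom
            h5.attrs["length"] = fit.length
            for key, val in fit.provenance.items():
                h5.attrs[f"provenance/{key}"] = val
            for k, name in enumerate(fit.smooth_names):
                grp = h5.create_group(name)
                grp.create_dataset("fit", data=fit.values[k],
                                   chunks=(chunk_len,))
                grp.create_dataset("se", data=fit.se[k], chunks=(chunk_len,))
    elif fmt == "tsv":
        df = pd.DataFrame({"chrom": fit.chrom, "pos": np.arange(fit.length)})
        for k, name in enumerate(fit.smooth_names):
            df[f"{name}_fit"] = fit.values[k]
            df[f"{name}_se"] = fit.se[k]
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "bigwig":
        import pyBigWig

        for k, name in enumerate(fit.smooth_names):
            for track, arr in (("fit", fit.values[k]), ("se", fit.se[k])):
                bw = pyBigWig.open(f"{path}.{name}.{track}.bw", "w")
                bw.addHeader([(fit.chrom, fit.length)])
                bw.addEntries(fit.chrom, 0, values=arr.astype(np.float64),
                              span=1, step=1)
                bw.close()
    elif fmt == "bed":
        with open(path, "w") as out:
            for k, name in enumerate(fit.smooth_names):
                ok = np.isfinite(fit.values[k]) & (fit.se[k] > 0)
                _, pvals = pointwise_pvalues(
                    np.where(ok, fit.values[k], 0.0),
                    np.where(ok, fit.se[k] ** 2, 1.0))
                sig = ok & (pvals < pvalue_threshold)
                for s, e in _runs(sig):
                    out.write(f"{fit.chrom}\t{s}\t{e}\t{name}\n")
    else:
        raise InvalidArgumentError(f"unsupported export format {fmt!r}")


def read_tracks_h5(path) -> dict[str, dict[str, np.ndarray]]:
    """Read back an HDF5 export: ``{smooth: {'fit': ..., 'se': ...}}``."""
    import h5py

    out: dict[str, dict[str, np.ndarray]] = {}
    with h5py.File(path, "r") as h5:
        for name in h5:
            out[name] = {"fit": h5[name]["fit"][()], "se": h5[name]["se"][()]}
    return out


def _runs(mask: np.ndarray):
    """Half-open (start, end) runs of True in a boolean vector."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    yield from zip(starts.tolist(), ends.tolist())
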