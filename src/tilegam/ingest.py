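"""Read ingestion and genome tiling.

Fragments are reduced to their center base: the midpoint of the template
span for proper pairs, or the 5' start shifted by half the user-supplied
fragment length for single-end reads.  Coverage is the per-base count of
fragment centers — no binning, no smoothing; the model operates at
base-pair resolution.

Chromosomes are cut into overlapping *tiles*, each fitted independently,
and disjoint *chunks* (tile interiors bounded by overlap midpoints) that
own the final per-base output.  Chunks partition the chromosome exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import InvalidArgumentError

DEFAULT_TILE_SIZE = 24_000
DEFAULT_OVERLAP = 3_000


@dataclass
class QCSummary:
    """Per-file ingestion accounting."""

    retained: int = 0
    unmapped: int = 0
    secondary: int = 0
    duplicate: int = 0
    qcfail: int = 0
    improper_pair: int = 0
    clipped: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def center_fragments(bam_path: str, chrom: str, fragment_length: int | None = None,
                     drop_duplicates: bool = False) -> tuple[np.ndarray, QCSummary]:
    """Fragment center positions for one chromosome of an indexed BAM.

    Paired-end: centers are template midpoints, taken once per pair from
    the leftmost mate.  Single-end: the 5' start is shifted inward by
    ``fragment_length // 2`` along the read orientation;
    ``fragment_length`` is then required.  Secondary, supplementary,
    unmapped and QC-fail records are skipped and tallied; duplicates are
    kept unless ``drop_duplicates``.
    """
    import pysam

    if not (os.path.exists(bam_path + ".bai")
            or os.path.exists(os.path.splitext(bam_path)[0] + ".bai")
            or os.path.exists(bam_path + ".csi")):
        raise IOError(f"BAM index not found for {bam_path}")
    qc = QCSummary()
    centers: list[int] = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for read in bam.fetch(chrom):
            if read.is_unmapped:
                qc.unmapped += 1
                continue
            if read.is_secondary or read.is_supplementary:
                qc.secondary += 1
                continue
            if read.is_qcfail:
                qc.qcfail += 1
                continue
            if read.is_duplicate:
                qc.duplicate += 1
                if drop_duplicates:
                    continue
            if read.is_paired:
                if not read.is_proper_pair:
                    qc.improper_pair += 1
                    continue
                # count each template once, from the leftmost mate
                if read.template_length <= 0:
                    continue
                center = read.reference_start + read.template_length // 2
            else:
                if fragment_length is None:
                    raise InvalidArgumentError(
                        "fragment_length is required for single-end reads")
                if read.is_reverse:
                    center = (read.reference_end - 1) - fragment_length // 2
                else:
                    center = read.reference_start + fragment_length // 2
            centers.append(center)
            qc.retained += 1
    return np.asarray(centers, dtype=np.int64), qc


def compute_coverage(centers: np.ndarray, chrom_length: int,
                     qc: QCSummary | None = None) -> np.ndarray:
    """Per-base counts of fragment centers; out-of-range centers are
    clipped to the nearest boundary and tallied in ``qc.clipped``."""
    centers = np.asarray(centers, dtype=np.int64)
    if centers.size == 0:
        return np.zeros(chrom_length, dtype=np.int64)
    out_of_range = int(((centers < 0) | (centers >= chrom_length)).sum())
    if out_of_range and qc is not None:
        qc.clipped += out_of_range
    clipped = np.clip(centers, 0, chrom_length - 1)
    return np.bincount(clipped, minlength=chrom_length).astype(np.int64)


@dataclass(frozen=True)
class TileLayout:
    """Overlapping tiles and the disjoint chunks they own.

    ``tiles[i] = (start, end)`` half-open; ``chunks[i]`` is the interval of
    bases whose final fitted values come from tile ``i``.  Interior chunk
    boundaries sit at the midpoints of tile overlaps; the first and last
    chunks extend to the chromosome boundaries.
    """

    chrom_length: int
    tile_size: int
    overlap: int
    tiles: tuple[tuple[int, int], ...]
    chunks: tuple[tuple[int, int], ...]

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)


def make_tiles(chrom_length: int, tile_size: int = DEFAULT_TILE_SIZE,
               overlap: int = DEFAULT_OVERLAP) -> TileLayout:
    """Lay out overlapping tiles advancing by ``tile_size - overlap``.

    The final tile is pinned to end exactly at ``chrom_length`` (its
    overlap with the previous tile may exceed ``overlap``).  A chromosome
    shorter than one tile gets a single tile covering it entirely.
    """
    if chrom_length <= 0:
        raise InvalidArgumentError("chromosome length must be positive")
    if overlap <= 0 or overlap >= tile_size:
        raise InvalidArgumentError(
            f"need 0 < overlap < tile_size, got overlap={overlap}, "
            f"tile_size={tile_size}")
    if chrom_length <= tile_size:
        return TileLayout(chrom_length, tile_size, overlap,
                          tiles=((0, chrom_length),),
                          chunks=((0, chrom_length),))
    step = tile_size - overlap
    starts = list(range(0, chrom_length - tile_size, step))
    last = chrom_length - tile_size
    if starts[-1] != last:
        starts.append(last)
    tiles = tuple((s, s + tile_size) for s in starts)
    boundaries = [0]
    for i in range(1, len(tiles)):
        boundaries.append((tiles[i][0] + tiles[i - 1][1]) // 2)
    boundaries.append(chrom_length)
    chunks = tuple((boundaries[i], boundaries[i + 1]) for i in range(len(tiles)))
    return TileLayout(chrom_length, tile_size, overlap, tiles, chunks)


def read_track_tsv(path) -> tuple[str, np.ndarray, list[str]]:
    """Read a per-base count track: columns chrom, pos, then one per sample.

    Returns (chrom, counts of shape (samples, length), sample names).
    Positions absent from the file are zero.
    """
    df = pd.read_csv(path, sep="\t")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise InvalidArgumentError("track TSV must contain a single chromosome")
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    length = int(df["pos"].max()) + 1
    counts = np.zeros((len(sample_cols), length), dtype=np.int64)
    pos = df["pos"].to_numpy()
    for s, col in enumerate(sample_cols):
        counts[s, pos] = df[col].to_numpy()
    return str(chroms[0]), counts, sample_cols


def write_track_tsv(path, chrom: str, counts: np.ndarray,
                    sample_names: list[str] | None = None) -> None:
    """Write a (samples x length) count matrix as a dense per-base TSV."""
    counts = np.atleast_2d(counts)
    names = sample_names or [f"sample{j + 1}" for j in range(counts.shape[0])]
    df = pd.DataFrame({"chrom": chrom, "pos": np.arange(counts.shape[1])})
    for name, row in zip(names, counts):
        df[name] = row
    df.to_csv(path, sep="\t", index=False)


def write_counts_h5(path, chrom: str, counts: np.ndarray, layout: TileLayout) -> None:
    """Store per-base counts in HDF5, chunked by tile size for fast
    per-tile reads."""
    import h5py

    counts = np.atleast_2d(counts)
    with h5py.File(path, "a") as h5:
        grp = h5.require_group("counts")
        if chrom in grp:
            del grp[chrom]
        grp.create_dataset(chrom, data=counts,
                           chunks=(counts.shape[0],
                                   min(layout.tile_size, counts.shape[1])))


def read_counts_h5(path, chrom: str) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as h5:
        return h5["counts"][chrom][()]
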