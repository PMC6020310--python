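"""Synthetic ChIP-seq-like data with known ground truth.

Each smooth log-occupancy function is a baseline plus a sum of Gaussian
bumps — deliberately *not* a spline, so the estimator's basis never
trivially matches the truth.  Per-sample means follow the factorial
model ``mu_j(x) = exp(log s_j + sum_k Z_jk f_k(x))`` with size factors
``s_j``, and counts are drawn negative-binomial with dispersion
``theta`` (variance ``mu + mu^2/theta``).  Optionally each count is
expanded into aligned read records whose fragment centers map back to
the originating base, closing the loop with the ingestion module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import InvalidArgumentError


@dataclass(frozen=True)
class BumpSmooth:
    """One true smooth: ``f(x) = baseline + sum_b h_b exp(-(x-c_b)^2 / 2 w_b^2)``."""

    centers: tuple[float, ...]
    widths: tuple[float, ...]
    heights: tuple[float, ...]
    baseline: float = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        f = np.full_like(x, self.baseline)
        for c, w, h in zip(self.centers, self.widths, self.heights):
            f += h * np.exp(-0.5 * ((x - c) / w) ** 2)
        return f


@dataclass(frozen=True)
class SimConfig:
    """Generative configuration; ``seed`` is mandatory for reproducibility."""

    length: int
    smooths: tuple[BumpSmooth, ...]
    Z: np.ndarray
    theta: float
    seed: int
    size_factors: np.ndarray | None = None
    chrom: str = "chrSim"

    def __post_init__(self):
        if self.theta <= 0:
            raise InvalidArgumentError("theta must be positive")
        z = np.asarray(self.Z)
        if z.ndim != 2 or z.shape[1] != len(self.smooths):
            raise InvalidArgumentError(
                "Z must be (n_samples x n_smooths) matching the smooth list")
        if self.size_factors is not None and len(self.size_factors) != z.shape[0]:
            raise InvalidArgumentError("one size factor per sample required")

    @property
    def n_samples(self) -> int:
        return np.asarray(self.Z).shape[0]


@dataclass
class SimulatedDataset:
    """Ground truth plus one NB draw of per-base counts."""

    config: SimConfig
    truth: np.ndarray         # (length x K): f_k(x)
    mu: np.ndarray            # (samples x length)
    counts: np.ndarray        # (samples x length), integers

    @property
    def chrom(self) -> str:
        return self.config.chrom


def simulate_counts(config: SimConfig) -> SimulatedDataset:
    """Draw per-base NB counts for every sample under the factorial model."""
    x = np.arange(config.length, dtype=float)
    truth = np.column_stack([f(x) for f in config.smooths])
    z = np.asarray(config.Z, dtype=float)
    sf = (np.ones(config.n_samples) if config.size_factors is None
          else np.asarray(config.size_factors, dtype=float))
    mu = np.exp(np.log(sf)[:, None] + z @ truth.T)
    rng = np.random.default_rng(config.seed)
    # NB(mu, theta): numpy's parameterization is (n, p) with n = theta,
    # p = theta / (theta + mu)
    counts = rng.negative_binomial(config.theta, config.theta / (config.theta + mu))
    return SimulatedDataset(config=config, truth=truth, mu=mu,
                            counts=counts.astype(np.int64))


def simulate_fragments(dataset: SimulatedDataset, fragment_length: int = 200,
                       read_length: int = 50, paired: bool = False,
                       bam_path: str | None = None, sample: int | None = None):
    """Expand counts into read records whose centers map back exactly.

    Single-end records place the 5' start so that shifting by
    ``fragment_length // 2`` recovers the originating base, choosing the
    strand that keeps the read inside the chromosome; paired-end records
    span the full fragment.  When ``bam_path`` is given, a coordinate-
    sorted indexed BAM for one sample (``sample``, required when the
    dataset has several) is written and the path returned; otherwise a
    record list over all requested samples is returned.
    """
    import pysam

    length = dataset.config.length
    half = fragment_length // 2
    n_samples = dataset.counts.shape[0]
    if bam_path is not None and sample is None:
        if n_samples > 1:
            raise InvalidArgumentError(
                "BAM output is per sample; pass sample=<index>")
        sample = 0
    sample_range = range(n_samples) if sample is None else [sample]
    records = []       # (sample, serial, start, span, kind)
    shifted = 0
    for j in sample_range:
        bases = np.repeat(np.arange(length), dataset.counts[j])
        for serial, x in enumerate(bases):
            if paired:
                start = int(x) - half
                if start < 0 or start + fragment_length > length:
                    start = min(max(start, 0), length - fragment_length)
                    shifted += 1
                records.append((j, serial, start, fragment_length, "paired"))
            else:
                fwd_start = int(x) - half
                rev_end = int(x) + half + 1           # exclusive
                if fwd_start >= 0 and fwd_start + read_length <= length:
                    records.append((j, serial, fwd_start, read_length, "fwd"))
                elif rev_end <= length and rev_end - read_length >= 0:
                    records.append((j, serial, rev_end - read_length,
                                    read_length, "rev"))
                else:
                    records.append((j, serial, max(fwd_start, 0),
                                    read_length, "fwd"))
                    shifted += 1
    if shifted:
        import warnings
        warnings.warn(f"{shifted} fragment(s) overhung the chromosome and "
                      "were shifted inward", RuntimeWarning, stacklevel=2)
    if bam_path is None:
        return records
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": dataset.chrom, "LN": int(length)}]}
    unsorted = str(bam_path) + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for j, serial, start, span, kind in records:
            if kind == "paired":
                for mate in (0, 1):
                    a = pysam.AlignedSegment(bam.header)
                    a.query_name = f"s{j}:f{serial}"
                    a.reference_id = 0
                    a.query_sequence = "A" * read_length
                    a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                    a.cigarstring = f"{read_length}M"
                    a.flag = 0x1 | 0x2 | (0x40 if mate == 0 else 0x80)
                    if mate == 0:
                        a.reference_start = start
                        a.next_reference_start = start + span - read_length
                        a.template_length = span
                        a.flag |= 0x20
                    else:
                        a.reference_start = start + span - read_length
                        a.next_reference_start = start
                        a.template_length = -span
                        a.flag |= 0x10
                    a.next_reference_id = 0
                    bam.write(a)
            else:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"s{j}:f{serial}"
                a.reference_id = 0
                a.reference_start = start
                a.query_sequence = "A" * span
                a.query_qualities = pysam.qualitystring_to_array("I" * span)
                a.cigarstring = f"{span}M"
                a.flag = 0x10 if kind == "rev" else 0
                bam.write(a)
    pysam.sort("-o", str(bam_path), unsorted)
    pysam.index(str(bam_path))
    import os
    os.remove(unsorted)
    return str(bam_path)
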