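"""Per-window coverage extraction, control normalization and sample merging.

Coverage is computed as a per-base pileup of aligned read spans (no fragment
extension, strand ignored) and aggregated per window either as the mean
per-base depth (Gaussian emissions) or as the summed depth (negative-binomial
emissions, which need non-negative integer counts).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DimensionError, InputError
from .windows import GenomeWindows

log = logging.getLogger(__name__)

_BEDGRAPH_SUFFIXES = (".bedgraph", ".bdg", ".bg")
_ALIGNMENT_SUFFIXES = (".bam", ".sam", ".cram")


@dataclass
class CoverageMatrix:
    """Per-window signal: T windows x D samples.

    ``mode`` records how per-base depth was aggregated ("mean" or "sum");
    ``normalized`` is True after log2 control normalization, which is only
    legal in mean mode (values may then be negative).
    """

    windows: GenomeWindows
    values: np.ndarray  # (T, D)
    mode: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != len(self.windows):
            raise DimensionError(
                f"{self.values.shape[0]} rows for {len(self.windows)} windows"
            )
        if self.mode not in ("mean", "sum"):
            raise ConfigurationError(f"unknown aggregation mode {self.mode!r}")
        if self.normalized and self.mode != "mean":
            raise ConfigurationError("normalized coverage requires mode == 'mean'")
        if not self.normalized and (self.values < 0).any():
            raise ConfigurationError("unnormalized coverage must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def per_base_depth_from_alignments(path: str, chrom: str, length: int) -> np.ndarray:
    """Pileup of aligned read spans for one chromosome (no extension/shift)."""
    import pysam

    depth = np.zeros(length + 1, dtype=np.float64)
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as bam:
        if chrom not in bam.references:
            return depth[:-1]
        if bam.has_index():
            it = bam.fetch(chrom)
        else:
            # no index: stream the whole file and filter
            it = (r for r in bam if r.reference_name == chrom)
        for read in it:
            if read.is_unmapped:
                continue
            start = read.reference_start
            end = read.reference_end or start + read.query_length
            start = max(0, min(start, length))
            end = max(0, min(end, length))
            if end > start:
                depth[start] += 1
                depth[end] -= 1
    return np.cumsum(depth[:-1])


def per_base_depth_from_bedgraph(path: str, chrom: str, length: int) -> np.ndarray:
    """Expand a bedGraph track (0-based half-open) into per-base values."""
    depth = np.zeros(length, dtype=np.float64)
    seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise InputError(f"{path}:{lineno}: bad bedGraph line {line!r}")
            if fields[0] != chrom:
                continue
            seen = True
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            if start < 0 or end > length:
                raise InputError(
                    f"{path}:{lineno}: interval [{start},{end}) outside {chrom} "
                    f"of length {length}"
                )
            depth[start:end] += value
    if not seen:
        log.warning("chromosome %s not present in %s; coverage set to 0", chrom, path)
    return depth


def aggregate_depth(depth: np.ndarray, windows: GenomeWindows, chrom: str,
                    aggregator: str) -> np.ndarray:
    """Aggregate a per-base depth array over the windows of one chromosome."""
    sl = windows.chrom_slice(chrom)
    starts = np.array([w[1] for w in windows.windows[sl]], dtype=np.int64)
    sums = np.add.reduceat(depth, starts)
    if aggregator == "sum":
        return sums
    lengths = np.array([w[2] - w[1] for w in windows.windows[sl]], dtype=np.float64)
    return sums / lengths


def bin_coverage(source: str, windows: GenomeWindows, aggregator: str = "mean") -> CoverageMatrix:
    """Aggregate per-base coverage of one sample over a window grid.

    ``source`` is an alignment file (BAM/SAM, positions piled up over the
    aligned span) or a bedGraph coverage track. Returns a single-column
    :class:`CoverageMatrix`; sum-mode values are rounded to integers (with a
    warning if the track was fractional, as NB emissions need counts).
    """
    if aggregator not in ("mean", "sum"):
        raise ConfigurationError(f"unknown aggregator {aggregator!r}")
    if not os.path.exists(source):
        raise InputError(f"input file not found: {source}")
    is_alignment = source.endswith(_ALIGNMENT_SUFFIXES)
    if not is_alignment and not source.endswith(_BEDGRAPH_SUFFIXES):
        raise InputError(
            f"cannot infer format of {source!r}: expected one of "
            f"{_ALIGNMENT_SUFFIXES + _BEDGRAPH_SUFFIXES}"
        )

    columns = []
    for chrom in windows.chrom_order:
        length = windows.chrom_sizes[chrom]
        if is_alignment:
            depth = per_base_depth_from_alignments(source, chrom, length)
        else:
            depth = per_base_depth_from_bedgraph(source, chrom, length)
        columns.append(aggregate_depth(depth, windows, chrom, aggregator))
    values = np.concatenate(columns)

    if aggregator == "sum":
        rounded = np.rint(values)
        if not np.allclose(values, rounded):
            log.warning(
                "fractional values in %s rounded to integers for sum-mode coverage",
                source,
            )
        values = rounded
    return CoverageMatrix(windows=windows, values=values, mode=aggregator)


def normalize_with_control(chip: CoverageMatrix, control: CoverageMatrix) -> CoverageMatrix:
    """log2((chip + 1) / (control + 1)) per window.

    The pseudocount of 1 avoids division by zero and log of zero. Only
    defined for mean-mode coverage: the ratio is fractional, so the
    negative-binomial path (integer counts) cannot consume it.
    """
    if chip.windows is not control.windows and chip.windows != control.windows:
        raise DimensionError("ChIP and control were binned on different window grids")
    if chip.mode != "mean" or control.mode != "mean":
        raise ConfigurationError("control normalization requires mean-mode coverage")
    if chip.normalized or control.normalized:
        raise ConfigurationError("inputs to control normalization must be raw coverage")
    if control.n_samples != 1:
        raise ConfigurationError("exactly one control sample is supported")
    values = np.log2((chip.values + 1.0) / (control.values + 1.0))
    return CoverageMatrix(windows=chip.windows, values=values, mode="mean", normalized=True)


def combine_samples(columns: list[CoverageMatrix], strategy: str = "sum") -> CoverageMatrix:
    """Merge per-sample coverage columns.

    ``sum`` adds the signals window-wise into a single column; ``vector``
    stacks them into a T x D matrix so the HMM emits multivariate values.
    """
    if not columns:
        raise ConfigurationError("no coverage columns to combine")
    if strategy not in ("sum", "vector"):
        raise ConfigurationError(f"unknown combine strategy {strategy!r}")
    first = columns[0]
    for col in columns[1:]:
        if col.windows != first.windows:
            raise DimensionError("coverage columns use different window grids")
        if col.mode != first.mode:
            raise ConfigurationError("cannot combine mean-mode with sum-mode coverage")
        if col.normalized != first.normalized:
            raise ConfigurationError("cannot mix normalized and unnormalized columns")
    stacked = np.concatenate([c.values for c in columns], axis=1)
    if strategy == "vector":
        values = stacked
    else:
        values = stacked.sum(axis=1, keepdims=True)
    return CoverageMatrix(
        windows=first.windows, values=values, mode=first.mode, normalized=first.normalized
    )


def coverage_from_reads(reads: np.ndarray, chrom: str, windows: GenomeWindows,
                        aggregator: str = "mean") -> CoverageMatrix:
    """Bin an in-memory array of (start, end) read spans on one chromosome."""
    length = windows.chrom_sizes[chrom]
    depth = np.zeros(length + 1, dtype=np.float64)
    starts = np.clip(reads[:, 0], 0, length)
    ends = np.clip(reads[:, 1], 0, length)
    np.add.at(depth, starts, 1.0)
    np.add.at(depth, ends, -1.0)
    per_base = np.cumsum(depth[:-1])
    values = np.zeros(len(windows), dtype=float)
    values[windows.chrom_slice(chrom)] = aggregate_depth(per_base, windows, chrom, aggregator)
    if aggregator == "sum":
        values = np.rint(values)
    return CoverageMatrix(windows=windows, values=values, mode=aggregator)


def write_bedgraph(matrix: CoverageMatrix, path: str, sample: int = 0) -> None:
    """Debug dump of one coverage column as bedGraph (one line per window)."""
    with open(path, "w") as fh:
        for (chrom, start, end), value in zip(matrix.windows.windows, matrix.values[:, sample]):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
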