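"""Synthetic ChIP-seq generator with known truth peaks.

The generator emulates a broad-mark ChIP-seq experiment on a single
chromosome: fixed-width truth peaks are placed from template start
coordinates, background reads are sampled uniformly across the chromosome
at mean fold-coverage x, and peak reads are sampled uniformly within peaks
at mean fold-coverage y — so the realized mean coverage over peak regions
is x + y. Reads are sampled as genomic spans directly (no sequence, no
alignment), which preserves every coverage statistic the caller consumes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError
from .evaluate import IntervalSet

log = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 100
DEFAULT_CHROM = "chrS"

# the study grid: 18 fixed peak widths x 7 peak coverages x 6 noise coverages
GRID_PEAK_WIDTHS = (50, 100, 200, 400, 600, 800, 1000, 1500, 2000, 2500,
                    3000, 5000, 7500, 10_000, 20_000, 30_000, 40_000, 50_000)
GRID_PEAK_COVERAGES = (2, 3, 5, 10, 15, 20, 25)
GRID_NOISE_COVERAGES = (0.25, 0.5, 1, 2, 3, 5)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset."""

    genome_size: int
    template_starts: tuple[int, ...]
    peak_width: int
    peak_coverage: float  # y: mean fold-coverage contributed by peak reads
    noise_coverage: float  # x: mean fold-coverage contributed by background reads
    read_length: int = DEFAULT_READ_LENGTH
    seed: int = 0
    chrom: str = DEFAULT_CHROM

    def __post_init__(self) -> None:
        object.__setattr__(self, "template_starts", tuple(int(s) for s in self.template_starts))
        if self.peak_coverage < 0 or self.noise_coverage < 0:
            raise ConfigurationError("coverages must be non-negative")
        if self.peak_width < 1 or self.read_length < 1:
            raise ConfigurationError("peak width and read length must be positive")
        if self.peak_width < self.read_length:
            log.warning(
                "peak width %d is shorter than the read length %d; peak reads "
                "will overhang the truth intervals", self.peak_width, self.read_length,
            )
        if self.template_starts and self.genome_size <= max(self.template_starts) + self.peak_width:
            raise ConfigurationError("peaks extend beyond the genome end")
        if not self.template_starts:
            raise ConfigurationError("at least one template start is required")


class FixedWidthPeaks(NamedTuple):
    intervals: IntervalSet
    kept_indices: tuple[int, ...]


def make_fixed_width_peaks(template_starts, peak_width: int,
                           genome_size: int) -> FixedWidthPeaks:
    """Fixed-width truth peaks from template starts.

    Each template start s becomes [s, s + peak_width); a peak overlapping its
    retained predecessor is dropped, as is one running past the genome end.
    The kept index set is returned so that the same templates can be removed
    from peak sets of other widths, keeping peak counts comparable.
    """
    starts = [int(s) for s in template_starts]
    if starts != sorted(starts):
        raise ConfigurationError("template starts must be sorted ascending")
    kept: list[int] = []
    intervals: list[tuple[str, int, int]] = []
    prev_end = -1
    for i, s in enumerate(starts):
        end = s + peak_width
        if s < prev_end or end > genome_size:
            continue
        kept.append(i)
        intervals.append((DEFAULT_CHROM, s, end))
        prev_end = end
    if not intervals:
        raise ConfigurationError("no peaks survive overlap/end filtering")
    return FixedWidthPeaks(IntervalSet.from_intervals(intervals), tuple(kept))


def make_fixed_width_peak_sets(template_starts, peak_widths,
                               genome_size: int) -> dict[int, IntervalSet]:
    """Peak sets over several widths with a common retained template subset.

    Templates dropped at any width (overlap or genome end) are dropped at
    every width, so all sets contain the same number of peaks.
    """
    per_width = {w: make_fixed_width_peaks(template_starts, w, genome_size)
                 for w in peak_widths}
    common = set.intersection(*(set(fw.kept_indices) for fw in per_width.values()))
    if not common:
        raise ConfigurationError("no template survives filtering at every width")
    starts = [int(s) for s in template_starts]
    out = {}
    for w in peak_widths:
        out[w] = IntervalSet.from_intervals(
            (DEFAULT_CHROM, starts[i], starts[i] + w) for i in sorted(common)
        )
    return out


def n_reads(coverage: float, span_bp: int, read_length: int) -> int:
    """Reads needed for mean fold-coverage over a span: coverage*span/read_length."""
    if span_bp <= 0 or read_length <= 0:
        raise ConfigurationError("span and read length must be positive")
    if coverage < 0:
        raise ConfigurationError("coverage must be non-negative")
    return int(round(coverage * span_bp / read_length))


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reads: np.ndarray  # (N, 2) start/end spans, background first
    truth: IntervalSet

    def per_base_coverage(self) -> np.ndarray:
        depth = np.zeros(self.config.genome_size + 1)
        np.add.at(depth, self.reads[:, 0], 1.0)
        np.add.at(depth, self.reads[:, 1], -1.0)
        return np.cumsum(depth[:-1])

    def write_reads_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for start, end in self.reads:
                fh.write(f"{self.config.chrom}\t{start}\t{end}\n")

    def write_coverage_bedgraph(self, path: str) -> None:
        """Run-length-encoded per-base coverage track."""
        cov = self.per_base_coverage()
        change = np.flatnonzero(np.diff(cov)) + 1
        bounds = np.concatenate([[0], change, [len(cov)]])
        with open(path, "w") as fh:
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{self.config.chrom}\t{lo}\t{hi}\t{cov[lo]:g}\n")

    def write_truth_bed(self, path: str) -> None:
        self.truth.to_bed(path)

    def write_chrom_sizes(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.config.chrom}\t{self.config.genome_size}\n")

    def write_config(self, path: str) -> None:
        cfg = self.config
        with open(path, "w") as fh:
            for key in ("genome_size", "peak_width", "peak_coverage", "noise_coverage",
                        "read_length", "seed", "chrom"):
                fh.write(f"{key}: {getattr(cfg, key)}\n")
            fh.write(f"template_starts: {','.join(map(str, cfg.template_starts))}\n")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Sample background and peak reads; deterministic under the config seed.

    Background read starts are uniform on [0, genome_size - read_length];
    peak reads pick a retained peak uniformly (all peaks share one width, so
    this matches the per-peak coverage target in expectation) and start
    uniformly inside it, clipped so the read stays within the genome.
    """
    fixed = make_fixed_width_peaks(config.template_starts, config.peak_width,
                                   config.genome_size)
    truth = fixed.intervals
    peak_list = truth.intervals()
    rng = np.random.default_rng(config.seed)
    rl = config.read_length

    n_noise = n_reads(config.noise_coverage, config.genome_size, rl)
    n_peak = n_reads(config.peak_coverage, config.peak_width * len(peak_list), rl)

    noise_starts = rng.integers(0, config.genome_size - rl + 1, size=n_noise)
    which = rng.integers(0, len(peak_list), size=n_peak)
    offsets = rng.integers(0, config.peak_width, size=n_peak)
    peak_starts_arr = np.array([s for _, s, _ in peak_list], dtype=np.int64)
    peak_starts = np.minimum(peak_starts_arr[which] + offsets,
                             config.genome_size - rl)

    starts = np.concatenate([noise_starts, peak_starts]).astype(np.int64)
    reads = np.stack([starts, starts + rl], axis=1)
    log.info("simulated %d background + %d peak reads over %d peaks",
             n_noise, n_peak, len(peak_list))
    return SimulatedDataset(config=config, reads=reads, truth=truth)


def make_grid(peak_widths=GRID_PEAK_WIDTHS,
              peak_coverages=GRID_PEAK_COVERAGES,
              noise_coverages=GRID_NOISE_COVERAGES,
              base: SimulationConfig | None = None) -> list[SimulationConfig]:
    """Cartesian product of the simulation axes, width-major order.

    With the default axes this yields the full study grid: 18 peak-width
    sets, each crossed with 7 peak coverages x 6 noise coverages = 42
    enrichment/noise variants. ``base`` supplies the shared genome geometry;
    a small default is used when omitted.
    """
    if not (len(tuple(peak_widths)) and len(tuple(peak_coverages))
            and len(tuple(noise_coverages))):
        raise ConfigurationError("all grid axes must be nonempty")
    if base is None:
        base = SimulationConfig(
            genome_size=1_000_000,
            template_starts=tuple(range(10_000, 900_000, 60_000)),
            peak_width=int(min(peak_widths)),
            peak_coverage=1.0, noise_coverage=1.0,
        )
    configs = []
    for w, y, x in itertools.product(peak_widths, peak_coverages, noise_coverages):
        configs.append(replace(base, peak_width=int(w), peak_coverage=float(y),
                               noise_coverage=float(x)))
    return configs


def read_config(path: str) -> SimulationConfig:
    """Parse the plain-text key: value config written by ``write_config``."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            key, _, value = line.partition(":")
            kv[key.strip()] = value.strip()
    try:
        return SimulationConfig(
            genome_size=int(kv["genome_size"]),
            template_starts=tuple(int(s) for s in kv["template_starts"].split(",") if s),
            peak_width=int(kv["peak_width"]),
            peak_coverage=float(kv["peak_coverage"]),
            noise_coverage=float(kv["noise_coverage"]),
            read_length=int(kv.get("read_length", DEFAULT_READ_LENGTH)),
            seed=int(kv.get("seed", 0)),
            chrom=kv.get("chrom", DEFAULT_CHROM),
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing key {exc} in simulation config {path}") from exc
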