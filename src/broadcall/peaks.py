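"""Peak construction, scoring and output.

Maximal runs of windows decoded as "peak" are merged into intervals (never
across chromosomes). Each peak gets four scores computed over its
constituent windows: mean coverage, maximum coverage, the product of the
per-window peak-state posteriors, and the maximum of those posteriors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coverage import CoverageMatrix
from .errors import DimensionError, InputError
from .windows import GenomeWindows

log = logging.getLogger(__name__)

SCORE_NAMES = ("mean_coverage", "max_coverage", "posterior_product", "max_posterior")
BED_SCORE_CHOICES = {
    "mean": "mean_coverage",
    "max": "max_coverage",
    "posterior": "posterior_product",
    "max_posterior": "max_posterior",
}
_PRODUCT_UNDERFLOW = 1e-300


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class PeakSet:
    """Scored peaks ordered by (chrom, start); non-overlapping within a chromosome."""

    peaks: list[Peak] = field(default_factory=list)
    provenance: dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(p.chrom, p.start, p.end) for p in self.peaks]


def merge_peak_windows(states, windows: GenomeWindows,
                       peak_label: object = "peak") -> PeakSet:
    """Merge maximal runs of peak-labelled windows into intervals.

    ``states`` holds one label per window (strings or state indices);
    windows whose label equals ``peak_label`` are peak windows. Runs never
    span a chromosome boundary.
    """
    states = list(states)
    if len(states) != len(windows):
        raise DimensionError(f"{len(states)} states for {len(windows)} windows")
    peaks: list[Peak] = []
    run_start = None  # window index where the current run began
    prev_chrom = None
    for i, ((chrom, start, end), label) in enumerate(zip(windows.windows, states)):
        is_peak = label == peak_label
        if run_start is not None and (not is_peak or chrom != prev_chrom):
            peaks.append(_close_run(windows, run_start, i))
            run_start = None
        if is_peak and run_start is None:
            run_start = i
        prev_chrom = chrom
    if run_start is not None:
        peaks.append(_close_run(windows, run_start, len(windows)))
    return PeakSet(peaks=peaks)


def _close_run(windows: GenomeWindows, first: int, stop: int) -> Peak:
    chrom, start, _ = windows.windows[first]
    _, _, end = windows.windows[stop - 1]
    return Peak(chrom=chrom, start=start, end=end)


def score_peaks(peaks: PeakSet, coverage: CoverageMatrix,
                posteriors: np.ndarray, peak_state: int) -> PeakSet:
    """Attach the four per-peak scores.

    Coverage per window is the across-sample sum when the matrix has several
    columns. Posterior products are computed as exp of summed logs; products
    below ~1e-300 are stored as 0.
    """
    win_cov = coverage.values.sum(axis=1)
    win_post = np.asarray(posteriors)[:, peak_state]
    starts = {(c, s): i for i, (c, s, _) in enumerate(coverage.windows.windows)}
    for peak in peaks:
        idx = []
        i = starts[(peak.chrom, peak.start)]
        pos = peak.start
        while pos < peak.end:
            idx.append(i)
            pos = coverage.windows.windows[i][2]
            i += 1
        cov = win_cov[idx]
        post = win_post[idx]
        with np.errstate(divide="ignore"):
            log_prod = np.log(post).sum()
        product = 0.0 if log_prod < np.log(_PRODUCT_UNDERFLOW) else float(np.exp(log_prod))
        peak.scores = {
            "mean_coverage": float(cov.mean()),
            "max_coverage": float(cov.max()),
            "posterior_product": product,
            "max_posterior": float(post.max()),
        }
    return peaks


def write_bed(peaks: PeakSet, path: str, score: str = "mean") -> None:
    """Write BED5 (chrom, start, end, "peak_N", chosen score).

    BED holds a single score column; ``score`` selects which of the four to
    write (mean coverage by default).
    """
    if score not in BED_SCORE_CHOICES:
        raise InputError(f"score must be one of {sorted(BED_SCORE_CHOICES)}")
    key = BED_SCORE_CHOICES[score]
    try:
        with open(path, "w") as fh:
            for n, peak in enumerate(peaks, 1):
                fh.write(f"{peak.chrom}\t{peak.start}\t{peak.end}\tpeak_{n}\t"
                         f"{float(peak.scores[key])}\n")
    except OSError as exc:
        raise InputError(f"cannot write BED to {path}: {exc}") from exc


def write_tab(peaks: PeakSet, path: str) -> None:
    """Write all four scores as a tab-separated table with one header line."""
    try:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\t" + "\t".join(SCORE_NAMES) + "\n")
            for peak in peaks:
                row = [peak.chrom, str(peak.start), str(peak.end)]
                row += [str(float(peak.scores[k])) for k in SCORE_NAMES]
                fh.write("\t".join(row) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write table to {path}: {exc}") from exc


def read_tab(path: str) -> PeakSet:
    """Read back a score table written by :func:`write_tab`."""
    peaks: list[Peak] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rec = dict(zip(header, fields))
            peaks.append(Peak(
                chrom=rec["chrom"], start=int(rec["start"]), end=int(rec["end"]),
                scores={k: float(rec[k]) for k in SCORE_NAMES},
            ))
    return PeakSet(peaks=peaks)
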