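"""Nucleotide-level comparison of called peaks against a truth set.

All three metrics count individual base pairs of half-open intervals,
pooled genome-wide: Jaccard = |called ∩ real| / |called ∪ real|,
TPR = |called ∩ real| / |real|, FDR = |called \\ real| / |called|.
Inputs are merged per file before computation, so overlapping intervals
never double-count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, UndefinedMetricError


@dataclass
class IntervalSet:
    """Per-chromosome sorted, merged, pairwise-disjoint half-open intervals."""

    by_chrom: dict[str, np.ndarray] = field(default_factory=dict)  # (N, 2) int arrays

    @classmethod
    def from_intervals(cls, intervals) -> "IntervalSet":
        """Build from (chrom, start, end) triples; overlaps/adjacency merged."""
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if end <= start:
                raise InputError(f"empty or inverted interval [{start},{end}) on {chrom}")
            grouped.setdefault(chrom, []).append((start, end))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivs in grouped.items():
            ivs.sort()
            out = [list(ivs[0])]
            for start, end in ivs[1:]:
                if start <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], end)
                else:
                    out.append([start, end])
            merged[chrom] = np.array(out, dtype=np.int64)
        return cls(by_chrom=merged)

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        return cls.from_intervals(
            (c, s, e) for c, s, e, _ in _iter_bed(path)
        )

    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.by_chrom.values()))

    def is_empty(self) -> bool:
        return self.total_bp() == 0

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.by_chrom):
            for start, end in self.by_chrom[chrom]:
                out.append((chrom, int(start), int(end)))
        return out

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals():
                fh.write(f"{chrom}\t{start}\t{end}\n")


def _iter_bed(path: str):
    """Yield (chrom, start, end, name) from a BED file; name may be ''."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: bad BED line {line!r}")
            name = fields[3] if len(fields) > 3 else ""
            yield fields[0], int(fields[1]), int(fields[2]), name


def _intersection_bp(a: IntervalSet, b: IntervalSet) -> int:
    total = 0
    for chrom, ivs_a in a.by_chrom.items():
        ivs_b = b.by_chrom.get(chrom)
        if ivs_b is None:
            continue
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            lo = max(ivs_a[i, 0], ivs_b[j, 0])
            hi = min(ivs_a[i, 1], ivs_b[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if ivs_a[i, 1] <= ivs_b[j, 1]:
                i += 1
            else:
                j += 1
    return total


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Nucleotide Jaccard index |a ∩ b| / |a ∪ b|; 0 when both sets are empty."""
    inter = _intersection_bp(a, b)
    union = a.total_bp() + b.total_bp() - inter
    return inter / union if union else 0.0


def tpr(real: IntervalSet, called: IntervalSet) -> float:
    """Sensitivity: fraction of truth nucleotides recovered by the calls."""
    denom = real.total_bp()
    if denom == 0:
        raise UndefinedMetricError("TPR undefined: the truth set is empty")
    return _intersection_bp(real, called) / denom


def fdr(real: IntervalSet, called: IntervalSet) -> float:
    """Fraction of called nucleotides that fall outside the truth set."""
    denom = called.total_bp()
    if denom == 0:
        raise UndefinedMetricError("FDR undefined: the called set is empty")
    return (denom - _intersection_bp(real, called)) / denom


def genes_overlapping(genes, peaks: IntervalSet) -> list[str]:
    """Names of genes sharing at least 1 bp with any peak.

    ``genes`` is an iterable of (chrom, start, end, name) records or a BED
    path with a name column. Order of first appearance is kept; duplicates
    (e.g. multi-interval genes) are reported once.
    """
    if isinstance(genes, str):
        genes = list(_iter_bed(genes))
    hits: list[str] = []
    seen: set[str] = set()
    for chrom, start, end, name in genes:
        ivs = peaks.by_chrom.get(chrom)
        if ivs is None or not len(ivs):
            continue
        # first peak ending after the gene start; overlap iff it begins before gene end
        k = int(np.searchsorted(ivs[:, 1], start, side="right"))
        if k < len(ivs) and ivs[k, 0] < end and name not in seen:
            seen.add(name)
            hits.append(name)
    return hits


def report(real: IntervalSet, called: IntervalSet) -> str:
    """Tab-separated metric report (FDR/Jaccard fall back to 'NA' when undefined)."""
    lines = ["metric\tvalue"]
    lines.append(f"jaccard\t{jaccard(real, called):.6g}")
    try:
        lines.append(f"tpr\t{tpr(real, called):.6g}")
    except UndefinedMetricError:
        lines.append("tpr\tNA")
    try:
        lines.append(f"fdr\t{fdr(real, called):.6g}")
    except UndefinedMetricError:
        lines.append("fdr\tNA")
    return "\n".join(lines) + "\n"
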