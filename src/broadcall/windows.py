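"""Genome tiling into fixed-width windows.

The caller aggregates read coverage over adjacent, non-overlapping windows
(800 bp by default) and emits one value (or vector) per window to the HMM.
All coordinates are 0-based half-open, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, InputError

DEFAULT_WINDOW_WIDTH = 800


@dataclass(frozen=True)
class GenomeWindows:
    """An ordered tiling of chromosomes into fixed-width half-open windows.

    Windows tile each chromosome left to right with no gaps or overlaps;
    every window except possibly the last per chromosome spans exactly
    ``width`` bp, and starts are multiples of ``width``.
    """

    chrom_order: tuple[str, ...]
    chrom_sizes: dict[str, int]
    width: int
    windows: tuple[tuple[str, int, int], ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.windows)

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the window list covering one chromosome."""
        offset = 0
        for name in self.chrom_order:
            n = n_windows(self.chrom_sizes[name], self.width)
            if name == chrom:
                return slice(offset, offset + n)
            offset += n
        raise KeyError(chrom)

    def lengths(self):
        """Window lengths in bp (the last window per chromosome may be short)."""
        import numpy as np

        return np.array([e - s for _, s, e in self.windows], dtype=np.int64)


def n_windows(length: int, width: int) -> int:
    return -(-length // width)  # ceil division


def make_windows(chrom_sizes: dict[str, int], width: int = DEFAULT_WINDOW_WIDTH) -> GenomeWindows:
    """Tile chromosomes into adjacent windows of ``width`` bp.

    Parameters
    ----------
    chrom_sizes
        Mapping of chromosome name to length in bp; iteration order is kept.
    width
        Window width in bp. The final window of a chromosome is truncated to
        the chromosome end when the length is not a multiple of the width.
    """
    if width < 1:
        raise ConfigurationError(f"window width must be >= 1, got {width}")
    if not chrom_sizes:
        raise ConfigurationError("empty chromosome table")
    for name, length in chrom_sizes.items():
        if length < 1:
            raise ConfigurationError(f"chromosome {name!r} has non-positive length {length}")

    windows: list[tuple[str, int, int]] = []
    for name, length in chrom_sizes.items():
        for start in range(0, length, width):
            windows.append((name, start, min(start + width, length)))
    return GenomeWindows(
        chrom_order=tuple(chrom_sizes),
        chrom_sizes=dict(chrom_sizes),
        width=width,
        windows=tuple(windows),
    )


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column (name, length) chromosome-sizes table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: expected 'name length', got {line!r}")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    if not sizes:
        raise ConfigurationError(f"no chromosomes found in {path}")
    return sizes
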