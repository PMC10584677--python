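"""Fixed-grid fragment binning and per-bp coverage tracks.

The analysis grid tiles a locus with adjacent, non-overlapping bins
(default 500 bp) anchored at the locus start; the final bin may be
shorter and is kept un-normalised. A fragment increments every bin it
overlaps by at least 1 bp, so one fragment can count in two or more bins
— the convention is overlap counting, not midpoint or 5'-end assignment,
and per-bin sums can exceed the number of fragments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import ConfigError, DataError
from .simulate import FragmentSet, GeneModel

logger = logging.getLogger(__name__)

__all__ = ["BinGrid", "BinTrack", "make_bins", "count_fragments", "coverage_track"]

DEFAULT_BIN_SIZE = 500


@dataclass(frozen=True)
class BinGrid:
    """Adjacent non-overlapping bins tiling ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ConfigError(f"bin_size must be >= 1, got {self.bin_size}")
        if self.end <= self.start:
            raise ConfigError("locus end must exceed start")

    @property
    def n_bins(self) -> int:
        return -((self.start - self.end) // self.bin_size)  # ceil division

    @property
    def bin_starts(self) -> np.ndarray:
        return self.start + self.bin_size * np.arange(self.n_bins, dtype=np.int64)

    @property
    def bin_ends(self) -> np.ndarray:
        return np.minimum(self.bin_starts + self.bin_size, self.end)

    @property
    def last_bin_length(self) -> int:
        """Length of the final (possibly partial, un-normalised) bin."""
        return self.end - int(self.bin_starts[-1])

    def bin_of(self, position: int) -> int:
        """Index of the bin containing an absolute bp position."""
        if not self.start <= position < self.end:
            raise DataError(f"position {position} outside grid")
        return (position - self.start) // self.bin_size


@dataclass
class BinTrack:
    """Per-bin signal over a :class:`BinGrid`.

    Raw counts are integers; normalised tracks are reals. ``n_skipped``
    records fragments that did not contribute (wrong chromosome or
    entirely outside the locus).
    """

    grid: BinGrid
    counts: np.ndarray
    label: str = ""
    library_size: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (self.grid.n_bins,):
            raise DataError(
                f"counts length {self.counts.shape} does not match "
                f"{self.grid.n_bins} bins"
            )
        if (self.counts < 0).any():
            raise DataError("bin counts must be non-negative")


def make_bins(locus: GeneModel | tuple[str, int, int], bin_size: int = DEFAULT_BIN_SIZE) -> BinGrid:
    """Tile a locus with adjacent bins anchored at the locus start.

    ``locus`` is a :class:`GeneModel` or a ``(chrom, start, end)`` tuple
    in 0-based half-open coordinates.
    """
    if isinstance(locus, GeneModel):
        chrom, start, end = locus.chrom, locus.locus_start, locus.locus_end
    else:
        chrom, start, end = locus
    return BinGrid(chrom=chrom, start=int(start), end=int(end), bin_size=int(bin_size))


def count_fragments(grid: BinGrid, fragments: FragmentSet) -> BinTrack:
    """Count fragments overlapping each bin (order-independent).

    A fragment is counted once in every bin it overlaps by >= 1 bp.
    Fragments on another chromosome or wholly outside the locus are
    skipped; the skip count is logged and stored on the track.
    """
    n_bins = grid.n_bins
    counts = np.zeros(n_bins, dtype=np.int64)
    n_skipped = 0
    if fragments.chrom != grid.chrom:
        n_skipped = fragments.library_size
        logger.warning(
            "chromosome mismatch (%s vs %s): skipped %d fragments",
            fragments.chrom, grid.chrom, n_skipped,
        )
    elif fragments.library_size:
        starts, ends = fragments.starts, fragments.ends
        inside = (starts < grid.end) & (ends > grid.start)
        n_skipped = int((~inside).sum())
        if n_skipped:
            logger.info("skipped %d fragments outside the locus", n_skipped)
        s = np.clip(starts[inside], grid.start, grid.end) - grid.start
        e = np.clip(ends[inside], grid.start, grid.end) - grid.start
        first = s // grid.bin_size
        last = (e - 1) // grid.bin_size
        # range-increment via difference array: +1 on [first, last]
        diff = np.bincount(first, minlength=n_bins + 1).astype(np.int64)
        diff -= np.bincount(last + 1, minlength=n_bins + 1)
        counts = np.cumsum(diff[:n_bins])
    return BinTrack(
        grid=grid,
        counts=counts.astype(np.float64),
        label=fragments.label,
        library_size=fragments.library_size,
        n_skipped=n_skipped,
    )


def coverage_track(fragments: FragmentSet, total_mapped: int) -> np.ndarray:
    """Per-bp coverage in read counts per million mapped reads (CPM).

    Depth at each locus bp, scaled by 1e6 / ``total_mapped`` — the y-axis
    convention of genome-browser profile tracks. Returns an array over
    ``[locus_start, locus_end)``; write out with
    :func:`txroadblock.io.write_bedgraph`.
    """
    if total_mapped <= 0:
        raise ConfigError("total_mapped must be positive")
    lo, hi = fragments.locus_start, fragments.locus_end
    L = hi - lo
    if L <= 0:
        raise DataError("fragment set has an empty locus")
    diff = np.zeros(L + 1, dtype=np.float64)
    s = np.clip(fragments.starts, lo, hi) - lo
    e = np.clip(fragments.ends, lo, hi) - lo
    keep = e > s
    diff += np.bincount(s[keep], minlength=L + 1)
    diff -= np.bincount(e[keep], minlength=L + 1)
    return np.cumsum(diff[:-1]) * (1e6 / float(total_mapped))
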