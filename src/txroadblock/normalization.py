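"""Median-of-ratios size factors, track normalisation and TPM.

Size factors follow the canonical median-ratio estimator: each gene's
reference is its geometric mean across samples (genes with a zero in any
sample drop out of the reference set via the log convention), and a
sample's factor is the median over reference genes of its count divided
by the reference. Factors are estimated on gene-level counts and then
applied to bin-level tracks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ConfigError, DataError
from .binning import BinTrack

logger = logging.getLogger(__name__)

__all__ = ["CountMatrix", "median_ratio_size_factors", "normalize_track", "tpm"]


@dataclass
class CountMatrix:
    """Genes x samples raw counts with per-gene annotation lengths (bp)."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise DataError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise DataError("gene lengths must be positive")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        """Read a TSV with a gene-id index, a ``length`` column and one
        column per sample."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "length" not in df.columns:
            raise DataError("count matrix TSV needs a 'length' column")
        lengths = df.pop("length")
        return cls(counts=df, lengths=lengths)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t")


def median_ratio_size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    reference_g = geometric mean of gene g across samples (all-nonzero
    genes only); factor_s = median_g count_{g,s} / reference_g. Raises if
    no gene is nonzero in every sample.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    arr = counts.to_numpy(dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise DataError("count matrix must be 2-D with >= 1 sample")
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    ref = logs.mean(axis=1)  # -inf for genes with any zero: drops them below
    usable = np.isfinite(ref)
    if not usable.any():
        raise DataError(
            "size factors undefined: no gene has nonzero counts in every sample"
        )
    # ratios against the geometric-mean reference; plain median (mean of
    # the two middle values for even n) for cross-platform determinism
    ratios = arr[usable] / np.exp(ref[usable])[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_track(track: BinTrack, factor: float) -> BinTrack:
    """Divide a bin track by a size factor (label preserved)."""
    if factor <= 0:
        raise ConfigError(f"size factor must be positive, got {factor}")
    return BinTrack(
        grid=track.grid,
        counts=track.counts / float(factor),
        label=track.label,
        library_size=track.library_size,
        n_skipped=track.n_skipped,
    )


def tpm(counts, lengths) -> pd.Series:
    """Transcripts per million from per-gene counts and lengths (bp).

    TPM_g = 1e6 * (count_g / length_g) / sum_g (count_g / length_g);
    the result sums to 1e6 (or to 0 for an all-zero input, with a warning).
    """
    counts = pd.Series(counts, dtype=np.float64)
    lengths = pd.Series(lengths, dtype=np.float64).reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise DataError("gene lengths must be positive for every gene")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        logger.warning("all-zero counts: TPM is zero for every gene")
        return rate.rename("tpm")
    return (1e6 * rate / total).rename("tpm")
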