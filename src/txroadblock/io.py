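"""Plain-text genomics I/O: BED, bedGraph, TSV tables, run configs.

All interval output is 0-based half-open. Genome-browser-style position
strings ("chr12:104,286,383-104,372,549") are 1-based inclusive and are
converted on read.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import DataError
from .simulate import FragmentSet

__all__ = [
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "parse_browser_position",
    "read_annotation",
    "write_size_factors",
    "read_config",
    "write_json",
]


def parse_browser_position(text: str) -> tuple[str, int, int]:
    """Parse "chrom:start-end" (1-based inclusive, commas allowed) to
    0-based half-open ``(chrom, start, end)``."""
    m = re.fullmatch(r"\s*([\w.]+):([\d,]+)[-–]([\d,]+)\s*", text)
    if not m:
        raise DataError(f"cannot parse browser position {text!r}")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if end < start:
        raise DataError(f"end before start in {text!r}")
    return chrom, start - 1, end


def read_bed(path, label: str = "", locus: tuple[int, int] | None = None) -> FragmentSet:
    """Read a 3+ column BED into a FragmentSet (extra columns ignored).

    All records must share one chromosome (one-locus analyses); pass
    ``locus=(start, end)`` to fix the locus extent explicitly.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#", dtype={0: str},
    )
    if df.empty:
        raise DataError(f"no intervals in {path}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise DataError(f"expected a single chromosome in {path}, got {list(chroms)}")
    lo, hi = (locus if locus is not None else (int(df["start"].min()), int(df["end"].max())))
    return FragmentSet(
        chrom=str(chroms[0]),
        starts=df["start"].to_numpy(np.int64),
        ends=df["end"].to_numpy(np.int64),
        label=label or Path(str(path)).stem,
        locus_start=lo,
        locus_end=hi,
    )


def write_bed(fragments: FragmentSet, path) -> None:
    """Write fragments as 3-column BED."""
    pd.DataFrame(
        {"chrom": fragments.chrom, "start": fragments.starts, "end": fragments.ends}
    ).to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(values: np.ndarray, chrom: str, start: int, path, precision: int = 6) -> None:
    """Write a per-bp track as run-length-merged 4-column bedGraph."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        Path(path).write_text("")
        return
    rounded = np.round(values, precision)
    change = np.nonzero(np.diff(rounded))[0] + 1
    run_starts = np.concatenate(([0], change))
    run_ends = np.concatenate((change, [values.size]))
    vals = rounded[run_starts]
    keep = vals != 0
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": run_starts[keep] + start,
            "end": run_ends[keep] + start,
            "value": vals[keep],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV.

    Required columns: gene_id, chrom, start, end, length; optional: tpm,
    targeted (0/1 flag).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end", "length"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"annotation missing columns: {sorted(missing)}")
    return df


def write_size_factors(factors: pd.Series, path) -> None:
    factors.rename("size_factor").to_csv(path, sep="\t", header=True, index_label="sample")


def read_config(path) -> dict:
    """Load a YAML run config into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} must be a mapping")
    return cfg


def write_json(obj, path) -> None:
    """JSON dump with numpy-scalar tolerance and stable key order."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def write_bin_track(track, path) -> None:
    """Write a BinTrack as 4-column TSV (chrom, bin_start, bin_end, count)."""
    pd.DataFrame(
        {
            "chrom": track.grid.chrom,
            "bin_start": track.grid.bin_starts,
            "bin_end": track.grid.bin_ends,
            "count": track.counts,
        }
    ).to_csv(path, sep="\t", index=False)


def read_bin_track(path, label: str = ""):
    """Read a BinTrack TSV written by :func:`write_bin_track`."""
    from .binning import BinGrid, BinTrack

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "bin_start", "bin_end", "count"}
    if missing := required - set(df.columns):
        raise DataError(f"bin track TSV missing columns: {sorted(missing)}")
    if df.empty:
        raise DataError(f"empty bin track in {path}")
    starts = df["bin_start"].to_numpy(np.int64)
    widths = np.diff(starts)
    bin_size = int(widths[0]) if len(widths) else int(df["bin_end"].iloc[0] - starts[0])
    grid = BinGrid(
        chrom=str(df["chrom"].iloc[0]),
        start=int(starts[0]),
        end=int(df["bin_end"].iloc[-1]),
        bin_size=bin_size,
    )
    return BinTrack(
        grid=grid, counts=df["count"].to_numpy(np.float64), label=label or Path(str(path)).stem
    )
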