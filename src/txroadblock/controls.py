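"""Matched negative-control genes and the per-gene control panel.

Negative controls for the binned differential analysis are untargeted
genes of similar annotation length (within 2,500 bp) and expression
(within 5 TPM) to the targeted gene; each is analysed with the identical
bin/normalise/test procedure, and a specific roadblock effect should
flag bins only on the target.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ConfigError, DataError
from .binning import DEFAULT_BIN_SIZE, count_fragments, make_bins
from .binomial_test import BinTestConfig, BinTestResult, bin_test
from .normalization import median_ratio_size_factors, normalize_track
from .simulate import FragmentSet

logger = logging.getLogger(__name__)

__all__ = [
    "MatchTolerance",
    "GeneRecord",
    "select_matched_controls",
    "run_control_panel",
]


@dataclass(frozen=True)
class MatchTolerance:
    """Inclusive matching windows: |Δlength| <= length_window and
    |ΔTPM| <= tpm_window."""

    length_window: int = 2_500
    tpm_window: float = 5.0

    def __post_init__(self) -> None:
        if self.length_window <= 0 or self.tpm_window <= 0:
            raise ConfigError("matching windows must be positive")


@dataclass(frozen=True)
class GeneRecord:
    """One annotation row: coordinates, length, expression, targeting flag."""

    gene_id: str
    chrom: str
    start: int
    end: int
    length: int
    tpm: float = 0.0
    targeted: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigError(f"{self.gene_id}: length must be positive")
        if self.tpm < 0:
            raise ConfigError(f"{self.gene_id}: tpm must be >= 0")

    def overlaps(self, other: "GeneRecord") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def select_matched_controls(
    genes: list[GeneRecord],
    target: GeneRecord,
    tol: MatchTolerance | None = None,
) -> list[GeneRecord]:
    """All untargeted genes within the length and TPM windows of the target.

    The target itself, any gene flagged ``targeted`` and any gene whose
    locus overlaps the target's are excluded. Returns an empty list (with
    a warning) when nothing matches.
    """
    tol = tol or MatchTolerance()
    if not genes:
        raise DataError("empty annotation: no candidate control genes")
    matches = [
        g
        for g in genes
        if g.gene_id != target.gene_id
        and not g.targeted
        and not g.overlaps(target)
        and abs(g.length - target.length) <= tol.length_window
        and abs(g.tpm - target.tpm) <= tol.tpm_window
    ]
    if not matches:
        logger.warning("no control genes matched %s", target.gene_id)
    return matches


def run_control_panel(
    controls: list[GeneRecord],
    treated_frags: FragmentSet,
    control_frags: FragmentSet,
    cfg: BinTestConfig | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    target: GeneRecord | None = None,
) -> pd.DataFrame:
    """Apply the binned differential test to each panel gene.

    Size factors are estimated once from gene-level counts over the whole
    panel (target included when given), then applied to every gene's bin
    track. Genes with no coverage in either library are reported as
    untestable rather than as zero significant bins.

    Returns a per-gene summary with columns gene_id, n_bins,
    n_significant, n_sig_depleted, n_sig_elevated, testable.
    """
    cfg = cfg or BinTestConfig()
    panel = list(controls) + ([target] if target is not None else [])
    if not panel:
        raise DataError("empty control panel")

    tracks = {}
    for g in panel:
        grid = make_bins((g.chrom, g.start, g.end), bin_size)
        tracks[g.gene_id] = (
            grid,
            count_fragments(grid, treated_frags),
            count_fragments(grid, control_frags),
        )

    gene_counts = pd.DataFrame(
        {
            "treated": {gid: t.counts.sum() for gid, (_, t, _) in tracks.items()},
            "control": {gid: c.counts.sum() for gid, (_, _, c) in tracks.items()},
        }
    )
    try:
        factors = median_ratio_size_factors(gene_counts.round().astype(int))
    except DataError:
        logger.warning(
            "no gene covered in both libraries; falling back to library-size factors"
        )
        sizes = np.array([treated_frags.library_size, control_frags.library_size], float)
        if (sizes <= 0).any():
            raise
        geo = float(np.exp(np.mean(np.log(sizes))))
        factors = pd.Series(sizes / geo, index=["treated", "control"])

    rows = []
    for g in panel:
        grid, t_raw, c_raw = tracks[g.gene_id]
        testable = t_raw.counts.sum() > 0 or c_raw.counts.sum() > 0
        row = {
            "gene_id": g.gene_id,
            "is_target": target is not None and g.gene_id == target.gene_id,
            "n_bins": grid.n_bins,
            "testable": bool(testable),
            "n_significant": 0,
            "n_sig_depleted": 0,
            "n_sig_elevated": 0,
        }
        if testable:
            res = bin_test(
                normalize_track(t_raw, factors["treated"]),
                normalize_track(c_raw, factors["control"]),
                cfg,
            )
            dep = res.significant & (res.log2fc < 0)
            row.update(
                n_significant=res.n_significant,
                n_sig_depleted=int(dep.sum()),
                n_sig_elevated=int((res.significant & (res.log2fc > 0)).sum()),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
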