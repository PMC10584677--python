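"""Readthrough, alternative-polyadenylation and expression ratio metrics.

These mirror the qPCR-style summary statistics of roadblock experiments:

* readthrough — signal downstream of the block divided by signal
  upstream (DS/US), normalised to the same ratio in the control library;
  values below 1 mean suppressed readthrough.
* APA — signal in the shared region upstream of the proximal PAS ("up")
  divided by signal in the long-isoform-specific region ("down"),
  normalised to control; values above 1 mean a shift to the proximal PAS.
* expression — polyadenylated mRNA output relative to control,
  optionally double-normalised to an unperturbed reference gene.

Signals are fragment counts over declared checkpoint intervals, the
in-silico analogue of qPCR amplicons; checkpoint positions are fully
user-declared because amplicon placement is gene- and design-specific.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import ConfigError, DataError
from .binomial_test import BinTestResult
from .simulate import ExpressionSummary, FragmentSet

__all__ = [
    "ReadthroughResult",
    "ApaResult",
    "interval_signal",
    "readthrough_ratio",
    "apa_ratio",
    "expression_ratio",
    "estimate_block_position",
]


def interval_signal(fragments: FragmentSet, start: int, end: int) -> int:
    """Number of fragments overlapping ``[start, end)`` by >= 1 bp."""
    if end <= start:
        raise ConfigError("checkpoint interval must satisfy start < end")
    return int(((fragments.starts < end) & (fragments.ends > start)).sum())


@dataclass(frozen=True)
class ReadthroughResult:
    """Downstream/upstream readthrough ratio, raw and control-normalised."""

    ds_treated: float
    us_treated: float
    ds_control: float
    us_control: float

    @property
    def ratio_treated(self) -> float:
        return self.ds_treated / self.us_treated

    @property
    def ratio_control(self) -> float:
        return self.ds_control / self.us_control

    @property
    def normalized_ratio(self) -> float:
        """< 1 means less readthrough than in the control sample."""
        return self.ratio_treated / self.ratio_control


@dataclass(frozen=True)
class ApaResult:
    """Up/down (shared/long-isoform) ratio, raw and control-normalised."""

    up_treated: float
    down_treated: float
    up_control: float
    down_control: float

    @property
    def ratio_treated(self) -> float:
        return self.up_treated / self.down_treated

    @property
    def ratio_control(self) -> float:
        return self.up_control / self.down_control

    @property
    def normalized_ratio(self) -> float:
        """> 1 means a shift toward proximal-PAS (short-isoform) usage."""
        return self.ratio_treated / self.ratio_control


def _require_positive(**signals: float) -> None:
    for name, value in signals.items():
        if value <= 0:
            raise DataError(f"checkpoint signal {name!r} must be positive, got {value}")


def readthrough_ratio(
    ds_treated: float, us_treated: float, ds_control: float, us_control: float
) -> ReadthroughResult:
    """Control-normalised downstream/upstream readthrough ratio."""
    _require_positive(
        ds_treated=ds_treated, us_treated=us_treated,
        ds_control=ds_control, us_control=us_control,
    )
    return ReadthroughResult(ds_treated, us_treated, ds_control, us_control)


def apa_ratio(
    up_treated: float, down_treated: float, up_control: float, down_control: float
) -> ApaResult:
    """Control-normalised up/down alternative-polyadenylation ratio."""
    _require_positive(
        up_treated=up_treated, down_treated=down_treated,
        up_control=up_control, down_control=down_control,
    )
    return ApaResult(up_treated, down_treated, up_control, down_control)


def expression_ratio(
    treated: ExpressionSummary,
    control: ExpressionSummary,
    treated_ref: ExpressionSummary | None = None,
    control_ref: ExpressionSummary | None = None,
) -> float:
    """mRNA output of the treated run relative to control.

    With reference summaries given, the ratio is double-normalised to the
    reference gene's treated/control ratio (the qPCR housekeeping-gene
    convention).
    """
    if control.mrna_count <= 0:
        raise DataError("control mRNA count is zero; expression ratio undefined")
    ratio = treated.mrna_count / control.mrna_count
    if (treated_ref is None) != (control_ref is None):
        raise ConfigError("provide both reference summaries or neither")
    if treated_ref is not None:
        if control_ref.mrna_count <= 0 or treated_ref.mrna_count <= 0:
            raise DataError("reference mRNA counts must be positive")
        ratio /= treated_ref.mrna_count / control_ref.mrna_count
    return ratio


def estimate_block_position(result: BinTestResult) -> int | None:
    """Locate the roadblock boundary bin from a bin-test result.

    The boundary is the most upstream significantly depleted bin
    (log2fc < 0) whose immediately upstream neighbour is not
    significantly depleted; the first bin qualifies vacuously. Returns
    the bin index, or None when no significantly depleted bin exists
    ("not detected" is a result, not an error).
    """
    depleted = result.significant & (result.log2fc < 0)
    if not depleted.any():
        return None
    prev = np.concatenate(([False], depleted[:-1]))
    candidates = np.nonzero(depleted & ~prev)[0]
    return int(candidates[0])
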