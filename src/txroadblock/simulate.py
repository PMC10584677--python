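"""Stochastic Pol II elongation under a dCas9 roadblock.

The generator produces, for a single gene locus, the three objects the
downstream analysis consumes: a per-bp Pol II occupancy profile, a
fragment library sampled from it (chromatin RNA-seq stand-in), and a
per-transcript fate/expression summary.

Model
-----
Each elongation complex (EC) initiates at the TSS and walks 3'-ward,
depositing one unit of dwell weight per bp traversed (occupancy is dwell
weight; no explicit time axis — only relative coverage matters for the
analysis). Along the way it can encounter, in genomic order:

* a dCas9 roadblock (non-template-strand targeting only): the EC stalls
  ``pause_offset`` bp upstream of the dCas9-binding site — the gap between
  the polymerase active centre and its front edge — depositing extra dwell
  weight over a short pause window, then terminates with probability
  ``term_prob`` or resumes. Template-strand targeting is a pass-through:
  dCas9 acts as a one-way valve and presents no roadblock to an EC
  approaching from the PAM-distal side.
* one or more polyadenylation sites (PAS): crossing PAS *k* the EC commits
  to cleavage there with probability ``pas_commit[k]`` (the terminal PAS
  commits always). After commitment a per-bp termination hazard ``h``
  models torpedo-mediated release, so run-on distance past the PAS is
  geometric with mean 1/h.

ECs that exit the locus without committing to any PAS, or are stopped by
the roadblock before any PAS, yield no polyadenylated mRNA (the abortive
transcript is degraded). Optionally, roadblock-stopped ECs that already
passed a skipped proximal PAS are rescued — cleaved and polyadenylated at
that proximal PAS — which is the mechanism behind the alternative-
polyadenylation shift the block induces.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._util import ConfigError, DataError, substream

logger = logging.getLogger(__name__)

__all__ = [
    "Orientation",
    "GeneModel",
    "RoadblockConfig",
    "ElongationParams",
    "OccupancyProfile",
    "FragmentSet",
    "ExpressionSummary",
    "simulate_occupancy",
    "sample_fragments",
    "simulate_expression",
    "default_locus",
]

#: default sonication/library fragment length, bp
DEFAULT_FRAG_LEN = 150


class Orientation(str, Enum):
    """sgRNA strand: NT (non-template, roadblock) or T (template, inert)."""

    NT = "NT"
    T = "T"


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: coordinates, TSS and polyadenylation site(s).

    Coordinates are 0-based half-open. ``pas_positions`` is strictly
    increasing; the last entry is the distal/terminal PAS. ``gene_length``
    is the annotation length used for TPM and control matching.
    """

    chrom: str
    locus_start: int
    locus_end: int
    tss: int
    pas_positions: tuple[int, ...]
    gene_length: int

    def __post_init__(self) -> None:
        pas = tuple(int(p) for p in self.pas_positions)
        object.__setattr__(self, "pas_positions", pas)
        if not pas:
            raise ConfigError("at least one PAS position is required")
        if any(b <= a for a, b in zip(pas, pas[1:])):
            raise ConfigError("pas_positions must be strictly increasing")
        if not (self.locus_start <= self.tss < pas[0] < self.locus_end):
            raise ConfigError(
                "require locus_start <= tss < first PAS < locus_end, got "
                f"{self.locus_start}, {self.tss}, {pas[0]}, {self.locus_end}"
            )
        if pas[-1] >= self.locus_end:
            raise ConfigError("all PAS must lie within the locus")
        if self.gene_length <= 0:
            raise ConfigError("gene_length must be positive")

    @property
    def locus_length(self) -> int:
        return self.locus_end - self.locus_start


def default_locus() -> GeneModel:
    """The TXNRD1 study locus, chr12:104,286,383-104,372,549 (half-open).

    The locus spans the gene body plus its downstream termination zone.
    The terminal PAS is placed 10 kb before the locus end so the native
    termination zone (mean run-on 1/h = 2 kb, tail to several kb) fits
    inside the analysed window; the PAS coordinate itself is a
    phenomenological placement, not an annotation lookup.
    """
    start, end = 104_286_383, 104_372_549
    return GeneModel(
        chrom="chr12",
        locus_start=start,
        locus_end=end,
        tss=start,
        pas_positions=(end - 10_000,),
        gene_length=end - 10_000 - start,
    )


@dataclass(frozen=True)
class RoadblockConfig:
    """A dCas9 roadblock at ``position`` (the dCas9-binding site, bp).

    ``term_prob`` is the probability that an EC reaching the block
    terminates; ``pause_dwell`` multiplies occupancy over the pause window
    ``[stall - pause_width, stall)`` where ``stall = position -
    pause_offset`` (the 19-bp active-centre-to-front-edge gap).
    Template-strand (T) orientation behaves as pass-through regardless of
    the configured ``term_prob``/``pause_dwell``.
    """

    position: int
    orientation: Orientation = Orientation.NT
    term_prob: float = 0.8
    pause_dwell: float = 20.0
    pause_width: int = 50
    pause_offset: int = 19

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if not 0.0 <= self.term_prob <= 1.0:
            raise ConfigError(f"term_prob must be in [0, 1], got {self.term_prob}")
        if self.pause_dwell < 1.0:
            raise ConfigError(f"pause_dwell must be >= 1, got {self.pause_dwell}")
        if self.pause_width <= 0:
            raise ConfigError("pause_width must be positive")
        if self.pause_offset < 0:
            raise ConfigError("pause_offset must be >= 0")

    @property
    def stall(self) -> int:
        """Stall point of the EC front edge, bp."""
        return self.position - self.pause_offset


@dataclass(frozen=True)
class ElongationParams:
    """Termination behaviour of elongating complexes.

    ``term_hazard``: per-bp torpedo termination probability after PAS
    commitment (geometric run-on, mean 1/h bp). ``pas_commit``: per-PAS
    cleavage-commitment probabilities, aligned with
    ``GeneModel.pas_positions``; the terminal entry must be 1.
    ``inter_pas_rescue``: whether roadblock-stopped ECs that already
    crossed a skipped proximal PAS are polyadenylated at that PAS.
    """

    term_hazard: float = 5e-4
    pas_commit: tuple[float, ...] = (1.0,)
    inter_pas_rescue: bool = True

    def __post_init__(self) -> None:
        commit = tuple(float(c) for c in self.pas_commit)
        object.__setattr__(self, "pas_commit", commit)
        if not 0.0 < self.term_hazard < 1.0:
            raise ConfigError(f"term_hazard must be in (0, 1), got {self.term_hazard}")
        if any(not 0.0 <= c <= 1.0 for c in commit):
            raise ConfigError("each pas_commit must be in [0, 1]")
        if commit and commit[-1] != 1.0:
            raise ConfigError("terminal PAS commitment probability must be 1")


@dataclass
class OccupancyProfile:
    """Per-bp dwell-weighted Pol II density plus per-EC fate bookkeeping.

    ``density[i]`` is expected occupancy at locus bp ``locus_start + i``.
    ``fates`` partitions the initiated ECs exactly:
    ``terminated_at_block`` (stopped by the roadblock, uncommitted),
    ``terminated_in_zone_at_pas_k`` (committed at PAS k, released in the
    termination zone), ``premature_no_pas`` (exited the locus without
    commitment). ``stop`` and ``committed_pas`` are per-EC arrays kept for
    downstream fate accounting.
    """

    gene: GeneModel
    density: np.ndarray
    fates: dict[str, int]
    n_ec: int
    stop: np.ndarray = field(repr=False)
    committed_pas: np.ndarray = field(repr=False)
    block_terminated: np.ndarray = field(repr=False)
    block_stall: int | None = None

    def __post_init__(self) -> None:
        if int(sum(self.fates.values())) != self.n_ec:
            raise AssertionError("fate tallies do not conserve EC count")
        if (self.density < 0).any():
            raise AssertionError("negative occupancy density")


@dataclass
class FragmentSet:
    """Aligned-fragment intervals over one locus (BED-like, half-open)."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    label: str = ""
    locus_start: int = 0
    locus_end: int | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.starts.shape != self.ends.shape:
            raise DataError("starts and ends must have equal length")
        if (self.ends <= self.starts).any():
            raise DataError("fragments must satisfy start < end")
        if self.locus_end is None:
            self.locus_end = int(self.ends.max()) if len(self.ends) else self.locus_start

    @property
    def library_size(self) -> int:
        return len(self.starts)


@dataclass
class ExpressionSummary:
    """Polyadenylated output of one simulated run.

    ``pas_counts`` are mRNA 3' ends per PAS (rescued roadblock terminations
    included when applicable); ``mrna_count`` is their sum. ``readthrough_count``
    is the number of ECs whose traversal crossed the declared checkpoint.
    """

    mrna_count: int
    pas_counts: tuple[int, ...]
    readthrough_count: int
    n_ec: int

    def __post_init__(self) -> None:
        if self.mrna_count != sum(self.pas_counts):
            raise AssertionError("mrna_count must equal the sum of per-PAS counts")
        if not (0 <= self.mrna_count <= self.n_ec):
            raise AssertionError("mrna_count outside [0, n_ec]")


def simulate_occupancy(
    gene: GeneModel,
    block: RoadblockConfig | None,
    params: ElongationParams,
    n_ec: int = 1_000_000,
    seed: int = 0,
) -> OccupancyProfile:
    """Simulate ``n_ec`` elongation complexes over the locus.

    Returns the dwell-weighted occupancy density and exact fate tallies.
    All stochastic draws come from the labeled ``"fates"`` substream of
    ``seed``, so fragment sampling later never perturbs fates.
    """
    if n_ec <= 0:
        raise ConfigError("n_ec must be positive")
    if len(params.pas_commit) != len(gene.pas_positions):
        raise ConfigError(
            f"pas_commit has {len(params.pas_commit)} entries for "
            f"{len(gene.pas_positions)} PAS"
        )
    L = gene.locus_length
    tss = gene.tss - gene.locus_start

    active_block = block is not None and block.orientation is Orientation.NT
    if block is not None and block.orientation is Orientation.T:
        if block.term_prob > 0 or block.pause_dwell > 1:
            warnings.warn(
                "template-strand (T) targeting presents no roadblock; "
                "term_prob/pause_dwell are ignored",
                stacklevel=2,
            )
    stall = None
    if active_block:
        if not (gene.locus_start <= block.position < gene.locus_end):
            raise ConfigError(
                f"block position {block.position} outside locus "
                f"[{gene.locus_start}, {gene.locus_end})"
            )
        stall = block.stall - gene.locus_start
        if stall <= tss:
            raise ConfigError("roadblock stall point must lie downstream of the TSS")

    rng = substream(seed, "fates")

    stop = np.full(n_ec, L, dtype=np.int64)  # exclusive end of traversal
    committed = np.full(n_ec, -1, dtype=np.int64)
    block_term = np.zeros(n_ec, dtype=bool)
    pause_extra = 0.0
    pause_lo = pause_hi = 0

    events: list[tuple[int, str, int]] = [
        (p - gene.locus_start, "pas", k) for k, p in enumerate(gene.pas_positions)
    ]
    if active_block:
        events.append((stall, "block", -1))
    events.sort()

    h = params.term_hazard
    for pos, kind, k in events:
        if kind == "block":
            reach = stop > pos
            n_reach = int(reach.sum())
            if n_reach:
                pause_lo = max(pos - block.pause_width, 0)
                pause_hi = pos
                pause_extra = n_reach * (block.pause_dwell - 1.0)
                if block.term_prob > 0:
                    term = reach & (rng.random(n_ec) < block.term_prob)
                    stop[term] = pos
                    block_term |= term & (committed == -1)
        else:  # PAS crossing
            reach = (stop > pos) & (committed == -1)
            c = params.pas_commit[k]
            if c <= 0:
                continue
            commit = reach if c >= 1.0 else reach & (rng.random(n_ec) < c)
            idx = np.nonzero(commit)[0]
            if len(idx):
                committed[idx] = k
                run = rng.geometric(h, size=len(idx))
                stop[idx] = np.minimum(pos + run, L)

    # fate tallies (exact conservation)
    fates: dict[str, int] = {}
    uncommitted = committed == -1
    fates["terminated_at_block"] = int((uncommitted & block_term).sum())
    fates["premature_no_pas"] = int((uncommitted & ~block_term).sum())
    for k in range(len(gene.pas_positions)):
        fates[f"terminated_in_zone_at_pas_{k}"] = int((committed == k).sum())

    # density via difference array: each EC covers [tss, stop)
    diff = np.zeros(L + 1, dtype=np.float64)
    diff[tss] += n_ec
    diff -= np.bincount(stop, minlength=L + 1)
    density = np.cumsum(diff[:-1])
    if pause_extra > 0:
        density[pause_lo:pause_hi] += pause_extra

    return OccupancyProfile(
        gene=gene,
        density=density,
        fates=fates,
        n_ec=n_ec,
        stop=stop,
        committed_pas=committed,
        block_terminated=block_term,
        block_stall=stall if active_block else None,
    )


def sample_fragments(
    profile: OccupancyProfile,
    n_fragments: int = 1_000_000,
    frag_len: int = DEFAULT_FRAG_LEN,
    seed: int = 0,
    label: str = "",
) -> FragmentSet:
    """Draw a fragment library with start positions proportional to density.

    Emulates fixed-depth sequencing: exactly ``n_fragments`` fragments are
    returned whatever the total occupancy, so depth normalisation between
    libraries is implicit (as in real libraries sequenced to a target
    depth). Fragments are truncated at the locus end.
    """
    if n_fragments <= 0:
        raise ConfigError("n_fragments must be positive")
    if frag_len < 1:
        raise ConfigError("frag_len must be >= 1")
    total = float(profile.density.sum())
    if total <= 0:
        raise DataError("occupancy density is zero everywhere; cannot sample")
    gene = profile.gene
    rng = substream(seed, "fragments")
    cum = np.cumsum(profile.density)
    u = rng.random(n_fragments) * total
    starts_rel = np.searchsorted(cum, u, side="right")
    starts_rel.sort(kind="stable")
    ends_rel = np.minimum(starts_rel + frag_len, gene.locus_length)
    return FragmentSet(
        chrom=gene.chrom,
        starts=starts_rel + gene.locus_start,
        ends=ends_rel + gene.locus_start,
        label=label,
        locus_start=gene.locus_start,
        locus_end=gene.locus_end,
    )


def simulate_expression(
    profile: OccupancyProfile,
    gene: GeneModel,
    params: ElongationParams,
    readthrough_checkpoint: int | None = None,
) -> ExpressionSummary:
    """Tally polyadenylated mRNA output from the simulated EC fates.

    Only PAS-cleaved ECs produce mRNA; roadblock-stopped ECs upstream of
    every PAS contribute nothing (abortive transcripts are degraded). With
    ``inter_pas_rescue``, roadblock-stopped ECs that had already crossed a
    skipped PAS are polyadenylated at the nearest upstream PAS.

    ``readthrough_checkpoint`` (absolute bp) defaults to the midpoint
    between the terminal PAS and the locus end.
    """
    n_pas = len(gene.pas_positions)
    committed = profile.committed_pas
    counts = np.bincount(committed[committed >= 0], minlength=n_pas).astype(int)

    if params.inter_pas_rescue and profile.block_stall is not None:
        stall_abs = profile.block_stall + gene.locus_start
        upstream = [k for k, p in enumerate(gene.pas_positions) if p < stall_abs]
        if upstream:
            n_rescued = int((profile.block_terminated & (committed == -1)).sum())
            counts[upstream[-1]] += n_rescued

    if readthrough_checkpoint is None:
        readthrough_checkpoint = (gene.pas_positions[-1] + gene.locus_end) // 2
    cp_rel = readthrough_checkpoint - gene.locus_start
    if not 0 <= cp_rel <= gene.locus_length:
        raise ConfigError("readthrough checkpoint outside the locus")
    readthrough = int((profile.stop > cp_rel).sum())

    return ExpressionSummary(
        mrna_count=int(counts.sum()),
        pas_counts=tuple(int(c) for c in counts),
        readthrough_count=readthrough,
        n_ec=profile.n_ec,
    )
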