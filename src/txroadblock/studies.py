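"""Seeded simulation studies: calibration, recovery and consistency.

Each function runs a self-contained multi-seed study of one pipeline
property — Monte-Carlo/exact p-value agreement, null calibration of the
bin test, roadblock position recovery, template-strand neutrality,
readthrough-estimator consistency, the expression dichotomy and the
alternative-polyadenylation sweep — and returns plain dictionaries of
measured quantities. The studies are deterministic given their seed.

Scenario geometry uses the default study locus: a roadblock inside the
gene body sits mid-bin so the stall point and pause window share one
bin; the post-PAS roadblock sits 2 kb past the terminal PAS (the
distance at which the native termination zone is replaced by the induced
one); qPCR-style checkpoints are 1-kb intervals placed at least 200 bp
clear of the pause window so fragment-length smearing cannot mix pause
and readthrough signal.
"""
from __future__ import annotations

import numpy as np

from ._util import derive_seed
from .binning import count_fragments, make_bins
from .binomial_test import (
    BinTestConfig,
    bin_test,
    exact_binomial_pvalue,
    mc_binomial_pvalue,
)
from .metrics import estimate_block_position, expression_ratio, interval_signal
from .simulate import (
    ElongationParams,
    GeneModel,
    Orientation,
    RoadblockConfig,
    default_locus,
    sample_fragments,
    simulate_expression,
    simulate_occupancy,
)

__all__ = [
    "mc_exact_agreement_study",
    "null_calibration_study",
    "block_recovery_study",
    "orientation_null_study",
    "readthrough_consistency_study",
    "expression_dichotomy_study",
    "apa_sweep_study",
]

# study-scale defaults: a 1e6-fragment library from 1e6 elongation
# complexes, the scale at which counting noise dominates fate noise
N_EC = 1_000_000
N_FRAGMENTS = 1_000_000
FRAG_LEN = 150

# exact tails are the analysis mode for the multi-seed studies; the
# Monte-Carlo null is validated against them in mc_exact_agreement_study
_STUDY_TEST = BinTestConfig(method="exact")


def _library(gene, block, params, seed, label):
    profile = simulate_occupancy(gene, block, params, N_EC, seed)
    frags = sample_fragments(profile, N_FRAGMENTS, FRAG_LEN, seed, label=label)
    return profile, frags


def _compare(gene, treated_frags, control_frags, cfg=_STUDY_TEST, bin_size=500):
    grid = make_bins(gene, bin_size)
    return bin_test(
        count_fragments(grid, treated_frags),
        count_fragments(grid, control_frags),
        cfg,
    )


def mc_exact_agreement_study(
    n_cases: int = 100, n_sim: int = 100_000, max_n: int = 10_000, seed: int = 0
) -> dict:
    """Monte-Carlo vs exact binomial p-values on random (k, n).

    n is uniform on [1, max_n]; k is drawn from the Binomial(n, 1/2)
    null so the resulting p-values span (0, 1] the way real null bins
    do. Agreement means |p_mc - p_exact| <= 4 sqrt(p(1-p)/n_sim).
    """
    rng = np.random.default_rng(derive_seed(seed, "mc-exact"))
    cfg = BinTestConfig(n_sim=n_sim, seed=derive_seed(seed, "mc-draws"))
    agree = 0
    abs_err = []
    for _ in range(n_cases):
        n = int(rng.integers(1, max_n + 1))
        k = int(rng.binomial(n, 0.5))
        exact = exact_binomial_pvalue(k, n)
        mc = mc_binomial_pvalue(k, n, cfg)
        bound = 4.0 * np.sqrt(exact * (1.0 - exact) / n_sim)
        abs_err.append(abs(mc - exact))
        if abs(mc - exact) <= max(bound, 2.0 / (n_sim + 1)):
            agree += 1
    return {
        "n_cases": n_cases,
        "n_agree": agree,
        "agreement_rate": agree / n_cases,
        "max_abs_error": float(max(abs_err)),
    }


def null_calibration_study(
    n_pairs: int = 20,
    seed: int = 0,
    gene: GeneModel | None = None,
    cfg: BinTestConfig = _STUDY_TEST,
) -> dict:
    """Significant-bin counts for pairs of identically-distributed libraries.

    Both libraries of a pair are simulated from the same no-block
    parameters with different seeds; at alpha = 1e-5 over the 173-bin
    default locus the expected false-positive count is ~0.002 per pair.
    """
    gene = gene or default_locus()
    params = ElongationParams()
    counts = []
    for i in range(n_pairs):
        _, a = _library(gene, None, params, derive_seed(seed, f"null-a-{i}"), "treated")
        _, b = _library(gene, None, params, derive_seed(seed, f"null-b-{i}"), "control")
        counts.append(_compare(gene, a, b, cfg).n_significant)
    return {
        "n_pairs": n_pairs,
        "significant_per_pair": counts,
        "total_significant": int(sum(counts)),
        "pairs_clean": int(sum(c == 0 for c in counts)),
    }


def block_recovery_study(
    n_seeds: int = 20,
    block_bin: int = 40,
    term_prob: float = 0.8,
    seed: int = 0,
    gene: GeneModel | None = None,
) -> dict:
    """Recover a known roadblock bin from the bin-test pattern.

    The block sits mid-bin (stall point at the bin centre). Success per
    seed: the estimated boundary bin is within one bin of the block bin,
    and the maximal positive log2fc bin equals the pause bin.
    """
    gene = gene or default_locus()
    grid = make_bins(gene)
    # place the dCas9 site so the stall (site - 19 bp) is the bin centre
    position = gene.locus_start + block_bin * grid.bin_size + grid.bin_size // 2 + 19
    block = RoadblockConfig(position=position, term_prob=term_prob)
    pause_bin = grid.bin_of(block.stall)
    params = ElongationParams()
    boundary_hits = pause_hits = 0
    boundaries = []
    for i in range(n_seeds):
        _, t = _library(gene, block, params, derive_seed(seed, f"rec-t-{i}"), "treated")
        _, c = _library(gene, None, params, derive_seed(seed, f"rec-c-{i}"), "control")
        res = _compare(gene, t, c)
        boundary = estimate_block_position(res)
        boundaries.append(boundary)
        if boundary is not None and abs(boundary - block_bin) <= 1:
            boundary_hits += 1
        if int(np.argmax(res.log2fc)) == pause_bin:
            pause_hits += 1
    return {
        "n_seeds": n_seeds,
        "block_bin": block_bin,
        "pause_bin": pause_bin,
        "boundaries": boundaries,
        "boundary_hits": boundary_hits,
        "pause_hits": pause_hits,
    }


def orientation_null_study(
    n_seeds: int = 20, seed: int = 0, gene: GeneModel | None = None
) -> dict:
    """Template-strand targeting vs control: significant bins per seed.

    T-orientation dCas9 presents no roadblock, so the comparison is a
    null and should flag no bins.
    """
    gene = gene or default_locus()
    grid = make_bins(gene)
    block = RoadblockConfig(
        position=gene.locus_start + 40 * grid.bin_size + grid.bin_size // 2 + 19,
        orientation=Orientation.T,
        term_prob=0.0,
        pause_dwell=1.0,
    )
    params = ElongationParams()
    counts = []
    for i in range(n_seeds):
        _, t = _library(gene, block, params, derive_seed(seed, f"ori-t-{i}"), "treated")
        _, c = _library(gene, None, params, derive_seed(seed, f"ori-c-{i}"), "control")
        counts.append(_compare(gene, t, c).n_significant)
    return {
        "n_seeds": n_seeds,
        "significant_per_seed": counts,
        "seeds_clean": int(sum(c == 0 for c in counts)),
    }


def _post_pas_block(gene: GeneModel) -> RoadblockConfig:
    """A roadblock 2 kb downstream of the terminal PAS (DS2-like)."""
    return RoadblockConfig(position=gene.pas_positions[-1] + 2_000, term_prob=0.8)


def readthrough_checkpoints(block: RoadblockConfig, width: int = 1_000, gap: int = 200):
    """US/DS checkpoint intervals flanking a block, clear of the pause window."""
    stall = block.stall
    us = (stall - block.pause_width - gap - width, stall - block.pause_width - gap)
    ds = (block.position + gap, block.position + gap + width)
    return us, ds


def readthrough_consistency_study(
    taus=(0.25, 0.5, 0.8), n_seeds: int = 20, seed: int = 0, gene: GeneModel | None = None
) -> dict:
    """Normalised downstream/upstream ratio vs the thinning expectation 1 - tau.

    One control library per seed is shared across the tau values; the
    block sits 2 kb past the terminal PAS, checkpoints flank it.
    """
    gene = gene or default_locus()
    params = ElongationParams()
    ratios: dict[float, list[float]] = {float(t): [] for t in taus}
    for i in range(n_seeds):
        _, c = _library(gene, None, params, derive_seed(seed, f"rt-c-{i}"), "control")
        for tau in taus:
            block = RoadblockConfig(position=gene.pas_positions[-1] + 2_000, term_prob=float(tau))
            us, ds = readthrough_checkpoints(block)
            _, t = _library(gene, block, params, derive_seed(seed, f"rt-t-{i}-{tau}"), "treated")
            num = interval_signal(t, *ds) / interval_signal(t, *us)
            den = interval_signal(c, *ds) / interval_signal(c, *us)
            ratios[float(tau)].append(num / den)
    return {
        "n_seeds": n_seeds,
        "mean_ratio": {tau: float(np.mean(v)) for tau, v in ratios.items()},
        "expected": {float(t): 1.0 - float(t) for t in taus},
    }


def expression_dichotomy_study(
    tau: float = 0.6, seed: int = 0, gene: GeneModel | None = None
) -> dict:
    """mRNA output ratio for an intragenic vs a post-PAS roadblock.

    An intragenic block aborts a fraction tau of transcripts (expected
    ratio 1 - tau); a block downstream of the PAS leaves expression
    unchanged (expected ratio 1).
    """
    gene = gene or default_locus()
    params = ElongationParams()
    ctrl_profile = simulate_occupancy(gene, None, params, N_EC, derive_seed(seed, "ex-c"))
    ctrl = simulate_expression(ctrl_profile, gene, params)
    intragenic = RoadblockConfig(
        position=(gene.tss + gene.pas_positions[0]) // 2, term_prob=tau
    )
    post_pas = _post_pas_block(gene)
    out = {}
    for name, block in (("intragenic", intragenic), ("post_pas", post_pas)):
        prof = simulate_occupancy(gene, block, params, N_EC, derive_seed(seed, f"ex-{name}"))
        summ = simulate_expression(prof, gene, params)
        out[name] = expression_ratio(summ, ctrl)
    se = float(np.sqrt(tau * (1 - tau) / N_EC))
    return {
        "n_ec": N_EC,
        "intragenic_ratio": out["intragenic"],
        "post_pas_ratio": out["post_pas"],
        "expected_intragenic": 1.0 - tau,
        "binomial_se": se,
    }


def apa_sweep_study(
    proximal_commit: float = 0.2,
    taus=(0.0, 0.25, 0.5, 0.75, 1.0),
    seed: int = 0,
) -> dict:
    """Inter-PAS roadblock sweep: up/down APA ratio and proximal-PAS usage.

    A two-PAS gene (proximal commitment c, terminal commitment 1) carries
    a block midway between the PAS. With rescue on, the closed-form
    proximal usage is c + (1 - c) * tau; the control-normalised up/down
    checkpoint ratio is non-decreasing in tau (the tau = 1 point rests on
    the fragment-length bleed floor of the 'down' checkpoint).
    """
    base = default_locus()
    distal = base.pas_positions[-1]
    proximal = distal - 10_000
    gene = GeneModel(
        chrom=base.chrom,
        locus_start=base.locus_start,
        locus_end=base.locus_end,
        tss=base.tss,
        pas_positions=(proximal, distal),
        gene_length=base.gene_length,
    )
    params = ElongationParams(pas_commit=(proximal_commit, 1.0), inter_pas_rescue=True)
    block_pos = (proximal + distal) // 2
    up = (proximal - 1_200, proximal - 200)

    _, c_frags = _library(gene, None, params, derive_seed(seed, "apa-c"), "control")
    norm_ratios = []
    proximal_fracs = []
    for tau in taus:
        block = RoadblockConfig(position=block_pos, term_prob=float(tau))
        down = (block.position + 100, block.position + 1_100)
        prof, t_frags = _library(gene, block, params, derive_seed(seed, f"apa-{tau}"), "treated")
        num = interval_signal(t_frags, *up) / interval_signal(t_frags, *down)
        den = interval_signal(c_frags, *up) / interval_signal(c_frags, *down)
        norm_ratios.append(num / den)
        summ = simulate_expression(prof, gene, params)
        proximal_fracs.append(summ.pas_counts[0] / summ.mrna_count)
    return {
        "taus": [float(t) for t in taus],
        "normalized_up_down_ratio": norm_ratios,
        "proximal_fraction": proximal_fracs,
        "expected_proximal_fraction": [
            proximal_commit + (1 - proximal_commit) * float(t) for t in taus
        ],
        "n_ec": N_EC,
    }
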