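"""Matched negative controls and the specificity panel.

Selects untargeted genes within 2,500 bp and 5 TPM of the target, then
runs the identical bin/normalise/test procedure on each: with a
roadblock simulated on the target only, significant bins appear only on
the target.
"""
import numpy as np

from txroadblock import (
    BinTestConfig,
    ElongationParams,
    FragmentSet,
    GeneModel,
    GeneRecord,
    MatchTolerance,
    RoadblockConfig,
    run_control_panel,
    sample_fragments,
    select_matched_controls,
    simulate_occupancy,
)

target = GeneRecord("target", "chrT", 2_000_000, 2_020_000, 20_000, tpm=12.0, targeted=True)
annotation = [target] + [
    GeneRecord(f"g{i}", "chrT", 1_000_000 + i * 60_000, 1_000_000 + i * 60_000 + l, l, tpm=t)
    for i, (l, t) in enumerate(
        [(20_500, 13.0), (22_400, 12.5), (18_000, 14.0), (26_000, 12.0), (20_000, 30.0)]
    )
]
controls = select_matched_controls(annotation, target, MatchTolerance())
print("matched controls:", [g.gene_id for g in controls],
      "(g3 fails the length window, g4 the TPM window)")


def library(genes, blocked_id, block, seed):
    starts, ends = [], []
    for g in genes:
        model = GeneModel(g.chrom, g.start, g.end, g.start, (g.end - 3_000,), g.length)
        prof = simulate_occupancy(
            model, block if g.gene_id == blocked_id else None,
            ElongationParams(), n_ec=60_000, seed=seed + g.start % 1_000,
        )
        f = sample_fragments(prof, 120_000, seed=seed + g.start % 1_000)
        starts.append(f.starts)
        ends.append(f.ends)
    return FragmentSet(
        chrom="chrT", starts=np.concatenate(starts), ends=np.concatenate(ends),
        locus_start=min(g.start for g in genes), locus_end=max(g.end for g in genes),
    )


panel = controls
block = RoadblockConfig(position=target.start + 8_000, term_prob=0.8)
treated = library(panel + [target], "target", block, seed=41)
control = library(panel + [target], None, None, seed=42)
summary = run_control_panel(panel, treated, control, BinTestConfig(method="exact"), target=target)
print(summary[["n_significant", "n_sig_depleted", "testable"]])
# Only the targeted gene shows significant (depleted) bins — the
# roadblock signature is locus-specific, not a normalisation artefact.
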