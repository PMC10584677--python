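"""End-to-end roadblock scan: simulate -> bin -> normalise -> test -> metrics.

A run is driven by one flat YAML config (keys mirror the domain types)
plus an integer seed. Re-running the same config and seed reproduces
every output byte-identically; the JSON summary records the seed, a hash
of the resolved config and per-stage counts.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from ._util import ConfigError, DataError, derive_seed
from .binning import DEFAULT_BIN_SIZE, count_fragments, coverage_track, make_bins
from .binomial_test import BinTestConfig, bin_test, heatmap_matrix
from .metrics import (
    estimate_block_position,
    expression_ratio,
    interval_signal,
    readthrough_ratio,
)
from .normalization import median_ratio_size_factors, normalize_track
from .simulate import (
    ElongationParams,
    GeneModel,
    RoadblockConfig,
    default_locus,
    sample_fragments,
    simulate_expression,
    simulate_occupancy,
)

logger = logging.getLogger(__name__)

__all__ = ["LibraryParams", "RunConfig", "run_roadblock_scan"]

SUMMARY_SCHEMA_VERSION = 1

_TOP_KEYS = {
    "gene", "block", "elongation", "library", "bin_size", "bin_test",
    "checkpoints", "seed", "outdir", "write_fragments", "render_heatmap",
}


@dataclass(frozen=True)
class LibraryParams:
    """Simulated library scale: initiated ECs, fragments, fragment length."""

    n_ec: int = 1_000_000
    n_fragments: int = 1_000_000
    frag_len: int = 150

    def __post_init__(self) -> None:
        if self.n_ec <= 0 or self.n_fragments <= 0 or self.frag_len < 1:
            raise ConfigError("library parameters must be positive")


@dataclass
class RunConfig:
    """Validated configuration for one end-to-end scan."""

    gene: GeneModel = field(default_factory=default_locus)
    block: RoadblockConfig | None = None
    elongation: ElongationParams = field(default_factory=ElongationParams)
    library: LibraryParams = field(default_factory=LibraryParams)
    bin_size: int = DEFAULT_BIN_SIZE
    bin_test: BinTestConfig = field(default_factory=BinTestConfig)
    checkpoints: dict[str, tuple[int, int]] = field(default_factory=dict)
    seed: int = 0
    outdir: Path = Path("txroadblock_out")
    write_fragments: bool = False
    render_heatmap: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        """Build and validate a config; collect all offending keys."""
        errors: list[str] = []
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            errors.append(f"unknown top-level keys: {sorted(unknown)}")

        def build(factory, key, **kwargs):
            try:
                return factory(**kwargs)
            except (ConfigError, TypeError) as exc:
                errors.append(f"{key}: {exc}")
                return None

        gene = default_locus()
        if "gene" in raw:
            g = dict(raw["gene"])
            if "pas_positions" in g:
                g["pas_positions"] = tuple(g["pas_positions"])
            gene = build(GeneModel, "gene", **g) or gene
        block = None
        if raw.get("block") is not None:
            block = build(RoadblockConfig, "block", **raw["block"])
        elong = ElongationParams()
        if "elongation" in raw:
            e = dict(raw["elongation"])
            if "pas_commit" in e:
                e["pas_commit"] = tuple(e["pas_commit"])
            elong = build(ElongationParams, "elongation", **e) or elong
        library = build(LibraryParams, "library", **raw.get("library", {})) or LibraryParams()
        btcfg = build(BinTestConfig, "bin_test", **raw.get("bin_test", {})) or BinTestConfig()

        checkpoints: dict[str, tuple[int, int]] = {}
        for name, iv in (raw.get("checkpoints") or {}).items():
            if not (isinstance(iv, (list, tuple)) and len(iv) == 2 and iv[0] < iv[1]):
                errors.append(f"checkpoints.{name}: need [start, end] with start < end")
            else:
                checkpoints[name] = (int(iv[0]), int(iv[1]))

        bin_size = int(raw.get("bin_size", DEFAULT_BIN_SIZE))
        if bin_size < 1:
            errors.append("bin_size: must be >= 1")
        if gene is not None and elong is not None and len(elong.pas_commit) != len(gene.pas_positions):
            errors.append("elongation.pas_commit: length must match gene.pas_positions")
        if errors:
            raise ConfigError("invalid run config: " + "; ".join(errors))
        return cls(
            gene=gene,
            block=block,
            elongation=elong,
            library=library,
            bin_size=bin_size,
            bin_test=btcfg,
            checkpoints=checkpoints,
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "txroadblock_out")),
            write_fragments=bool(raw.get("write_fragments", False)),
            render_heatmap=bool(raw.get("render_heatmap", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(tio.read_config(path))

    def resolved(self) -> dict:
        """JSON-serialisable view of the resolved configuration."""
        out = {
            "gene": asdict(self.gene),
            "block": asdict(self.block) if self.block else None,
            "elongation": asdict(self.elongation),
            "library": asdict(self.library),
            "bin_size": self.bin_size,
            "bin_test": asdict(self.bin_test),
            "checkpoints": {k: list(v) for k, v in self.checkpoints.items()},
            "seed": self.seed,
        }
        if self.block:
            out["block"]["orientation"] = self.block.orientation.value
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_roadblock_scan(cfg: RunConfig, seed: int | None = None) -> dict:
    """Execute the full analysis for one config; returns the JSON summary.

    Stages: simulate control and treated occupancy, sample fragment
    libraries, per-bp CPM coverage (bedGraph), 500-bp binning, gene-level
    median-ratio size factors applied to bin tracks, per-bin binomial
    test, heatmap matrix, block-boundary estimate, expression ratio and
    any declared checkpoint (readthrough) ratios. All outputs are written
    under ``cfg.outdir``.
    """
    if seed is not None:
        cfg.seed = int(seed)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene, lib = cfg.gene, cfg.library
    logger.info("scan: seed=%d config=%s", cfg.seed, cfg.config_hash())

    runs = {}
    for name, block in (("control", None), ("treated", cfg.block)):
        run_seed = derive_seed(cfg.seed, name)
        profile = simulate_occupancy(gene, block, cfg.elongation, lib.n_ec, run_seed)
        frags = sample_fragments(profile, lib.n_fragments, lib.frag_len, run_seed, label=name)
        runs[name] = (profile, frags)
        tio.write_bedgraph(
            coverage_track(frags, frags.library_size),
            gene.chrom, gene.locus_start, outdir / f"{name}.coverage.bedgraph",
        )
        if cfg.write_fragments:
            tio.write_bed(frags, outdir / f"{name}.fragments.bed")
        logger.info("%s: fates=%s", name, runs[name][0].fates)

    grid = make_bins(gene, cfg.bin_size)
    raw = {name: count_fragments(grid, frags) for name, (_, frags) in runs.items()}
    gene_counts = np.array(
        [[interval_signal(runs["treated"][1], gene.locus_start, gene.locus_end)],
         [interval_signal(runs["control"][1], gene.locus_start, gene.locus_end)]]
    ).T
    factors = median_ratio_size_factors(
        pd.DataFrame(gene_counts, index=[gene.chrom], columns=["treated", "control"])
    )
    tio.write_size_factors(factors, outdir / "size_factors.tsv")
    norm = {name: normalize_track(raw[name], factors[name]) for name in raw}
    for name in norm:
        tio.write_bin_track(norm[name], outdir / f"{name}.bins.tsv")

    result = bin_test(norm["treated"], norm["control"], cfg.bin_test)
    result.to_tsv(outdir / "bin_test.tsv")
    hm = heatmap_matrix([result], labels=["treated_vs_control"])
    hm.to_csv(outdir / "heatmap.tsv", sep="\t", na_rep="NA")
    if cfg.render_heatmap:
        from .binomial_test import render_heatmap

        render_heatmap(hm, outdir / "heatmap.png")

    expr = {
        name: simulate_expression(profile, gene, cfg.elongation)
        for name, (profile, _) in runs.items()
    }
    boundary = estimate_block_position(result)

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.resolved(),
        "size_factors": {k: float(v) for k, v in factors.items()},
        "fates": {name: runs[name][0].fates for name in runs},
        "n_bins": grid.n_bins,
        "n_significant": result.n_significant,
        "n_sig_depleted": int((result.significant & (result.log2fc < 0)).sum()),
        "n_sig_elevated": int((result.significant & (result.log2fc > 0)).sum()),
        "boundary_bin": boundary,
        "expression_ratio": expression_ratio(expr["treated"], expr["control"]),
        "mrna_counts": {name: expr[name].mrna_count for name in expr},
        "pas_counts": {name: list(expr[name].pas_counts) for name in expr},
    }
    if {"us", "ds"} <= set(cfg.checkpoints):
        us, ds = cfg.checkpoints["us"], cfg.checkpoints["ds"]
        rt = readthrough_ratio(
            interval_signal(runs["treated"][1], *ds),
            interval_signal(runs["treated"][1], *us),
            interval_signal(runs["control"][1], *ds),
            interval_signal(runs["control"][1], *us),
        )
        summary["readthrough"] = {
            "ratio_treated": rt.ratio_treated,
            "ratio_control": rt.ratio_control,
            "normalized_ratio": rt.normalized_ratio,
        }
    tio.write_json(summary, outdir / "summary.json")
    return summary
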