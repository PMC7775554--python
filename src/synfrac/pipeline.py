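"""End-to-end orchestration: annotations -> homology -> synteny ->
fractionation -> stats (-> translocation audit), with file outputs.

`analyze` is the in-memory core used by the examples, the tests and the
acceptance script; `run_pipeline` wraps it with file I/O and a JSON/TSV
report bundle.  Every auto-selected parameter (notably the similarity
window) is recorded in the report so a run is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from pydantic import BaseModel, Field, model_validator

from . import annotations as ann
from . import fractionation as frac
from . import homology as hom
from . import stats as st
from . import synteny as syn
from . import translocation as tl

__all__ = ["RunConfig", "Analysis", "PipelineError", "analyze", "run_pipeline", "run_sensitivity"]


class PipelineError(RuntimeError):
    pass


class RunConfig(BaseModel):
    """File-based pipeline configuration (CLI mirrors these fields)."""

    gff_a: Optional[Path] = None
    gff_b: Optional[Path] = None
    bed_a: Optional[Path] = None
    bed_b: Optional[Path] = None
    anchors: Path
    sizes_a: Path
    sizes_b: Optional[Path] = None
    mode: str = "self"  # "self" | "cross"
    max_gap: int = Field(default=20, ge=1)
    min_block_size: int = Field(default=5, ge=1)
    similarity_policy: str = "auto"  # "auto" | "manual"
    sim_window: Optional[Tuple[float, float]] = None
    bin_width: float = Field(default=1.0, gt=0)
    regression_mode: str = "raw"  # "raw" | "length_means"
    l_cap: int = Field(default=30, ge=2)
    strict_gaps: bool = False
    run_audit: bool = False
    out_dir: Path = Path("synfrac_out")

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mode not in ("self", "cross"):
            raise ValueError(f"mode must be self or cross, got {self.mode!r}")
        if (self.gff_a is None) == (self.bed_a is None):
            raise ValueError("provide exactly one of gff_a / bed_a")
        if self.mode == "cross":
            if (self.gff_b is None) == (self.bed_b is None):
                raise ValueError("cross mode needs exactly one of gff_b / bed_b")
            if self.sizes_b is None:
                raise ValueError("cross mode needs sizes_b")
        if self.similarity_policy == "manual" and self.sim_window is None:
            raise ValueError("manual similarity policy needs sim_window")
        return self


@dataclass
class Analysis:
    """Everything one comparison produces, in memory."""

    window: hom.SimilarityWindow
    blocks_all: List[syn.SyntenyBlock]
    blocks: List[syn.SyntenyBlock]  # retained after similarity filtering
    gaps: List[frac.BlockGap]
    intervals: List[frac.DeletionInterval]
    profile: frac.IntervalProfile
    fit_unfractionated: st.RegressionFit
    fit_fractionated: st.RegressionFit
    slope_comparison: st.SlopeComparison
    density: List[st.DensityPoint]
    audit: Optional[tl.TranslocationAudit] = None
    params: Dict = field(default_factory=dict)


def analyze(
    table_a: ann.GeneTable,
    table_b: ann.GeneTable,
    pairs: Sequence[hom.AnchorPair],
    sizes_a: Dict[str, int],
    sizes_b: Optional[Dict[str, int]] = None,
    *,
    self_comparison: bool = False,
    max_gap: int = 20,
    min_block_size: int = 5,
    similarity_policy: str = "auto",
    sim_window: Optional[Tuple[float, float]] = None,
    bin_width: float = 1.0,
    regression_mode: str = "raw",
    l_cap: int = 30,
    strict_gaps: bool = False,
    run_audit: bool = False,
) -> Analysis:
    """Run the whole comparison on in-memory objects."""
    if similarity_policy == "manual":
        window = hom.select_similarity_window(
            hom.Histogram(bin_width, {}), "manual", sim_window
        )
    else:
        hist = hom.similarity_histogram(pairs, bin_width)
        window = hom.select_similarity_window(hist, "highest_mode")

    blocks_all = syn.chain_anchors(
        pairs, table_a, table_b, max_gap, min_block_size, self_comparison
    )
    if not blocks_all:
        raise PipelineError(
            "no synteny blocks found: the chaining step "
            f"(max_gap={max_gap}, min_block_size={min_block_size}) emptied the set"
        )
    blocks = syn.filter_blocks_by_similarity(blocks_all, window)
    if not blocks:
        raise PipelineError(
            f"no blocks retained: the similarity window ({window.lower}, {window.upper}) "
            "emptied the set; consider the manual policy"
        )

    # "pairing-visible" genes are those the block construction itself pairs:
    # a gene in any chained block's anchors is demonstrably two-copy, while
    # genes paired only outside blocks (the min-block-size-1 view) stay
    # eligible as singletons — that distinction is what the translocation
    # audit quantifies afterwards
    paired_a = {a.gene_a for b in blocks_all for a in b.anchors}
    paired_b = {a.gene_b for b in blocks_all for a in b.anchors}
    if self_comparison:
        paired_a = paired_a | paired_b
        paired_b = paired_a
    gaps: List[frac.BlockGap] = []
    intervals: List[frac.DeletionInterval] = []
    for block in blocks:
        bgaps = frac.scan_block_gaps(block, table_a, table_b, paired_a, paired_b)
        gaps.extend(bgaps)
        intervals.extend(
            frac.scan_deletion_intervals(
                block, table_a, table_b, paired_a, paired_b, strict=strict_gaps
            )
        )
    if not intervals:
        raise PipelineError("no deletion intervals found in the retained blocks")

    profile = frac.aggregate_profile(intervals)
    fit_u = st.fit_interval_regression(intervals, "unfractionated", regression_mode, l_cap)
    fit_f = st.fit_interval_regression(intervals, "fractionated", regression_mode, l_cap)
    comparison = st.compare_slopes(fit_u, fit_f)

    summary_a = ann.summarize_genome(table_a, sizes_a)
    summary_b = (
        summary_a if self_comparison else ann.summarize_genome(table_b, sizes_b or {})
    )
    density = st.density_comparison(gaps, summary_a, summary_b, pooled=self_comparison)

    audit = None
    if run_audit:
        singles = tl.collect_singletons(blocks, intervals, side="both")
        if singles:
            audit = tl.find_remote_partners(singles, pairs, window, table_a.genome_id)

    return Analysis(
        window=window,
        blocks_all=blocks_all,
        blocks=blocks,
        gaps=gaps,
        intervals=intervals,
        profile=profile,
        fit_unfractionated=fit_u,
        fit_fractionated=fit_f,
        slope_comparison=comparison,
        density=density,
        audit=audit,
        params={
            "max_gap": max_gap,
            "min_block_size": min_block_size,
            "similarity_policy": similarity_policy,
            "window": [window.lower, window.upper],
            "regression_mode": regression_mode,
            "l_cap": l_cap,
            "strict_gaps": strict_gaps,
        },
    )


def _load_tables(config: RunConfig) -> Tuple[ann.GeneTable, ann.GeneTable, Dict, Optional[Dict]]:
    table_a = (
        ann.read_gff3(config.gff_a) if config.gff_a else ann.read_bed(config.bed_a)
    )
    sizes_a = ann.read_assembly_sizes(config.sizes_a)
    if config.mode == "self":
        return table_a, table_a, sizes_a, None
    table_b = (
        ann.read_gff3(config.gff_b) if config.gff_b else ann.read_bed(config.bed_b)
    )
    sizes_b = ann.read_assembly_sizes(config.sizes_b)
    return table_a, table_b, sizes_a, sizes_b


def run_pipeline(config: RunConfig) -> Dict:
    """File-based run: loads inputs, analyzes, writes the report bundle."""
    table_a, table_b, sizes_a, sizes_b = _load_tables(config)
    pairs = hom.read_anchor_pairs(config.anchors, self_comparison=config.mode == "self")
    analysis = analyze(
        table_a,
        table_b,
        pairs,
        sizes_a,
        sizes_b,
        self_comparison=config.mode == "self",
        max_gap=config.max_gap,
        min_block_size=config.min_block_size,
        similarity_policy="manual" if config.sim_window else config.similarity_policy,
        sim_window=config.sim_window,
        bin_width=config.bin_width,
        regression_mode=config.regression_mode,
        l_cap=config.l_cap,
        strict_gaps=config.strict_gaps,
        run_audit=config.run_audit,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn.write_blocks(analysis.blocks, out / "blocks.tsv")
    frac.write_intervals(analysis.intervals, out / "intervals.tsv")
    analysis.profile.table.to_csv(out / "profile.tsv", sep="\t")
    report = build_report(analysis)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "density.tsv", "w") as fh:
        fh.write("genome_id\tbp_per_gene_in_blocks\tbp_per_gene_genomewide\n")
        for d in analysis.density:
            fh.write(
                f"{d.genome_id}\t{d.bp_per_gene_in_blocks:.2f}\t{d.bp_per_gene_genomewide:.2f}\n"
            )
    if analysis.audit is not None:
        tl.write_audit(analysis.audit, out / "audit.json", out / "audit.tsv")
    return report


def build_report(analysis: Analysis) -> Dict:
    report = {
        "params": analysis.params,
        "n_blocks_all": len(analysis.blocks_all),
        "n_blocks_retained": len(analysis.blocks),
        "n_intervals": len(analysis.intervals),
        "fit_unfractionated": {
            "slope": analysis.fit_unfractionated.slope,
            "intercept": analysis.fit_unfractionated.intercept,
            "se_slope": analysis.fit_unfractionated.se_slope,
            "n": analysis.fit_unfractionated.n,
            "r_squared": analysis.fit_unfractionated.r_squared,
        },
        "fit_fractionated": {
            "slope": analysis.fit_fractionated.slope,
            "intercept": analysis.fit_fractionated.intercept,
            "se_slope": analysis.fit_fractionated.se_slope,
            "n": analysis.fit_fractionated.n,
            "r_squared": analysis.fit_fractionated.r_squared,
        },
        "slope_comparison": {
            "t": analysis.slope_comparison.t_statistic,
            "df": analysis.slope_comparison.degrees_of_freedom,
            "p": analysis.slope_comparison.p_value,
        },
        "density": [
            {
                "genome_id": d.genome_id,
                "bp_per_gene_in_blocks": d.bp_per_gene_in_blocks,
                "bp_per_gene_genomewide": d.bp_per_gene_genomewide,
            }
            for d in analysis.density
        ],
    }
    if analysis.audit is not None:
        report["audit"] = {
            "n_singletons": analysis.audit.n_singletons,
            "n_paired_remotely": analysis.audit.n_paired_remotely,
            "percent_paired": analysis.audit.percent_paired,
        }
    return report


def run_sensitivity(
    config: RunConfig, thresholds: Sequence[int] = (3, 4, 5, 6)
) -> Dict[int, int]:
    """Genes-in-blocks for each minimum-block-size threshold."""
    table_a, table_b, _, _ = _load_tables(config)
    pairs = hom.read_anchor_pairs(config.anchors, self_comparison=config.mode == "self")
    return syn.block_size_sensitivity(
        pairs, table_a, table_b, config.max_gap, thresholds,
        self_comparison=config.mode == "self",
    )
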