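"""Deletion-interval scanning and residual-DNA span measurement.

Within a retained synteny block, the gap between two consecutive anchors is
a *deletion interval* when one side (the unfractionated side) carries L >= 1
contiguous single-copy genes while the other side (the fractionated side)
carries no annotated gene at all.  L is the interval's length; the DNA span
between the bounding anchor genes is measured on both sides.  Under
excision the fractionated span stays at a small residual regardless of L;
under pseudogenization the DNA (though not the annotations) remains, so the
fractionated span grows with L like the unfractionated one.

"Single-copy" is judged against a caller-supplied set of pairing-visible
gene ids — in the pipeline, genes appearing in any chained block's anchors.
A visible (demonstrably two-copy) gene anywhere in a gap marks the gap
"mixed": segments displaced by rearrangements look locally like deletions
but still carry their partners elsewhere, and counting them would
contaminate the span regressions.  Gaps with unpaired annotated genes on
*both* sides cannot be oriented and are marked "ambiguous".
``nonanchor_genes_in_gap`` is retained in the record/TSV contract for scans
run with a narrower visibility set, where the fractionated side may hold
annotated-but-invisible gene models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotations import GeneRecord, GeneTable
from .synteny import PlacedAnchor, SyntenyBlock

__all__ = [
    "BlockGap",
    "DeletionInterval",
    "IntervalProfile",
    "PseudogeneCapacity",
    "FractionationError",
    "scan_block_gaps",
    "scan_deletion_intervals",
    "measure_spans",
    "aggregate_profile",
    "pseudogene_capacity",
    "write_intervals",
]


class FractionationError(ValueError):
    pass


@dataclass(frozen=True)
class BlockGap:
    """One consecutive-anchor gap of a block, measured on both sides.

    ``kind`` is "conserved" (no genes between on either side), "deletion"
    (genes on exactly one side, none pairing-visible on the other),
    "ambiguous" (annotated genes on both sides but none visible on either),
    or "mixed" (pairing-visible genes on both sides).  ``bp_*`` spans run
    end-of-earlier-bounding-gene to start-of-later-bounding-gene;
    ``span_*`` run start-to-start so that each gap plus its left bounding
    anchor gene tiles the block, which is what gene-density accounting
    needs.
    """

    block_id: int
    left: PlacedAnchor
    right: PlacedAnchor
    kind: str
    genes_a: Tuple[GeneRecord, ...]
    genes_b: Tuple[GeneRecord, ...]
    visible_a: int
    visible_b: int
    bp_a: int
    bp_b: int
    span_a: int
    span_b: int
    flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class DeletionInterval:
    """A between-anchor gap where exactly one side lost its genes."""

    block_id: int
    chrom_a: str
    chrom_b: str
    left_anchor: PlacedAnchor
    right_anchor: PlacedAnchor
    length: int
    bp_unfractionated: int
    bp_fractionated: int
    fractionated_genome: str  # "A" | "B"
    nonanchor_genes_in_gap: int
    singleton_gene_ids: Tuple[str, ...]
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise FractionationError("deletion interval length must be >= 1")
        if self.fractionated_genome not in ("A", "B"):
            raise FractionationError("fractionated_genome must be 'A' or 'B'")


class PseudogeneCapacity(NamedTuple):
    capacity: float  # upper bound on full-length pseudogenes in the gap
    bp_per_missing_gene: float


@dataclass
class IntervalProfile:
    """Per-length means of both spans, plus the raw interval list."""

    table: pd.DataFrame  # index L; columns mean_bp_unfractionated, mean_bp_fractionated, n
    intervals: List[DeletionInterval] = field(default_factory=list)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)


def _span_between(left_gene: GeneRecord, right_gene: GeneRecord) -> Tuple[int, bool]:
    """bp from end of the positionally earlier gene to start of the later one.

    Bounding genes are oriented by coordinate, so inverted blocks need no
    special casing; overlapping bounding genes clamp to 0 with a flag.
    """
    first, second = sorted((left_gene, right_gene), key=lambda g: (g.start, g.end))
    raw = second.start - first.end
    return (max(raw, 0), raw < 0)


def measure_spans(
    left: PlacedAnchor,
    right: PlacedAnchor,
    table_a: GeneTable,
    table_b: GeneTable,
    block: Optional[SyntenyBlock] = None,
) -> Tuple[int, int, Tuple[str, ...]]:
    """(bp on side A, bp on side B, flags) between two bounding anchors."""
    ga_l, ga_r = table_a.gene(left.gene_a), table_a.gene(right.gene_a)
    gb_l, gb_r = table_b.gene(left.gene_b), table_b.gene(right.gene_b)
    if block is not None:
        if ga_l.chromosome != block.chrom_a or ga_r.chromosome != block.chrom_a:
            raise FractionationError(
                f"block {block.block_id}: bounding genes not on declared chrom_a"
            )
        if gb_l.chromosome != block.chrom_b or gb_r.chromosome != block.chrom_b:
            raise FractionationError(
                f"block {block.block_id}: bounding genes not on declared chrom_b"
            )
    bp_a, clamped_a = _span_between(ga_l, ga_r)
    bp_b, clamped_b = _span_between(gb_l, gb_r)
    flags = tuple(
        f for f, hit in (("clamped_a", clamped_a), ("clamped_b", clamped_b)) if hit
    )
    return bp_a, bp_b, flags


def scan_block_gaps(
    block: SyntenyBlock,
    table_a: GeneTable,
    table_b: GeneTable,
    paired_a: Optional[Set[str]] = None,
    paired_b: Optional[Set[str]] = None,
) -> List[BlockGap]:
    """Classify and measure every consecutive-anchor gap of a block.

    ``paired_a``/``paired_b`` are the gene ids appearing in any anchor pair
    of the comparison; when omitted, every annotated gene counts as
    pairing-visible (the conservative reading).
    """
    gaps: List[BlockGap] = []
    anchors = block.anchors
    for left, right in zip(anchors, anchors[1:]):
        if right.rank_a <= left.rank_a:
            raise FractionationError(
                f"block {block.block_id}: anchors out of order on side A"
            )
        if (right.rank_b - left.rank_b) * (-1 if block.orientation == "inverted" else 1) <= 0:
            raise FractionationError(
                f"block {block.block_id}: anchors out of order on side B"
            )
        genes_a = table_a.genes_between(block.chrom_a, left.rank_a, right.rank_a)
        genes_b = table_b.genes_between(block.chrom_b, left.rank_b, right.rank_b)
        vis_a = sum(1 for g in genes_a if paired_a is None or g.gene_id in paired_a)
        vis_b = sum(1 for g in genes_b if paired_b is None or g.gene_id in paired_b)
        bp_a, bp_b, flags = measure_spans(left, right, table_a, table_b, block)

        ga_l, ga_r = table_a.gene(left.gene_a), table_a.gene(right.gene_a)
        gb_l, gb_r = table_b.gene(left.gene_b), table_b.gene(right.gene_b)
        span_a = abs(max(ga_l.start, ga_r.start) - min(ga_l.start, ga_r.start))
        span_b = abs(max(gb_l.start, gb_r.start) - min(gb_l.start, gb_r.start))

        if not genes_a and not genes_b:
            kind = "conserved"
        elif vis_a > 0 or vis_b > 0:
            # a pairing-visible gene anywhere in the gap means this is not a
            # clean single-copy stretch (e.g. a displaced segment), not a
            # deletion
            kind = "mixed"
        elif genes_a and not genes_b:
            kind = "deletion"  # fractionated side is B
        elif genes_b and not genes_a:
            kind = "deletion"  # fractionated side is A
        else:
            kind = "ambiguous"  # unpaired genes on both sides: cannot orient
        gaps.append(
            BlockGap(
                block.block_id, left, right, kind,
                genes_a, genes_b, vis_a, vis_b, bp_a, bp_b, span_a, span_b, flags,
            )
        )
    return gaps


def scan_deletion_intervals(
    block: SyntenyBlock,
    table_a: GeneTable,
    table_b: GeneTable,
    paired_a: Optional[Set[str]] = None,
    paired_b: Optional[Set[str]] = None,
    strict: bool = False,
) -> List[DeletionInterval]:
    """Deletion intervals of one block (see module docstring for the rule).

    With ``strict=True``, intervals whose fractionated side contains any
    annotated (unpaired) gene are excluded instead of flagged.
    """
    out: List[DeletionInterval] = []
    for gap in scan_block_gaps(block, table_a, table_b, paired_a, paired_b):
        if gap.kind != "deletion":
            continue
        if gap.genes_a:
            fractionated, singletons = "B", gap.genes_a
            bp_unfrac, bp_frac = gap.bp_a, gap.bp_b
            nonanchor = len(gap.genes_b)
        else:
            fractionated, singletons = "A", gap.genes_b
            bp_unfrac, bp_frac = gap.bp_b, gap.bp_a
            nonanchor = len(gap.genes_a)
        if strict and nonanchor > 0:
            continue
        out.append(
            DeletionInterval(
                block_id=block.block_id,
                chrom_a=block.chrom_a,
                chrom_b=block.chrom_b,
                left_anchor=gap.left,
                right_anchor=gap.right,
                length=len(singletons),
                bp_unfractionated=bp_unfrac,
                bp_fractionated=bp_frac,
                fractionated_genome=fractionated,
                nonanchor_genes_in_gap=nonanchor,
                singleton_gene_ids=tuple(g.gene_id for g in singletons),
                flags=gap.flags,
            )
        )
    return out


def aggregate_profile(intervals: Iterable[DeletionInterval]) -> IntervalProfile:
    """Group intervals by exact length; report both per-length mean spans."""
    intervals = list(intervals)
    if not intervals:
        empty = pd.DataFrame(
            columns=["mean_bp_unfractionated", "mean_bp_fractionated", "n"]
        )
        empty.index.name = "length"
        return IntervalProfile(empty, [])
    df = pd.DataFrame(
        {
            "length": [iv.length for iv in intervals],
            "bp_unfractionated": [iv.bp_unfractionated for iv in intervals],
            "bp_fractionated": [iv.bp_fractionated for iv in intervals],
        }
    )
    grouped = df.groupby("length").agg(
        mean_bp_unfractionated=("bp_unfractionated", "mean"),
        mean_bp_fractionated=("bp_fractionated", "mean"),
        n=("bp_unfractionated", "size"),
    )
    return IntervalProfile(grouped.sort_index(), intervals)


def pseudogene_capacity(
    interval: DeletionInterval, mean_gene_bp: float
) -> PseudogeneCapacity:
    """Upper bound on full-length pseudogenes the fractionated gap could hold.

    Also reports residual bp per missing gene; near-zero values are the
    excision signature, values near the genome's bp-per-gene indicate
    retained (pseudogenized) DNA.
    """
    if mean_gene_bp <= 0:
        raise FractionationError(f"mean_gene_bp must be positive, got {mean_gene_bp}")
    return PseudogeneCapacity(
        capacity=interval.bp_fractionated / float(mean_gene_bp),
        bp_per_missing_gene=interval.bp_fractionated / interval.length,
    )


def write_intervals(intervals: Iterable[DeletionInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#block_id\tchrom_a\tchrom_b\tlength\tbp_unfractionated\t"
            "bp_fractionated\tfractionated_genome\tnonanchor_genes_in_gap\tflags\n"
        )
        for iv in intervals:
            fh.write(
                f"{iv.block_id}\t{iv.chrom_a}\t{iv.chrom_b}\t{iv.length}\t"
                f"{iv.bp_unfractionated}\t{iv.bp_fractionated}\t"
                f"{iv.fractionated_genome}\t{iv.nonanchor_genes_in_gap}\t"
                f"{','.join(iv.flags) or '.'}\n"
            )
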