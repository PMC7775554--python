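"""Regressions on deletion-interval spans and cross-genome density comparison.

The central statistic: regress DNA span (bp) between bounding anchors on
interval length L (genes).  On the unfractionated side the slope estimates
the genome's mean bp per gene (the inverse of gene density); on the
fractionated side a slope near zero — residual DNA independent of how many
genes were lost — is the signature of excision, while a slope comparable to
the unfractionated one indicates DNA retained in place (pseudogenization).
Slopes are compared with a Welch t-test on the two fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotations import GenomeSummary
from .fractionation import BlockGap, DeletionInterval, IntervalProfile

__all__ = [
    "RegressionFit",
    "SlopeComparison",
    "DensityPoint",
    "StatsError",
    "fit_linear",
    "interval_points",
    "fit_interval_regression",
    "compare_slopes",
    "normalize_profile",
    "genome_size_factor",
    "density_comparison",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares fit of bp against interval length."""

    slope: float  # bp per gene
    intercept: float  # bp
    se_slope: float
    n: int
    r_squared: float

    @property
    def residual_df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class SlopeComparison:
    """Welch t-test on the difference of two regression slopes."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class DensityPoint:
    """bp-per-gene inside unfractionated block regions vs. genome-wide."""

    genome_id: str
    bp_per_gene_in_blocks: float
    bp_per_gene_genomewide: float

    def __post_init__(self) -> None:
        if self.bp_per_gene_in_blocks <= 0 or self.bp_per_gene_genomewide <= 0:
            raise StatsError("density point coordinates must be positive")


def fit_linear(points: Iterable[Tuple[float, float]], mode: str = "raw") -> RegressionFit:
    """OLS of bp on L.

    raw: every interval is one point (honest standard errors, the default).
    length_means: fit the per-L mean spans, one point per distinct L (the
    plotted quantity in per-length profile figures).
    """
    pts = [(float(l), float(bp)) for l, bp in points]
    if mode == "length_means":
        df = pd.DataFrame(pts, columns=["L", "bp"]).groupby("L")["bp"].mean()
        pts = list(df.items())
    elif mode != "raw":
        raise StatsError(f"unknown regression mode {mode!r}")
    if len(pts) < 3:
        raise StatsError(f"need >= 3 points for a fit, got {len(pts)}")
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(xs).size < 2:
        raise StatsError("all interval lengths identical; slope undefined")
    res = sps.linregress(xs, ys)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        n=len(pts),
        r_squared=float(res.rvalue**2),
    )


def interval_points(
    intervals: Iterable[DeletionInterval],
    side: str = "unfractionated",
    l_cap: int | None = 30,
) -> List[Tuple[int, int]]:
    """(L, bp) points for one side; lengths beyond ``l_cap`` are excluded
    from fitting because long intervals are few and noisy."""
    if side not in ("unfractionated", "fractionated"):
        raise StatsError(f"side must be un/fractionated, got {side!r}")
    pts = []
    for iv in intervals:
        if l_cap is not None and iv.length > l_cap:
            continue
        bp = iv.bp_unfractionated if side == "unfractionated" else iv.bp_fractionated
        pts.append((iv.length, bp))
    return pts


def fit_interval_regression(
    intervals: Iterable[DeletionInterval],
    side: str = "unfractionated",
    mode: str = "raw",
    l_cap: int | None = 30,
) -> RegressionFit:
    return fit_linear(interval_points(intervals, side, l_cap), mode=mode)


def compare_slopes(fit1: RegressionFit, fit2: RegressionFit) -> SlopeComparison:
    """Two-sided Welch t-test for slope1 == slope2 (unpooled variances)."""
    se1, se2 = fit1.se_slope, fit2.se_slope
    diff = fit1.slope - fit2.slope
    if se1 == 0.0 and se2 == 0.0:
        if diff == 0.0:
            return SlopeComparison(0.0, float(fit1.residual_df + fit2.residual_df), 1.0)
        return SlopeComparison(
            math.copysign(math.inf, diff),
            float(fit1.residual_df + fit2.residual_df),
            0.0,
            degenerate=True,
        )
    pooled = se1**2 + se2**2
    t = diff / math.sqrt(pooled)
    # Welch-Satterthwaite from the two fits' residual degrees of freedom
    df = pooled**2 / (
        (se1**4 / fit1.residual_df if se1 else 0.0)
        + (se2**4 / fit2.residual_df if se2 else 0.0)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return SlopeComparison(t, df, min(p, 1.0))


def normalize_profile(profile: IntervalProfile, factor: float) -> IntervalProfile:
    """Divide all bp values by a genome-size factor; lengths untouched.

    Spans are scaled as exact rationals so that normalizing by ``factor``
    and then by ``1/factor`` round-trips to the original values.
    """
    if factor <= 0:
        raise StatsError(f"normalization factor must be positive, got {factor}")
    f = Fraction(factor)
    table = profile.table.copy()
    for col in ("mean_bp_unfractionated", "mean_bp_fractionated"):
        table[col] = table[col] / factor
    scaled = [
        DeletionInterval(
            block_id=iv.block_id,
            chrom_a=iv.chrom_a,
            chrom_b=iv.chrom_b,
            left_anchor=iv.left_anchor,
            right_anchor=iv.right_anchor,
            length=iv.length,
            bp_unfractionated=Fraction(iv.bp_unfractionated) / f,
            bp_fractionated=Fraction(iv.bp_fractionated) / f,
            fractionated_genome=iv.fractionated_genome,
            nonanchor_genes_in_gap=iv.nonanchor_genes_in_gap,
            singleton_gene_ids=iv.singleton_gene_ids,
            flags=iv.flags,
        )
        for iv in profile.intervals
    ]
    return IntervalProfile(table, scaled)


def genome_size_factor(
    summary_big: GenomeSummary,
    summary_small: GenomeSummary,
    basis: str = "bp_per_gene",
) -> float:
    """Ratio big/small measuring the size difference of two genomes."""
    if basis == "bp_per_gene":
        return float(summary_big.bp_per_gene / summary_small.bp_per_gene)
    if basis == "total_bp":
        return summary_big.total_bp / summary_small.total_bp
    raise StatsError(f"unknown basis {basis!r}")


def density_comparison(
    gaps: Iterable[BlockGap],
    summary_a: GenomeSummary,
    summary_b: GenomeSummary,
    pooled: bool = False,
) -> List[DensityPoint]:
    """Gene density of unfractionated block regions vs. the whole genome.

    For each genome, a gap contributes when that genome's side kept its
    genes: conserved gaps on both sides, deletion gaps only on the
    unfractionated side.  Each contributing gap adds its start-to-start
    span and 1 + (annotated genes between) genes, so the quotient is
    exactly total bp over total genes in unfractionated block regions.
    With ``pooled=True`` (self-comparison) both sides accumulate into a
    single point for the one genome.
    """
    bp: Dict[str, float] = {"A": 0.0, "B": 0.0}
    genes: Dict[str, int] = {"A": 0, "B": 0}
    for gap in gaps:
        if gap.kind in ("mixed", "ambiguous"):
            continue
        frac_side = None
        if gap.kind == "deletion":
            frac_side = "B" if gap.genes_a else "A"
        if frac_side != "A":
            bp["A"] += gap.span_a
            genes["A"] += 1 + len(gap.genes_a)
        if frac_side != "B":
            bp["B"] += gap.span_b
            genes["B"] += 1 + len(gap.genes_b)
    if pooled:
        total_bp = bp["A"] + bp["B"]
        total_genes = genes["A"] + genes["B"]
        if total_genes == 0:
            raise StatsError("no unfractionated gaps to compute density from")
        return [
            DensityPoint(
                summary_a.genome_id, total_bp / total_genes, float(summary_a.bp_per_gene)
            )
        ]
    out = []
    for side, summary in (("A", summary_a), ("B", summary_b)):
        if genes[side] == 0:
            raise StatsError(f"no unfractionated gaps on side {side}")
        out.append(
            DensityPoint(
                summary.genome_id, bp[side] / genes[side], float(summary.bp_per_gene)
            )
        )
    return out
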