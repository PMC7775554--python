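"""Deletion-interval scanning, span measurement and pseudogene capacity."""

import numpy as np
import pytest

import synfrac as sf
from synfrac.fractionation import FractionationError, measure_spans, pseudogene_capacity
from synfrac.synteny import PlacedAnchor, SyntenyBlock

from conftest import make_table


def block_of(table_a, table_b, id_pairs, orientation="same", block_id=0):
    anchors = []
    for ga, gb in id_pairs:
        _, ra = table_a.rank(ga)
        _, rb = table_b.rank(gb)
        anchors.append(PlacedAnchor(ga, gb, ra, rb, 90.0))
    ca = table_a.rank(id_pairs[0][0])[0]
    cb = table_b.rank(id_pairs[0][1])[0]
    return SyntenyBlock(block_id, ca, cb, orientation, tuple(anchors))


@pytest.fixture()
def singleton_gap():
    """Side A keeps three genes between the anchors; side B keeps none."""
    ta = make_table("A", [
        ("a0", "cA", 1_000, 4_000),
        ("s1", "cA", 9_000, 10_000),
        ("s2", "cA", 14_000, 15_500),
        ("s3", "cA", 20_000, 21_000),
        ("a1", "cA", 26_500, 29_000),
    ])
    tb = make_table("B", [
        ("b0", "cB", 2_000, 5_000),
        ("b1", "cB", 5_400, 8_000),
    ])
    block = block_of(ta, tb, [("a0", "b0"), ("a1", "b1")])
    return ta, tb, block


class TestScanDeletionIntervals:
    def test_three_singletons_on_one_side(self, singleton_gap):
        ta, tb, block = singleton_gap
        paired = {"a0", "a1", "b0", "b1"}
        (iv,) = sf.scan_deletion_intervals(block, ta, tb, paired, paired)
        assert iv.length == 3
        assert iv.fractionated_genome == "B"
        assert iv.singleton_gene_ids == ("s1", "s2", "s3")
        assert iv.bp_unfractionated == 26_500 - 4_000
        assert iv.bp_fractionated == 5_400 - 5_000

    def test_gap_with_no_genes_on_either_side_yields_nothing(self):
        ta = make_table("A", [("a0", "cA", 0, 100), ("a1", "cA", 500, 600)])
        tb = make_table("B", [("b0", "cB", 0, 100), ("b1", "cB", 900, 1_000)])
        block = block_of(ta, tb, [("a0", "b0"), ("a1", "b1")])
        assert sf.scan_deletion_intervals(block, ta, tb) == []
        (gap,) = sf.scan_block_gaps(block, ta, tb)
        assert gap.kind == "conserved"

    def test_visible_gene_in_gap_disqualifies(self, singleton_gap):
        ta, tb, block = singleton_gap
        paired = {"a0", "a1", "b0", "b1", "s2"}  # s2 is two-copy elsewhere
        assert sf.scan_deletion_intervals(block, ta, tb, paired, paired) == []
        (gap,) = sf.scan_block_gaps(block, ta, tb, paired, paired)
        assert gap.kind == "mixed"

    def test_out_of_order_anchors_rejected(self, singleton_gap):
        ta, tb, block = singleton_gap
        bad = SyntenyBlock(1, block.chrom_a, block.chrom_b, "same", block.anchors[::-1])
        with pytest.raises(FractionationError, match="out of order"):
            sf.scan_deletion_intervals(bad, ta, tb)

    def test_full_simulation_matches_truth_log(self, small_excision_run):
        """Every undisturbed loss run whose flanking pairs are consecutive
        anchors of a retained block appears as exactly one interval."""
        sim, analysis = small_excision_run
        disturbed = set()
        for r in sim.truth.rearrangements:
            disturbed.update(r.get("gene_ids", [r.get("gene_id")]))
        consec = {
            frozenset((l.gene_a, l.gene_b, r.gene_a, r.gene_b))
            for b in analysis.blocks
            for l, r in zip(b.anchors, b.anchors[1:])
        }
        expected = set()
        for ev in sim.truth.losses:
            if ev.left_flank is None or ev.right_flank is None:
                continue
            if set(ev.gene_ids) & disturbed or {ev.left_flank, ev.right_flank} & disturbed:
                continue
            key = frozenset((f"{ev.left_flank}a", f"{ev.left_flank}b",
                             f"{ev.right_flank}a", f"{ev.right_flank}b"))
            if key in consec:
                surv = "a" if ev.side == "b" else "b"
                expected.add(frozenset(f"{g}{surv}" for g in ev.gene_ids))
        got = set()
        for iv in analysis.intervals:
            touched = {g[:-1] for g in iv.singleton_gene_ids}
            touched |= {iv.left_anchor.gene_a[:-1], iv.right_anchor.gene_a[:-1]}
            if not touched & disturbed:
                got.add(frozenset(iv.singleton_gene_ids))
        assert expected and got == expected


class TestMeasureSpans:
    def test_plain_subtraction(self):
        ta = make_table("A", [("a0", "cA", 5_000, 10_000), ("a1", "cA", 18_500, 20_000)])
        tb = make_table("B", [("b0", "cB", 0, 100), ("b1", "cB", 200, 300)])
        block = block_of(ta, tb, [("a0", "b0"), ("a1", "b1")])
        bp_a, bp_b, flags = measure_spans(*block.anchors, ta, tb, block)
        assert bp_a == 8_500 and bp_b == 100 and flags == ()

    def test_inverted_block_orients_by_coordinate(self):
        ta = make_table("A", [("a0", "cA", 0, 1_000), ("a1", "cA", 2_000, 3_000)])
        tb = make_table("B", [("b1", "cB", 40_000, 41_500), ("b0", "cB", 50_000, 52_000)])
        block = block_of(ta, tb, [("a0", "b0"), ("a1", "b1")], orientation="inverted")
        bp_a, bp_b, flags = measure_spans(*block.anchors, ta, tb, block)
        assert bp_b == 50_000 - 41_500 == 8_500

    def test_overlapping_bounding_genes_clamp_to_zero_with_flag(self):
        ta = make_table("A", [("a0", "cA", 0, 5_000), ("a1", "cA", 4_000, 9_000)])
        tb = make_table("B", [("b0", "cB", 0, 100), ("b1", "cB", 200, 300)])
        block = block_of(ta, tb, [("a0", "b0"), ("a1", "b1")])
        bp_a, _, flags = measure_spans(*block.anchors, ta, tb, block)
        assert bp_a == 0 and "clamped_a" in flags

    def test_wrong_chromosome_rejected(self):
        ta = make_table("A", [("a0", "cA", 0, 100), ("a1", "cA", 500, 600)])
        tb = make_table("B", [("b0", "cB", 0, 100), ("b1", "cB", 500, 600)])
        block = block_of(ta, tb, [("a0", "b0"), ("a1", "b1")])
        wrong = SyntenyBlock(9, "cX", block.chrom_b, "same", block.anchors)
        with pytest.raises(FractionationError, match="chrom_a"):
            measure_spans(*block.anchors, ta, tb, wrong)


class TestAggregateProfile:
    def test_exact_length_means(self, singleton_gap):
        ta, tb, block = singleton_gap
        paired = {"a0", "a1", "b0", "b1"}
        (iv,) = sf.scan_deletion_intervals(block, ta, tb, paired, paired)
        other = sf.DeletionInterval(
            block_id=1, chrom_a="cA", chrom_b="cB",
            left_anchor=iv.left_anchor, right_anchor=iv.right_anchor,
            length=2, bp_unfractionated=18_000, bp_fractionated=100,
            fractionated_genome="B", nonanchor_genes_in_gap=0,
            singleton_gene_ids=("x1", "x2"),
        )
        third = sf.DeletionInterval(
            block_id=2, chrom_a="cA", chrom_b="cB",
            left_anchor=iv.left_anchor, right_anchor=iv.right_anchor,
            length=2, bp_unfractionated=20_000, bp_fractionated=300,
            fractionated_genome="B", nonanchor_genes_in_gap=0,
            singleton_gene_ids=("y1", "y2"),
        )
        profile = sf.aggregate_profile([iv, other, third])
        assert profile.table.loc[2, "mean_bp_fractionated"] == 200
        assert profile.table.loc[2, "n"] == 2
        assert int(profile.table["n"].sum()) == 3

    def test_empty_profile(self):
        profile = sf.aggregate_profile([])
        assert profile.n_intervals == 0 and profile.table.empty

    def test_excision_simulation_profile_shape(self, excision_runs):
        """Fractionated means stay within 2x the residual mean across
        L = 1..10 while unfractionated means grow roughly linearly."""
        _, analysis = excision_runs[0]
        t = analysis.profile.table
        rows = t.loc[[l for l in range(1, 11) if l in t.index]]
        assert (rows["mean_bp_fractionated"] < 2 * 400).all()
        growth = np.diff(rows["mean_bp_unfractionated"].to_numpy())
        assert np.median(growth) == pytest.approx(8_000, rel=0.25)


class TestPseudogeneCapacity:
    def test_division(self, singleton_gap):
        ta, tb, block = singleton_gap
        paired = {"a0", "a1", "b0", "b1"}
        (iv,) = sf.scan_deletion_intervals(block, ta, tb, paired, paired)
        cap = pseudogene_capacity(iv, 4_000)
        assert cap.capacity == iv.bp_fractionated / 4_000
        assert cap.bp_per_missing_gene == iv.bp_fractionated / 3

    def test_zero_residual_gives_zero_capacity(self, singleton_gap):
        ta, tb, block = singleton_gap
        paired = {"a0", "a1", "b0", "b1"}
        (iv,) = sf.scan_deletion_intervals(block, ta, tb, paired, paired)
        from dataclasses import replace

        assert pseudogene_capacity(replace(iv, bp_fractionated=0), 3_000).capacity == 0

    def test_nonpositive_gene_size_rejected(self, singleton_gap):
        ta, tb, block = singleton_gap
        paired = {"a0", "a1", "b0", "b1"}
        (iv,) = sf.scan_deletion_intervals(block, ta, tb, paired, paired)
        with pytest.raises(FractionationError):
            pseudogene_capacity(iv, 0)

    def test_pseudogenization_capacity_tracks_interval_length(self, pseudogenization_runs):
        """DNA retained in place: room for ~one full-length pseudogene per
        missing gene (capacity-vs-L slope ~ 1, within 20%), and at L >= 4
        capacity itself is within 20% of L."""
        sim, analysis = pseudogenization_runs[0]
        per_gene_bp = float(sim.config.mean_gene_bp + sim.config.mean_intergenic_bp)
        pts = [
            (iv.length, pseudogene_capacity(iv, per_gene_bp).capacity)
            for iv in analysis.intervals
        ]
        fit = sf.fit_linear(pts)
        assert fit.slope == pytest.approx(1.0, rel=0.20)
        for L in (4, 5):
            caps = [c for l, c in pts if l == L]
            assert np.mean(caps) == pytest.approx(L, rel=0.20)


def test_unfractionated_span_covers_its_singletons(small_excision_run):
    """Conservation: the unfractionated span contains the L singleton genes."""
    sim, analysis = small_excision_run
    table = sim.table_a
    for iv in analysis.intervals:
        total = sum(table.gene(g).length for g in iv.singleton_gene_ids)
        assert iv.bp_unfractionated >= total
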