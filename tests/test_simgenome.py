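"""Simulator determinism, event semantics, and truth-log replay."""

import filecmp

import numpy as np
import pytest

import synfrac as sf
from synfrac import simgenome as sg


def replay_truth_log(config):
    """Independent replay: rebuild both genome copies from the ancestor by
    applying the truth log with plain list splices, then lay out
    coordinates.  Returns {(side): {chrom_name: [(gene_id, start, end,
    strand), ...]}} plus per-chromosome sizes."""
    rng = np.random.default_rng(config.seed)
    ancestor = sg.simulate_ancestor(config, rng)
    result = sg.simulate(config)  # what we are checking against
    truth = result.truth

    copies = {}
    for side, scale in (("a", 1.0), ("b", config.intergenic_scale_b)):
        chroms = {}
        for chrom in ancestor.chromosomes:
            genes = [(g.gene_id, g.length, g.strand) for g in chrom.genes]
            gaps = [max(1, int(round(g * scale))) for g in chrom.gaps]
            chroms[chrom.name] = [genes, gaps]
        copies[side] = chroms

    for side in ("a", "b"):
        events = sorted(
            (ev for ev in truth.losses if ev.side == side),
            key=lambda ev: (ev.chrom, -ev.start),
        )
        for ev in events:  # descending start keeps earlier indices valid
            genes, gaps = copies[side][ev.chrom]
            s, L = ev.start, ev.length
            if ev.mechanism == "excision":
                gaps[s : s + L + 1] = [ev.residual_bp]
            else:
                merged = gaps[s] + sum(
                    genes[i][1] + gaps[i + 1] for i in range(s, s + L)
                )
                gaps[s : s + L + 1] = [merged]
            genes[s : s + L] = []

    for op in truth.rearrangements:
        genes, gaps = copies[op["side"]][op.get("chrom", op.get("from_chrom"))]
        if op["op"] == "inversion":
            s, L = op["start"], op["length"]
            seg = [(g, ln, "-" if st == "+" else "+") for g, ln, st in genes[s : s + L]]
            genes[s : s + L] = seg[::-1]
            gaps[s + 1 : s + L] = gaps[s + 1 : s + L][::-1]
        else:
            gi = op["from_index"]
            gene = genes.pop(gi)
            gaps[gi : gi + 2] = [gaps[gi] + gaps[gi + 1]]
            dgenes, dgaps = copies[op["side"]][op["to_chrom"]]
            slot, left = op["to_slot"], op["split_left"]
            right = dgaps[slot] - left
            dgenes.insert(slot, gene)
            dgaps[slot : slot + 1] = [left, right]

    layout = {}
    sizes = {}
    for side in ("a", "b"):
        layout[side] = {}
        for chrom_name, (genes, gaps) in copies[side].items():
            coord, rows = 0, []
            for i, (gid, ln, strand) in enumerate(genes):
                coord += gaps[i]
                rows.append((f"{gid}{side}", coord, coord + ln, strand))
                coord += ln
            coord += gaps[-1]
            layout[side][f"{chrom_name}{side}"] = rows
            sizes[f"{chrom_name}{side}"] = coord
    return layout, sizes, result


@pytest.mark.parametrize(
    "config",
    [
        sf.SimConfig(n_genes=1_500, seed=21, mechanism="excision",
                     n_inversions=8, n_translocations=10),
        sf.SimConfig(n_genes=1_500, seed=22, mechanism="mixed",
                     event="speciation", intergenic_scale_b=2.0, n_inversions=5),
        sf.SimConfig(n_genes=1_500, seed=23, mechanism="pseudogenization",
                     n_inversions=0),
    ],
    ids=["wgd-excision", "speciation-mixed", "pseudogenization"],
)
def test_truth_log_replay_reconstructs_emitted_genomes(config):
    layout, sizes, result = replay_truth_log(config)
    emitted = {}
    for table in {id(result.table_a): result.table_a, id(result.table_b): result.table_b}.values():
        for chrom, recs in table.chromosomes.items():
            emitted[chrom] = [(r.gene_id, r.start, r.end, r.strand) for r in recs]
    replayed = {**layout["a"], **layout["b"]}
    assert set(replayed) == set(emitted)
    for chrom in replayed:
        assert replayed[chrom] == emitted[chrom], chrom
    assert {**result.sizes_a, **result.sizes_b} == sizes


class TestAncestor:
    def test_degenerate_lengths_give_exact_layout(self):
        cfg = sf.SimConfig(n_genes=10, n_chromosomes=1, sigma_gene=0.0,
                           sigma_intergenic=0.0, loss_fraction=0.0, n_inversions=0)
        anc = sg.simulate_ancestor(cfg, np.random.default_rng(0))
        (chrom,) = anc.chromosomes
        assert chrom.total_bp() == 10 * 3_000 + 11 * 5_000 == 85_000

    def test_same_seed_reproduces_tables(self):
        cfg = sf.SimConfig(n_genes=500, seed=9)
        a, b = sf.simulate(cfg), sf.simulate(cfg)
        assert a.table_a == b.table_a and a.anchors == b.anchors

    def test_monte_carlo_gene_length_mean(self):
        cfg = sf.SimConfig(n_genes=10_000, seed=4)
        anc = sg.simulate_ancestor(cfg, np.random.default_rng(cfg.seed))
        lengths = [g.length for c in anc.chromosomes for g in c.genes]
        assert np.mean(lengths) == pytest.approx(cfg.mean_gene_bp, rel=0.02)


class TestEvent:
    def test_speciation_yields_one_recent_anchor_per_gene(self):
        sim = sf.simulate(sf.SimConfig(n_genes=100, seed=2, event="speciation",
                                       loss_fraction=0.0, old_pair_fraction=0.0,
                                       n_inversions=0))
        assert len(sim.anchors) == 100
        assert all(sim.cohorts[p.unordered] == "recent" for p in sim.anchors)
        assert sim.table_a.n_genes == sim.table_b.n_genes == 100

    def test_wgd_doubles_the_gene_count(self):
        sim = sf.simulate(sf.SimConfig(n_genes=100, seed=2, loss_fraction=0.0,
                                       n_inversions=0))
        assert sim.self_comparison and sim.table_a.n_genes == 200

    def test_old_cohort_size_matches_binomial_expectation(self):
        cfg = sf.SimConfig(n_genes=5_000, seed=6, loss_fraction=0.0, n_inversions=0)
        sim = sf.simulate(cfg)
        n_old = sum(1 for c in sim.cohorts.values() if c == "old")
        mean = cfg.old_pair_fraction * cfg.n_genes
        sd = np.sqrt(cfg.n_genes * cfg.old_pair_fraction * (1 - cfg.old_pair_fraction))
        assert abs(n_old - mean) < 4 * sd


class TestLoss:
    def test_zero_loss_is_identity(self):
        cfg = sf.SimConfig(n_genes=300, seed=3, loss_fraction=0.0, n_inversions=0)
        sim = sf.simulate(cfg)
        assert sim.truth.losses == []
        assert sim.table_a.n_genes == 600

    def test_pseudogenization_conserves_chromosome_lengths(self):
        base = sf.SimConfig(n_genes=2_000, seed=5, loss_fraction=0.0, n_inversions=0)
        lost = base.model_copy(update={"mechanism": "pseudogenization",
                                       "loss_fraction": 0.3})
        assert sf.simulate(lost).sizes_a == sf.simulate(base).sizes_a

    def test_excision_residuals_average_to_configured_mean(self):
        cfg = sf.SimConfig(n_genes=10_000, seed=8)
        sim = sf.simulate(cfg)
        residuals = [ev.residual_bp for ev in sim.truth.losses]
        assert len(residuals) >= 1_000
        assert np.mean(residuals) == pytest.approx(cfg.residual_mean_bp, rel=0.10)

    def test_at_most_one_copy_lost_per_pair(self):
        sim = sf.simulate(sf.SimConfig(n_genes=3_000, seed=10, loss_fraction=0.4))
        by_gene = {}
        for ev in sim.truth.losses:
            for g in ev.gene_ids:
                by_gene.setdefault(g, []).append(ev.side)
        assert all(len(sides) == 1 for sides in by_gene.values())

    def test_impossible_loss_fraction_raises(self):
        with pytest.raises(sg.SimulationError):
            sf.simulate(sf.SimConfig(n_genes=400, seed=1, loss_fraction=0.9))


class TestRearrangements:
    def test_zero_counts_are_identity(self):
        cfg = sf.SimConfig(n_genes=400, seed=3, loss_fraction=0.0,
                           n_inversions=0, n_translocations=0)
        sim = sf.simulate(cfg)
        assert sim.truth.rearrangements == []

    def test_single_inversion_reverses_exactly_its_segment(self):
        cfg = sf.SimConfig(n_genes=400, seed=3, loss_fraction=0.0, n_inversions=1,
                           inversion_min_genes=10, inversion_max_genes=10)
        sim = sf.simulate(cfg)
        (op,) = sim.truth.rearrangements
        assert op["length"] == 10
        base = sf.simulate(cfg.model_copy(update={"n_inversions": 0}))
        side = op["side"]
        chrom = f"{op['chrom']}{side}"
        before = [r.gene_id for r in base.table_a.chromosomes[chrom]]
        after = [r.gene_id for r in sim.table_a.chromosomes[chrom]]
        s, L = op["start"], op["length"]
        assert after[s : s + L] == before[s : s + L][::-1]
        assert after[:s] == before[:s] and after[s + L :] == before[s + L :]

    def test_blocks_recover_most_anchors_despite_inversions(self):
        sim = sf.simulate(sf.SimConfig(n_genes=10_000, seed=1, loss_fraction=0.0,
                                       old_pair_fraction=0.0, n_inversions=20))
        blocks = sf.chain_anchors(sim.anchors, sim.table_a, sim.table_b,
                                  self_comparison=True)
        in_blocks = {frozenset((a.gene_a, a.gene_b)) for b in blocks for a in b.anchors}
        assert len(in_blocks) >= 0.95 * len(sim.anchors)


class TestEmit:
    def test_fixture_round_trips_through_the_readers(self, tmp_path):
        sim = sf.simulate(sf.SimConfig(n_genes=800, seed=12))
        paths = sg.emit_fixture(sim, tmp_path)
        table = sf.read_gff3(paths["gff"], genome_id="sim_wgd")
        assert table == sim.table_a
        assert sf.read_assembly_sizes(paths["sizes"]) == sim.sizes_a
        assert sf.read_anchor_pairs(paths["anchors"]) == sim.anchors

    def test_same_seed_emits_byte_identical_files(self, tmp_path):
        cfg = sf.SimConfig(n_genes=600, seed=14, event="speciation",
                           n_translocations=5)
        p1 = sg.emit_fixture(sf.simulate(cfg), tmp_path / "one")
        p2 = sg.emit_fixture(sf.simulate(cfg), tmp_path / "two")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key
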