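"""Shared fixtures: tiny hand-built genomes and cached full-size simulations."""

from __future__ import annotations

import pytest
from hypothesis import settings

import synfrac as sf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_table(genome_id, spec):
    """Build a GeneTable from (gene_id, chrom, start, end[, strand]) tuples."""
    records = [sf.GeneRecord(*row) for row in spec]
    return sf.GeneTable(genome_id, records)


def uniform_tables(n, gene_bp=3000, gap_bp=5000, chrom="c1", prefix="g", genome_id="G"):
    """n genes laid head-to-tail with constant gene and intergenic lengths."""
    rows = []
    pos = gap_bp
    for i in range(n):
        rows.append((f"{prefix}{i}", chrom, pos, pos + gene_bp))
        pos += gene_bp + gap_bp
    return make_table(genome_id, rows)


@pytest.fixture(scope="session")
def excision_runs():
    """Default excision scenario at full size, seeds 1-3, analyzed."""
    out = []
    for seed in (1, 2, 3):
        sim = sf.simulate(sf.SimConfig(n_genes=10_000, seed=seed))
        analysis = sf.analyze(
            sim.table_a, sim.table_b, sim.anchors, sim.sizes_a, sim.sizes_b,
            self_comparison=sim.self_comparison, run_audit=True,
        )
        out.append((sim, analysis))
    return out


@pytest.fixture(scope="session")
def pseudogenization_runs():
    """Pseudogenization scenario at full size, seeds 1-3, analyzed."""
    out = []
    for seed in (1, 2, 3):
        sim = sf.simulate(
            sf.SimConfig(n_genes=10_000, seed=seed, mechanism="pseudogenization")
        )
        analysis = sf.analyze(
            sim.table_a, sim.table_b, sim.anchors, sim.sizes_a, sim.sizes_b,
            self_comparison=sim.self_comparison,
        )
        out.append((sim, analysis))
    return out


@pytest.fixture(scope="session")
def small_excision_run():
    """A 2,000-gene excision scenario for cheaper structural checks."""
    sim = sf.simulate(sf.SimConfig(n_genes=2_000, seed=7))
    analysis = sf.analyze(
        sim.table_a, sim.table_b, sim.anchors, sim.sizes_a, sim.sizes_b,
        self_comparison=sim.self_comparison,
    )
    return sim, analysis
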