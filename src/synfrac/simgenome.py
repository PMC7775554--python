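"""Synthetic genome-pair generator with a replayable ground-truth log.

The generator lays out a gene-dense ancestor (lognormal gene and intergenic
lengths, head-to-tail on a few chromosomes), duplicates it by whole genome
duplication (both copies in one genome, on distinct chromosomes) or
speciation (two genomes), and then erodes the duplicate-pair cohort:

* **excision** removes a run of genes *and* the intergenic DNA between the
  flanking survivors, leaving a single exponentially distributed residual
  stretch per event — this per-event (not per-gene) residual is exactly
  what makes a near-zero fractionated-side regression slope the excision
  signature;
* **pseudogenization** deletes the annotations (and hence the anchors) of
  a run but leaves every base pair in place;
* **translocation** moves a surviving pair member to a remote position,
  keeping its anchor;
* **inversions** reverse the gene order (and strand) of random segments,
  breaking synteny blocks.

Loss runs have geometric lengths, are placed uniformly at random, never
overlap, and are separated by at least one intact duplicate pair, so every
run is flanked by surviving anchors on both copies and corresponds to at
most one deletion interval.  Anchor similarities are drawn per cohort:
the event cohort at ``similarity_recent``, a configurable fraction of
older (pre-event) duplicates at ``similarity_old``.  Every random choice
flows from a single seed, and the truth log suffices to replay the
ancestor into the emitted genomes exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Set, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .annotations import (
    GeneRecord,
    GeneTable,
    write_assembly_sizes,
    write_gff3,
)
from .homology import AnchorPair, write_anchor_pairs

__all__ = [
    "SimConfig",
    "SimGene",
    "SimChromosome",
    "SimGenomeCopy",
    "LossEvent",
    "TruthLog",
    "SimResult",
    "SimulationError",
    "simulate",
    "simulate_ancestor",
    "apply_event",
    "apply_loss",
    "apply_rearrangements",
    "emit_fixture",
]


class SimulationError(RuntimeError):
    pass


class SimConfig(BaseModel):
    """Scenario parameters; the defaults mirror a mid-size plant genome."""

    n_genes: int = Field(default=10_000, ge=2)
    n_chromosomes: int = Field(default=5, ge=1)
    mean_gene_bp: float = Field(default=3_000.0, gt=0)
    sigma_gene: float = Field(default=0.4, ge=0)
    mean_intergenic_bp: float = Field(default=5_000.0, gt=0)
    sigma_intergenic: float = Field(default=0.6, ge=0)
    event: Literal["wgd", "speciation"] = "wgd"
    loss_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    run_length_p: float = Field(default=0.5, gt=0.0, le=1.0)
    mechanism: Literal["excision", "pseudogenization", "mixed"] = "excision"
    excision_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    residual_mean_bp: float = Field(default=400.0, ge=0)
    residual_growth_bp_per_gene: float = Field(default=0.0, ge=0)
    n_translocations: int = Field(default=0, ge=0)
    n_inversions: int = Field(default=20, ge=0)
    inversion_min_genes: int = Field(default=2, ge=2)
    inversion_max_genes: int = Field(default=30, ge=2)
    similarity_recent: Tuple[float, float] = (92.0, 2.0)
    similarity_old: Tuple[float, float] = (75.0, 3.0)
    old_pair_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    intergenic_scale_b: float = Field(default=1.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.inversion_max_genes < self.inversion_min_genes:
            raise ValueError("inversion_max_genes < inversion_min_genes")
        return self


@dataclass
class SimGene:
    gene_id: str  # ancestral id, e.g. "g000017"
    length: int
    strand: str


@dataclass
class SimChromosome:
    """gaps[0], genes[0], gaps[1], genes[1], ..., gaps[n] head-to-tail."""

    name: str
    genes: List[SimGene]
    gaps: List[int]

    def total_bp(self) -> int:
        return sum(g.length for g in self.genes) + sum(self.gaps)


@dataclass
class SimGenomeCopy:
    side: str  # "a" | "b"
    chromosomes: List[SimChromosome]

    def find(self, gene_id: str) -> Tuple[int, int]:
        for ci, chrom in enumerate(self.chromosomes):
            for gi, gene in enumerate(chrom.genes):
                if gene.gene_id == gene_id:
                    return ci, gi
        raise KeyError(gene_id)


@dataclass
class LossEvent:
    chrom: str  # ancestral chromosome name
    start: int  # ancestral gene position on that chromosome
    length: int
    side: str  # copy that lost the genes
    mechanism: str
    residual_bp: int
    gene_ids: Tuple[str, ...]  # ancestral ids of the lost run
    left_flank: Optional[str]
    right_flank: Optional[str]


@dataclass
class TruthLog:
    """Everything needed to replay the ancestor into the emitted genomes."""

    event: str
    losses: List[LossEvent] = field(default_factory=list)
    rearrangements: List[Dict] = field(default_factory=list)

    def singleton_ids(self) -> Set[str]:
        """Emitted ids of surviving copies whose partner a loss run removed."""
        out: Set[str] = set()
        for ev in self.losses:
            surv = "a" if ev.side == "b" else "b"
            out.update(f"{gid}{surv}" for gid in ev.gene_ids)
        return out

    def to_json(self) -> Dict:
        return {
            "event": self.event,
            "losses": [
                {
                    "chrom": ev.chrom,
                    "start": ev.start,
                    "length": ev.length,
                    "side": ev.side,
                    "mechanism": ev.mechanism,
                    "residual_bp": ev.residual_bp,
                    "gene_ids": list(ev.gene_ids),
                    "left_flank": ev.left_flank,
                    "right_flank": ev.right_flank,
                }
                for ev in self.losses
            ],
            "rearrangements": self.rearrangements,
        }

    @classmethod
    def from_json(cls, payload: Dict) -> "TruthLog":
        return cls(
            event=payload["event"],
            losses=[
                LossEvent(
                    chrom=d["chrom"],
                    start=d["start"],
                    length=d["length"],
                    side=d["side"],
                    mechanism=d["mechanism"],
                    residual_bp=d["residual_bp"],
                    gene_ids=tuple(d["gene_ids"]),
                    left_flank=d["left_flank"],
                    right_flank=d["right_flank"],
                )
                for d in payload["losses"]
            ],
            rearrangements=list(payload["rearrangements"]),
        )


@dataclass
class SimResult:
    config: SimConfig
    self_comparison: bool
    table_a: GeneTable
    table_b: GeneTable  # same object as table_a for a WGD self-comparison
    sizes_a: Dict[str, int]
    sizes_b: Dict[str, int]
    anchors: List[AnchorPair]
    cohorts: Dict[frozenset, str]  # unordered pair -> "recent" | "old"
    truth: TruthLog


def _lognormal_lengths(rng: np.random.Generator, mean: float, sigma: float, n: int) -> np.ndarray:
    if sigma == 0.0:
        return np.full(n, max(1, int(round(mean))), dtype=np.int64)
    mu = np.log(mean) - sigma**2 / 2.0
    draws = rng.lognormal(mu, sigma, size=n)
    return np.maximum(1, np.rint(draws)).astype(np.int64)


def simulate_ancestor(config: SimConfig, rng: np.random.Generator) -> SimGenomeCopy:
    """Ancestral genome: lognormal gene/intergenic lengths laid head-to-tail."""
    gene_lengths = _lognormal_lengths(rng, config.mean_gene_bp, config.sigma_gene, config.n_genes)
    gap_lengths = _lognormal_lengths(
        rng, config.mean_intergenic_bp, config.sigma_intergenic,
        config.n_genes + config.n_chromosomes,
    )
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if k < config.n_genes % config.n_chromosomes else 0)
        for k in range(config.n_chromosomes)
    ]
    width = len(str(config.n_genes))
    chroms: List[SimChromosome] = []
    gene_idx = 0
    gap_idx = 0
    for k, n_here in enumerate(per_chrom):
        genes = [
            SimGene(f"g{gene_idx + i:0{width}d}", int(gene_lengths[gene_idx + i]), str(strands[gene_idx + i]))
            for i in range(n_here)
        ]
        gaps = [int(x) for x in gap_lengths[gap_idx : gap_idx + n_here + 1]]
        chroms.append(SimChromosome(f"chr{k + 1}", genes, gaps))
        gene_idx += n_here
        gap_idx += n_here + 1
    return SimGenomeCopy("ancestor", chroms)


def _copy_of(ancestor: SimGenomeCopy, side: str, gap_scale: float) -> SimGenomeCopy:
    chroms = []
    for chrom in ancestor.chromosomes:
        genes = [SimGene(g.gene_id, g.length, g.strand) for g in chrom.genes]
        gaps = [max(1, int(round(g * gap_scale))) for g in chrom.gaps]
        chroms.append(SimChromosome(chrom.name, genes, gaps))
    return SimGenomeCopy(side, chroms)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.0, 100.0))


def apply_event(
    ancestor: SimGenomeCopy, config: SimConfig, rng: np.random.Generator
) -> Tuple[SimGenomeCopy, SimGenomeCopy, List[Tuple[str, str, float, str]]]:
    """Duplicate the ancestor and draw the anchor cohorts.

    Returns the two copies plus anchor truth rows
    (ancestral_id_a, ancestral_id_b, similarity, cohort); ids are ancestral
    here, the emitted per-copy suffixes are added at export.
    """
    copy_a = _copy_of(ancestor, "a", 1.0)
    copy_b = _copy_of(ancestor, "b", config.intergenic_scale_b)
    anchors: List[Tuple[str, str, float, str]] = []
    mu_r, sd_r = config.similarity_recent
    for chrom in ancestor.chromosomes:
        for gene in chrom.genes:
            anchors.append((gene.gene_id, gene.gene_id, _trunc_normal(rng, mu_r, sd_r), "recent"))
    # older duplications predating the event: scattered pairs at lower similarity
    mu_o, sd_o = config.similarity_old
    all_ids = [g.gene_id for chrom in ancestor.chromosomes for g in chrom.genes]
    hits = rng.random(len(all_ids)) < config.old_pair_fraction
    for i, hit in enumerate(hits):
        if not hit:
            continue
        j = int(rng.integers(0, len(all_ids) - 1))
        if j >= i:
            j += 1
        anchors.append((all_ids[i], all_ids[j], _trunc_normal(rng, mu_o, sd_o), "old"))
    return copy_a, copy_b, anchors


def apply_loss(
    copy_a: SimGenomeCopy,
    copy_b: SimGenomeCopy,
    config: SimConfig,
    rng: np.random.Generator,
) -> TruthLog:
    """Place geometric loss runs and apply them to one copy each, in place.

    Runs never overlap and keep one intact pair between them, so at most
    one member of every duplicate pair is lost and each run's flanking
    pairs survive on both copies.
    """
    truth = TruthLog(event=config.event)
    n_target = int(round(config.loss_fraction * config.n_genes))
    if n_target == 0:
        return truth
    chrom_sizes = [len(c.genes) for c in copy_a.chromosomes]
    offsets = np.cumsum([0] + chrom_sizes[:-1])
    blocked: Set[Tuple[int, int]] = set()
    planned: List[Tuple[int, int, int, str, str]] = []  # (chrom_idx, start, length, side, mechanism)
    lost = 0
    attempts = 0
    max_attempts = 500 * max(1, n_target)
    while lost < n_target:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError(
                f"could not place loss runs for loss_fraction={config.loss_fraction}; "
                "every duplicate pair needs a surviving member and runs need intact flanks"
            )
        u = int(rng.integers(0, config.n_genes))
        ci = int(np.searchsorted(offsets, u, side="right") - 1)
        pos = u - int(offsets[ci])
        length = int(rng.geometric(config.run_length_p))
        length = min(length, n_target - lost)
        if pos + length > chrom_sizes[ci]:
            continue
        window = range(max(0, pos - 1), min(chrom_sizes[ci], pos + length + 1))
        if any((ci, p) in blocked for p in window):
            continue
        side = "a" if rng.random() < 0.5 else "b"
        if config.mechanism == "mixed":
            mechanism = "excision" if rng.random() < config.excision_prob else "pseudogenization"
        else:
            mechanism = config.mechanism
        residual = 0
        if mechanism == "excision":
            residual = int(round(
                rng.exponential(config.residual_mean_bp)
                + config.residual_growth_bp_per_gene * length
            ))
        blocked.update((ci, p) for p in range(pos, pos + length))
        planned.append((ci, pos, length, side, mechanism))
        chrom = copy_a.chromosomes[ci]
        run_ids = tuple(g.gene_id for g in chrom.genes[pos : pos + length])
        truth.losses.append(
            LossEvent(
                chrom=chrom.name,
                start=pos,
                length=length,
                side=side,
                mechanism=mechanism,
                residual_bp=residual,
                gene_ids=run_ids,
                left_flank=chrom.genes[pos - 1].gene_id if pos > 0 else None,
                right_flank=(
                    chrom.genes[pos + length].gene_id
                    if pos + length < chrom_sizes[ci]
                    else None
                ),
            )
        )
        lost += length

    for copy in (copy_a, copy_b):
        events = sorted(
            (ev for ev in truth.losses if ev.side == copy.side),
            key=lambda ev: (ev.chrom, ev.start),
        )
        by_chrom: Dict[str, Dict[int, LossEvent]] = {}
        for ev in events:
            by_chrom.setdefault(ev.chrom, {})[ev.start] = ev
        for chrom in copy.chromosomes:
            starts = by_chrom.get(chrom.name)
            if not starts:
                continue
            _apply_losses_to_chromosome(chrom, starts)
    return truth


def _apply_losses_to_chromosome(chrom: SimChromosome, starts: Dict[int, LossEvent]) -> None:
    genes, gaps = chrom.genes, chrom.gaps
    out_genes: List[SimGene] = []
    out_gaps: List[int] = []
    cur_gap = gaps[0]
    pos = 0
    n = len(genes)
    while pos < n:
        ev = starts.get(pos)
        if ev is not None:
            if ev.mechanism == "excision":
                # run, its internal gaps and both flanking gaps collapse to a residual
                cur_gap = ev.residual_bp
            else:  # pseudogenization: annotations go, every base pair stays
                cur_gap += sum(
                    genes[p].length + gaps[p + 1] for p in range(pos, pos + ev.length)
                )
            pos += ev.length
            continue
        out_gaps.append(cur_gap)
        out_genes.append(genes[pos])
        cur_gap = gaps[pos + 1]
        pos += 1
    out_gaps.append(cur_gap)
    chrom.genes = out_genes
    chrom.gaps = out_gaps


def apply_rearrangements(
    copy_a: SimGenomeCopy,
    copy_b: SimGenomeCopy,
    config: SimConfig,
    rng: np.random.Generator,
    truth: TruthLog,
    anchored_ids: Optional[Set[str]] = None,
) -> None:
    """Apply inversions then single-gene translocations, logging each op.

    Inversions mirror a random rank segment (order, internal gaps and
    strands).  Translocations move one surviving pair member (its DNA and
    annotation, keeping its anchor) to a uniformly random remote position
    in the same genome copy.
    """
    copies = {"a": copy_a, "b": copy_b}
    for _ in range(config.n_inversions):
        side = "a" if rng.random() < 0.5 else "b"
        copy = copies[side]
        weights = np.array([len(c.genes) for c in copy.chromosomes], dtype=float)
        eligible = weights >= config.inversion_min_genes
        if not eligible.any():
            continue
        weights[~eligible] = 0.0
        ci = int(rng.choice(len(copy.chromosomes), p=weights / weights.sum()))
        chrom = copy.chromosomes[ci]
        hi = min(config.inversion_max_genes, len(chrom.genes))
        seg = int(rng.integers(config.inversion_min_genes, hi + 1))
        start = int(rng.integers(0, len(chrom.genes) - seg + 1))
        _invert_segment(chrom, start, seg)
        truth.rearrangements.append(
            {
                "op": "inversion",
                "side": side,
                "chrom": chrom.name,
                "start": start,
                "length": seg,
                "gene_ids": [g.gene_id for g in chrom.genes[start : start + seg]],
            }
        )

    if config.n_translocations:
        lost_ids = {gid for ev in truth.losses for gid in ev.gene_ids}
        candidates = sorted(
            g.gene_id
            for chrom in copy_a.chromosomes
            for g in chrom.genes
            if g.gene_id not in lost_ids
            and (anchored_ids is None or g.gene_id in anchored_ids)
        )
        if len(candidates) < config.n_translocations:
            raise SimulationError("not enough intact pairs to translocate")
        chosen = rng.choice(len(candidates), size=config.n_translocations, replace=False)
        for idx in sorted(int(i) for i in chosen):
            gene_id = candidates[idx]
            side = "a" if rng.random() < 0.5 else "b"
            copy = copies[side]
            ci, gi = copy.find(gene_id)
            chrom = copy.chromosomes[ci]
            gene = chrom.genes.pop(gi)
            merged = chrom.gaps[gi] + chrom.gaps[gi + 1]
            chrom.gaps[gi : gi + 2] = [merged]
            dci = int(rng.integers(0, len(copy.chromosomes)))
            dchrom = copy.chromosomes[dci]
            slot = int(rng.integers(0, len(dchrom.genes) + 1))
            split_left = int(rng.integers(0, dchrom.gaps[slot] + 1))
            right = dchrom.gaps[slot] - split_left
            dchrom.genes.insert(slot, gene)
            dchrom.gaps[slot : slot + 1] = [split_left, right]
            truth.rearrangements.append(
                {
                    "op": "translocation",
                    "side": side,
                    "gene_id": gene_id,
                    "from_chrom": chrom.name,
                    "from_index": gi,
                    "to_chrom": dchrom.name,
                    "to_slot": slot,
                    "split_left": split_left,
                }
            )


def _invert_segment(chrom: SimChromosome, start: int, length: int) -> None:
    seg = chrom.genes[start : start + length]
    for g in seg:
        g.strand = "-" if g.strand == "+" else "+"
    chrom.genes[start : start + length] = seg[::-1]
    inner = chrom.gaps[start + 1 : start + length]
    chrom.gaps[start + 1 : start + length] = inner[::-1]


def _export_copy(
    copy: SimGenomeCopy, genome_id: str, suffix_chrom: bool
) -> Tuple[GeneTable, Dict[str, int]]:
    records: List[GeneRecord] = []
    sizes: Dict[str, int] = {}
    for chrom in copy.chromosomes:
        name = f"{chrom.name}{copy.side}" if suffix_chrom else chrom.name
        coord = 0
        for i, gene in enumerate(chrom.genes):
            coord += chrom.gaps[i]
            records.append(
                GeneRecord(f"{gene.gene_id}{copy.side}", name, coord, coord + gene.length, gene.strand)
            )
            coord += gene.length
        coord += chrom.gaps[-1]
        sizes[name] = coord
    return GeneTable(genome_id, records), sizes


def simulate(config: SimConfig) -> SimResult:
    """Run the full scenario: ancestor, duplication, loss, rearrangements."""
    rng = np.random.default_rng(config.seed)
    ancestor = simulate_ancestor(config, rng)
    copy_a, copy_b, anchor_truth = apply_event(ancestor, config, rng)
    truth = apply_loss(copy_a, copy_b, config, rng)
    recent_ids = {row[0] for row in anchor_truth if row[3] == "recent"}
    apply_rearrangements(copy_a, copy_b, config, rng, truth, anchored_ids=recent_ids)

    lost = {(ev.side, gid) for ev in truth.losses for gid in ev.gene_ids}
    anchors: List[AnchorPair] = []
    cohorts: Dict[frozenset, str] = {}
    rng_sides = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    for ga, gb, sim, cohort in anchor_truth:
        if cohort == "recent":
            ia, ib = f"{ga}a", f"{gb}b"
            if ("a", ga) in lost or ("b", gb) in lost:
                continue
        else:
            # an old duplication pairs whichever copies happen to survive
            sa = "a" if rng_sides.random() < 0.5 else "b"
            sb = "a" if rng_sides.random() < 0.5 else "b"
            if config.event == "speciation":
                sa, sb = "a", "b"
            if ("a" if sa == "a" else "b", ga) in lost or (sb, gb) in lost:
                continue
            if ga == gb and sa == sb:
                continue
            ia, ib = f"{ga}{sa}", f"{gb}{sb}"
        pair = AnchorPair(ia, ib, round(sim, 2))
        anchors.append(pair)
        cohorts[pair.unordered] = cohort

    if config.event == "wgd":
        table_ab, sizes_a = _export_copy(copy_a, "sim_wgd", suffix_chrom=True)
        table_b2, sizes_b = _export_copy(copy_b, "sim_wgd", suffix_chrom=True)
        merged = GeneTable(
            "sim_wgd", list(table_ab.iter_records()) + list(table_b2.iter_records())
        )
        sizes = {**sizes_a, **sizes_b}
        return SimResult(
            config, True, merged, merged, sizes, sizes, anchors, cohorts, truth
        )
    table_a, sizes_a = _export_copy(copy_a, "sim_a", suffix_chrom=True)
    table_b, sizes_b = _export_copy(copy_b, "sim_b", suffix_chrom=True)
    return SimResult(
        config, False, table_a, table_b, sizes_a, sizes_b, anchors, cohorts, truth
    )


def emit_fixture(result: SimResult, out_dir: str | Path) -> Dict[str, Path]:
    """Write the pipeline's input files plus the truth log; byte-stable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    if result.self_comparison:
        paths["gff"] = out / "genome.gff3"
        write_gff3(result.table_a, paths["gff"])
        paths["sizes"] = out / "genome.sizes.tsv"
        write_assembly_sizes(result.sizes_a, paths["sizes"])
    else:
        paths["gff_a"] = out / "genome_a.gff3"
        paths["gff_b"] = out / "genome_b.gff3"
        write_gff3(result.table_a, paths["gff_a"])
        write_gff3(result.table_b, paths["gff_b"])
        paths["sizes_a"] = out / "genome_a.sizes.tsv"
        paths["sizes_b"] = out / "genome_b.sizes.tsv"
        write_assembly_sizes(result.sizes_a, paths["sizes_a"])
        write_assembly_sizes(result.sizes_b, paths["sizes_b"])
    paths["anchors"] = out / "anchors.tsv"
    write_anchor_pairs(result.anchors, paths["anchors"])
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(result.truth.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["config"] = out / "sim_config.json"
    with open(paths["config"], "w") as fh:
        fh.write(result.config.model_dump_json(indent=1))
        fh.write("\n")
    return paths
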