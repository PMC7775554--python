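"""Chaining anchor pairs into collinear synteny blocks.

A synteny block is a run of homologous gene pairs in conserved order on two
chromosomal regions.  Within each (chromosome A, chromosome B) combination
an anchor may follow another in a chain if its gene rank increases on side
A and changes in the orientation's direction on side B (increasing for
"same", decreasing for "inverted"), each step by at most ``max_gap`` ranks.
Gap is measured in gene ranks, not base pairs, so interval lengths measured
later (in genes) are exact.

Blocks are built by iterated longest-chain extraction, the scheme of the
classic collinearity chainers: dynamic programming finds the
maximum-anchor-count chain over the remaining anchors (ties broken by
leftmost start rank on side A, then rank on side B, then same before
inverted orientation, then the lexicographically smallest rank sequence —
a total order, so the output is deterministic), the chain becomes a block,
its anchors leave the pool, and the process repeats until the best chain
falls below ``min_block_size`` (default 5, the stringency that keeps
coincidental neighboring pairs out of the block set).  Anchors, not genes,
are consumed: a gene with several homologous partners can appear in
several blocks.  A maximum-length chain can skip no skippable anchor, so
the gaps between consecutive anchors of a block never hide an insertable
pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import fmean
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .annotations import GeneTable
from .homology import AnchorPair, SimilarityWindow

__all__ = [
    "PlacedAnchor",
    "SyntenyBlock",
    "SyntenyError",
    "chain_anchors",
    "filter_blocks_by_similarity",
    "block_size_sensitivity",
    "write_blocks",
]


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class PlacedAnchor:
    """An anchor pair located at its gene ranks in both genomes."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    similarity: float


@dataclass(frozen=True)
class SyntenyBlock:
    """A chained collinear run of anchors on one chromosome pair."""

    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: Tuple[PlacedAnchor, ...]

    @property
    def mean_similarity(self) -> float:
        return fmean(a.similarity for a in self.anchors)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _place(
    pairs: Iterable[AnchorPair],
    table_a: GeneTable,
    table_b: GeneTable,
    self_comparison: bool,
) -> Dict[Tuple[str, str], List[PlacedAnchor]]:
    groups: Dict[Tuple[str, str], List[PlacedAnchor]] = {}
    for p in pairs:
        if self_comparison and p.gene_a == p.gene_b:
            continue  # trivial diagonal
        try:
            ca, ia = table_a.rank(p.gene_a)
        except KeyError:
            raise SyntenyError(f"anchor gene {p.gene_a!r} not in genome A table") from None
        try:
            cb, ib = table_b.rank(p.gene_b)
        except KeyError:
            raise SyntenyError(f"anchor gene {p.gene_b!r} not in genome B table") from None
        groups.setdefault((ca, cb), []).append(
            PlacedAnchor(p.gene_a, p.gene_b, ia, ib, p.similarity)
        )
        if self_comparison:
            # each pair can play either role; only canonical chromosome
            # pairs (chrom_a <= chrom_b) are chained, mirrors are implied
            groups.setdefault((cb, ca), []).append(
                PlacedAnchor(p.gene_b, p.gene_a, ib, ia, p.similarity)
            )
    return groups


def _extract_chains(
    nodes: Sequence[PlacedAnchor], max_gap: int, min_block_size: int
) -> List[Tuple[str, Tuple[PlacedAnchor, ...]]]:
    """Iterated longest-chain extraction within one chromosome-pair group."""
    order = sorted(range(len(nodes)), key=lambda i: (nodes[i].rank_a, nodes[i].rank_b))
    ra = [nodes[i].rank_a for i in order]
    rb = [nodes[i].rank_b for i in order]
    n = len(order)

    succ: Dict[str, List[List[int]]] = {"same": [], "inverted": []}
    for i in range(n):
        same: List[int] = []
        inv: List[int] = []
        j = i + 1
        while j < n and ra[j] - ra[i] <= max_gap:
            if ra[j] > ra[i]:
                if 0 < rb[j] - rb[i] <= max_gap:
                    same.append(j)
                elif 0 < rb[i] - rb[j] <= max_gap:
                    inv.append(j)
            j += 1
        succ["same"].append(same)
        succ["inverted"].append(inv)

    alive = [True] * n
    chains: List[Tuple[str, Tuple[PlacedAnchor, ...]]] = []
    while True:
        best_key = None
        best = None  # (orientation, lengths array, start index)
        for orientation in ("same", "inverted"):
            slists = succ[orientation]
            lengths = [0] * n
            for i in range(n - 1, -1, -1):
                if not alive[i]:
                    continue
                top = 0
                for j in slists[i]:
                    if alive[j] and lengths[j] > top:
                        top = lengths[j]
                lengths[i] = 1 + top
            top_len = max((lengths[i] for i in range(n) if alive[i]), default=0)
            if top_len == 0:
                continue
            for i in range(n):  # sorted (rank_a, rank_b): first hit = leftmost start
                if alive[i] and lengths[i] == top_len:
                    key = (-top_len, ra[i], rb[i], 0 if orientation == "same" else 1)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = (orientation, lengths, i)
                    break
        if best is None or -best_key[0] < min_block_size:
            break
        orientation, lengths, start = best
        path = [start]
        cur = start
        while lengths[cur] > 1:
            nxt = None
            for j in succ[orientation][cur]:  # already in (rank_a, rank_b) order
                if alive[j] and lengths[j] == lengths[cur] - 1:
                    nxt = j
                    break
            assert nxt is not None
            path.append(nxt)
            cur = nxt
        for i in path:
            alive[i] = False
        label = orientation if len(path) > 1 else "same"
        chains.append((label, tuple(nodes[order[i]] for i in path)))
    return chains


def chain_anchors(
    pairs: Iterable[AnchorPair],
    table_a: GeneTable,
    table_b: GeneTable,
    max_gap: int = 20,
    min_block_size: int = 5,
    self_comparison: bool = False,
) -> List[SyntenyBlock]:
    """Chain anchor pairs into collinear synteny blocks (both orientations).

    In self-comparison mode the trivial diagonal (a gene matched to itself)
    is excluded and only the mirror copy with chrom_a <= chrom_b (then the
    lower start rank) of each block is kept.
    """
    if max_gap < 1:
        raise SyntenyError(f"max_gap must be >= 1, got {max_gap}")
    if min_block_size < 1:
        raise SyntenyError(f"min_block_size must be >= 1, got {min_block_size}")

    groups = _place(pairs, table_a, table_b, self_comparison)
    raw: List[Tuple[str, str, str, Tuple[PlacedAnchor, ...]]] = []
    for (ca, cb), nodes in sorted(groups.items()):
        if self_comparison and ca > cb:
            continue  # mirror of a canonical group
        for orientation, chain in _extract_chains(nodes, max_gap, min_block_size):
            raw.append((ca, cb, orientation, chain))

    if self_comparison:
        # same-chromosome groups still contain both placements of each pair
        by_mirror: Dict[frozenset, List[Tuple[str, str, str, Tuple[PlacedAnchor, ...]]]] = {}
        deduped = []
        for item in raw:
            if item[0] != item[1]:
                deduped.append(item)
                continue
            key = frozenset(frozenset((a.gene_a, a.gene_b)) for a in item[3])
            by_mirror.setdefault(key, []).append(item)
        for members in by_mirror.values():
            deduped.append(
                min(members, key=lambda m: (m[3][0].rank_a, m[3][0].rank_b))
            )
        raw = deduped

    raw.sort(
        key=lambda m: (
            m[0],
            m[1],
            m[3][0].rank_a,
            m[3][-1].rank_a - m[3][0].rank_a,
            m[2],
            tuple((a.rank_a, a.rank_b) for a in m[3]),
        )
    )
    return [
        SyntenyBlock(i, ca, cb, orientation, chain)
        for i, (ca, cb, orientation, chain) in enumerate(raw)
    ]


def filter_blocks_by_similarity(
    blocks: Iterable[SyntenyBlock], window: SimilarityWindow
) -> List[SyntenyBlock]:
    """Retain blocks whose *mean* similarity falls inside the cohort window."""
    return [b for b in blocks if window.lower <= b.mean_similarity <= window.upper]


def block_size_sensitivity(
    pairs: Iterable[AnchorPair],
    table_a: GeneTable,
    table_b: GeneTable,
    max_gap: int = 20,
    thresholds: Sequence[int] = (3, 4, 5, 6),
    self_comparison: bool = False,
) -> Dict[int, int]:
    """Distinct genes in blocks (both sides pooled) per minimum-block-size.

    Chains are extracted once at the smallest threshold; extraction order
    is by decreasing length, so larger thresholds only filter the same
    block set and counts are non-increasing in the threshold.
    """
    thresholds = sorted(set(thresholds))
    if not thresholds:
        return {}
    pairs = list(pairs)
    if not pairs:
        return {t: 0 for t in thresholds}
    blocks = chain_anchors(
        pairs, table_a, table_b, max_gap, min_block_size=thresholds[0],
        self_comparison=self_comparison,
    )
    out: Dict[int, int] = {}
    for t in thresholds:
        genes = set()
        for b in blocks:
            if b.n_anchors >= t:
                for a in b.anchors:
                    genes.add(("A", a.gene_a))
                    genes.add(("B", a.gene_b))
        if self_comparison:
            genes = {g for _, g in genes}
        out[t] = len(genes)
    return out


def write_blocks(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    """Write blocks as TSV: one header row per block, one row per anchor."""
    with open(path, "w") as fh:
        fh.write(
            "#block_id\tchrom_a\tchrom_b\torientation\tn_anchors\tmean_similarity\n"
        )
        for b in blocks:
            fh.write(
                f"B\t{b.block_id}\t{b.chrom_a}\t{b.chrom_b}\t{b.orientation}"
                f"\t{b.n_anchors}\t{b.mean_similarity:.3f}\n"
            )
            for a in b.anchors:
                fh.write(
                    f"A\t{b.block_id}\t{a.gene_a}\t{a.rank_a}\t{a.gene_b}"
                    f"\t{a.rank_b}\t{a.similarity:g}\n"
                )
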