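"""Translocation audit: did missing genes move elsewhere rather than excise?

Block singletons (surviving copies whose partner is absent from the block)
are searched for partners anywhere in the genome among *all* duplicate
pairs — the anchor list before any block-size filtering, equivalent to a
minimum block size of 1.  A singleton paired elsewhere at approximately the
event cohort's similarity level suggests its partner translocated rather
than being deleted.  Because pre-existing paralog triplets are not
deconvolved, the reported percentage is an upper bound on translocation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Set

from .fractionation import DeletionInterval
from .homology import AnchorPair, SimilarityWindow
from .synteny import SyntenyBlock

__all__ = [
    "TranslocationAudit",
    "TranslocationError",
    "collect_singletons",
    "find_remote_partners",
    "audit_percent",
    "write_audit",
]


class TranslocationError(ValueError):
    pass


@dataclass(frozen=True)
class TranslocationAudit:
    genome_id: str
    n_singletons: int
    n_paired_remotely: int
    percent_paired: int
    similarity_window_used: SimilarityWindow

    def __post_init__(self) -> None:
        if not (0 <= self.n_paired_remotely <= self.n_singletons):
            raise TranslocationError("paired count outside [0, n_singletons]")


def audit_percent(n_paired: int, n_total: int) -> int:
    """Percent paired remotely, rounded to the nearest integer."""
    if n_total <= 0:
        raise TranslocationError("percent undefined for an empty singleton set")
    return int(math.floor(100.0 * n_paired / n_total + 0.5))


def collect_singletons(
    blocks: Iterable[SyntenyBlock],
    intervals: Iterable[DeletionInterval],
    side: str = "both",
) -> Set[str]:
    """Union of unfractionated-side genes inside deletion intervals.

    ``side`` restricts to intervals whose surviving genes lie on genome
    "A" or "B"; "both" pools them (the natural choice in self-comparison,
    where both sides are the same genome).
    """
    if side not in ("A", "B", "both"):
        raise TranslocationError(f"side must be A, B or both, got {side!r}")
    block_ids = {b.block_id for b in blocks}
    singles: Set[str] = set()
    for iv in intervals:
        if iv.block_id not in block_ids:
            continue
        unfrac = "A" if iv.fractionated_genome == "B" else "B"
        if side != "both" and unfrac != side:
            continue
        singles.update(iv.singleton_gene_ids)
    return singles


def find_remote_partners(
    singletons: Set[str],
    all_pairs: Iterable[AnchorPair],
    window: SimilarityWindow,
    genome_id: str = "",
) -> TranslocationAudit:
    """Count singletons paired with any other gene at cohort similarity.

    ``all_pairs`` must be the unfiltered pair list (min block size 1);
    duplicate pair rows do not change the outcome.
    """
    if not singletons:
        raise TranslocationError("percent undefined for an empty singleton set")
    paired: Set[str] = set()
    for p in all_pairs:
        if p.gene_a == p.gene_b or not window.contains(p.similarity):
            continue
        if p.gene_a in singletons:
            paired.add(p.gene_a)
        if p.gene_b in singletons:
            paired.add(p.gene_b)
    n_total = len(singletons)
    n_paired = len(paired)
    return TranslocationAudit(
        genome_id=genome_id,
        n_singletons=n_total,
        n_paired_remotely=n_paired,
        percent_paired=audit_percent(n_paired, n_total),
        similarity_window_used=window,
    )


def write_audit(audit: TranslocationAudit, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
    payload: Dict = {
        "genome_id": audit.genome_id,
        "n_singletons": audit.n_singletons,
        "n_paired_remotely": audit.n_paired_remotely,
        "percent_paired": audit.percent_paired,
        "similarity_window": [
            audit.similarity_window_used.lower,
            audit.similarity_window_used.upper,
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("genome_id\tn_singletons\tn_paired_remotely\tpercent_paired\n")
            fh.write(
                f"{audit.genome_id}\t{audit.n_singletons}\t"
                f"{audit.n_paired_remotely}\t{audit.percent_paired}\n"
            )
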