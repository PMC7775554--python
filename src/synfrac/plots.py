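"""Optional figures: per-length span profile and the density diagonal."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .fractionation import IntervalProfile
from .stats import DensityPoint

__all__ = ["plot_profile", "plot_density", "plot_report"]


def plot_profile(profile: IntervalProfile, path: str | Path) -> None:
    """Mean bp span per interval length, both sides, with point counts."""
    fig, ax = plt.subplots(figsize=(6, 4))
    t = profile.table
    ax.plot(t.index, t["mean_bp_unfractionated"], "o-", label="unfractionated")
    ax.plot(t.index, t["mean_bp_fractionated"], "s-", label="fractionated")
    ax.set_xlabel("interval length L (genes)")
    ax.set_ylabel("mean bp between bounding anchors")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_density(points: Iterable[DensityPoint], path: str | Path) -> None:
    """bp-per-gene in blocks vs. genome-wide; diagonal marks equality."""
    points = list(points)
    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [p.bp_per_gene_genomewide for p in points]
    ys = [p.bp_per_gene_in_blocks for p in points]
    lim = max(xs + ys) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.scatter(xs, ys)
    for p in points:
        ax.annotate(p.genome_id, (p.bp_per_gene_genomewide, p.bp_per_gene_in_blocks))
    ax.set_xlabel("genome-wide bp per gene")
    ax.set_ylabel("bp per gene in unfractionated block regions")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_report(out_dir: str | Path) -> None:
    """Render PNGs next to a written report bundle."""
    import pandas as pd

    out = Path(out_dir)
    profile = pd.read_csv(out / "profile.tsv", sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.index, profile["mean_bp_unfractionated"], "o-", label="unfractionated")
    ax.plot(profile.index, profile["mean_bp_fractionated"], "s-", label="fractionated")
    ax.set_xlabel("interval length L (genes)")
    ax.set_ylabel("mean bp")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "profile.png", dpi=120)
    plt.close(fig)
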