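"""Homologous anchor pairs, similarity histograms and cohort window selection.

After a whole genome duplication (WGD) or a speciation event, the
duplicate-pair cohort created by that event shares a characteristic percent
identity, while older duplications sit at lower similarity.  The window
selected here isolates the most recent event's cohort; it is later applied
to synteny-block *mean* similarity (blocks are retained or dropped whole,
individual pairs are never removed from a retained block).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

__all__ = [
    "AnchorPair",
    "SimilarityWindow",
    "Histogram",
    "HomologyError",
    "read_anchor_pairs",
    "write_anchor_pairs",
    "similarity_histogram",
    "select_similarity_window",
]


class HomologyError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair with a percent-identity similarity score."""

    gene_a: str
    gene_b: str
    similarity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity <= 100.0):
            raise HomologyError(
                f"similarity {self.similarity} outside [0, 100] "
                f"for pair ({self.gene_a!r}, {self.gene_b!r})"
            )

    @property
    def unordered(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class SimilarityWindow:
    """Inclusive percent-identity bounds isolating one event cohort."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 100.0):
            raise HomologyError(f"bad similarity window ({self.lower}, {self.upper})")

    def contains(self, similarity: float) -> bool:
        return self.lower <= similarity <= self.upper


@dataclass(frozen=True)
class Histogram:
    """Fixed-width similarity histogram: counts keyed by bin left edge."""

    bin_width: float
    counts: Dict[float, int]

    def __getitem__(self, bin_left: float) -> int:
        return self.counts[bin_left]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def read_anchor_pairs(path: str | Path, self_comparison: bool = False) -> List[AnchorPair]:
    """Load anchor pairs from TSV (gene_a, gene_b, similarity; '#' comments).

    Duplicate unordered pairs are collapsed keeping the maximum similarity.
    In self-comparison mode a gene paired with itself is an error.
    """
    path = Path(path)
    best: Dict[frozenset, AnchorPair] = {}
    order: List[frozenset] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise HomologyError(f"{path.name}:{lineno}: need 3 columns")
            gene_a, gene_b, sim_s = fields[0], fields[1], fields[2]
            if self_comparison and gene_a == gene_b:
                raise HomologyError(
                    f"{path.name}:{lineno}: self-pair {gene_a!r} in self-comparison mode"
                )
            try:
                sim = float(sim_s)
            except ValueError:
                raise HomologyError(
                    f"{path.name}:{lineno}: non-numeric similarity {sim_s!r}"
                ) from None
            try:
                pair = AnchorPair(gene_a, gene_b, sim)
            except HomologyError as exc:
                raise HomologyError(f"{path.name}:{lineno}: {exc}") from None
            key = pair.unordered
            if key not in best:
                best[key] = pair
                order.append(key)
            elif pair.similarity > best[key].similarity:
                best[key] = pair
    return [best[k] for k in order]


def write_anchor_pairs(pairs: Iterable[AnchorPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\tsimilarity\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.similarity:g}\n")


def similarity_histogram(pairs: Iterable[AnchorPair], bin_width: float = 1.0) -> Histogram:
    """Histogram of pair similarities with bins [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise HomologyError(f"bin_width must be positive, got {bin_width}")
    counts: Dict[float, int] = {}
    for p in pairs:
        k = int(p.similarity // bin_width)
        # similarity == 100 falls in the last bin rather than opening a new one
        if p.similarity == 100.0:
            k -= 1 if (100.0 / bin_width) == k else 0
        left = k * bin_width
        counts[left] = counts.get(left, 0) + 1
    return Histogram(bin_width, dict(sorted(counts.items())))


def _smooth(values: Sequence[float]) -> List[float]:
    # centered 3-bin moving average; edges average the two available bins
    n = len(values)
    out = []
    for i in range(n):
        window = values[max(0, i - 1) : min(n, i + 2)]
        out.append(sum(window) / len(window))
    return out


def select_similarity_window(
    hist: Histogram,
    policy: str = "highest_mode",
    manual_bounds: Tuple[float, float] | None = None,
) -> SimilarityWindow:
    """Choose the similarity window isolating the most recent event cohort.

    highest_mode: smooth the histogram with a centered 3-bin moving average,
    take the local mode at the greatest similarity, and extend the window to
    the flanking local minima (or the histogram edges).  manual: return the
    user-supplied bounds unchanged.
    """
    if policy == "manual":
        if manual_bounds is None:
            raise HomologyError("manual policy requires manual_bounds")
        return SimilarityWindow(*manual_bounds)
    if policy != "highest_mode":
        raise HomologyError(f"unknown window policy {policy!r}")
    if not hist.counts:
        raise HomologyError("cannot select a window from an empty histogram")

    w = hist.bin_width
    lefts = sorted(hist.counts)
    lo_bin = int(round(lefts[0] / w))
    hi_bin = int(round(lefts[-1] / w))
    dense = [hist.counts.get(k * w, 0) for k in range(lo_bin, hi_bin + 1)]
    smoothed = _smooth(dense)
    n = len(smoothed)

    modes = [
        i
        for i in range(1, n - 1)
        if smoothed[i] >= smoothed[i - 1]
        and smoothed[i] >= smoothed[i + 1]
        and (smoothed[i] > smoothed[i - 1] or smoothed[i] > smoothed[i + 1])
    ]
    if n >= 2 and smoothed[-1] > smoothed[-2]:
        modes.append(n - 1)  # rising into the right edge still marks a recent cohort
    if not modes:
        raise HomologyError(
            "no local mode detectable (monotone histogram); use the manual policy"
        )
    peak = max(modes)  # the mode at the greatest similarity = most recent cohort

    left = peak
    while left > 0 and smoothed[left - 1] <= smoothed[left]:
        left -= 1
    right = peak
    while right < n - 1 and smoothed[right + 1] <= smoothed[right]:
        right += 1

    lower = max(0.0, (lo_bin + left) * w)
    upper = min(100.0, (lo_bin + right + 1) * w)
    return SimilarityWindow(lower, upper)
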