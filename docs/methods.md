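# Methods

## The measurement

The unit of analysis is the *deletion interval*.  Within a retained synteny
block, consecutive anchor pairs bound a gap; when one side of the gap holds
L ≥ 1 contiguous single-copy genes and the other side holds no annotated
gene, the gap records how much DNA survives where L genes were lost.  Spans
are measured gene-end to gene-start between the bounding anchor genes,
orienting by coordinate so inverted blocks need no special casing;
overlapping bounding genes clamp the span to zero and set a flag.  (A
midpoint convention would shift every span by half a bounding gene on each
side — an L-independent offset that moves intercepts, not slopes; the
end-to-start convention is implemented because the measured quantity is
"DNA between the pairs that bound the segment".)

Ordinary least squares of span on L is fit separately for the two sides.
The default fits every interval as one point (`raw`), which gives honest
standard errors; `length_means` mode fits the per-length means, the
quantity usually plotted.  Lengths beyond a cap (default 30) are excluded
from fits: long intervals are few, and their spans fluctuate accordingly.
Slopes are compared with an unpooled-variance (Welch) t-test,
t = (b₁ − b₂)/√(se₁² + se₂²) with Satterthwaite degrees of freedom from the
two fits' residual degrees of freedom; variances on the two sides differ by
orders of magnitude under excision, so pooling would be wrong.

Interpretation: the unfractionated slope estimates the genome's bp per gene
(inverse gene density); a fractionated slope near zero with a small
intercept is the excision signature (a fixed residual per loss event,
independent of how many genes the event removed); a fractionated slope
comparable to the unfractionated one means the lost genes' DNA is still in
place, i.e. pseudogenization.  `bp_fractionated / (bp per gene)` is an
upper bound on the full-length pseudogenes an interval could contain.

## Block construction

Anchors (homologous gene pairs with percent-identity scores) are chained
within each chromosome pair by iterated longest-chain extraction, the
scheme of the classic collinearity chainers: dynamic programming finds the
maximum-anchor-count chain in which each step advances at most `max_gap`
gene ranks on both sides (increasing on side A; increasing or decreasing on
side B for same/inverted orientation), the chain becomes a block, its
anchors leave the pool, and extraction repeats until the best chain is
shorter than `min_block_size`.  Ties are broken totally and deterministically:
leftmost start rank on side A, then side-B rank, then same before inverted
orientation, then the lexicographically smallest rank sequence.  Gaps are
counted in gene ranks rather than base pairs so interval lengths (in genes)
are exact.  Defaults: `max_gap` 20 ranks, `min_block_size` 5 — the
threshold below which coincidentally neighboring pairs start forming fake
blocks, as the sensitivity sweep (`block_size_sensitivity`) shows.
Self-comparisons drop the trivial self-diagonal and keep one copy of each
mirror-duplicate block (chromosome pair ordered, then lower start rank).

The event cohort is isolated on *block mean* similarity: the pair-similarity
histogram is smoothed with a centered 3-bin moving average, the local mode
at the greatest similarity is taken as the most recent WGD/speciation
cohort, and the window extends to the flanking local minima (a histogram
rising into the 100% edge counts as a mode; a monotone histogram raises an
error directing the user to the manual window).  Blocks whose mean
similarity falls outside the window are dropped whole; pairs are never
removed from a retained block.

## Which gap genes count

A gap gene is *pairing-visible* when it appears among the anchors of the
block construction itself — such a gene demonstrably has a partner and is
two-copy.  A visible gene anywhere in a gap marks the gap `mixed` and no
interval is emitted: segments displaced by inversions look locally like
deletions (genes present on one side, absent between the same anchors on
the other) while their partners live on elsewhere, and admitting them
contaminates both regressions with large-L, wrong-span points.  Gaps with
unpaired annotated genes on *both* sides cannot be oriented and are marked
`ambiguous`.  Genes paired only in the raw anchor list (outside any block)
remain eligible as singletons — that distinction is deliberate: it is
exactly what the translocation audit quantifies afterwards.  The scan
accepts caller-supplied visibility sets, so a raw-pair-list or
all-annotated rule can be swapped in; `nonanchor_genes_in_gap` and the
strict flag in the interval records support those narrower rules.

## The translocation audit

Singletons (unfractionated-side genes of the intervals) are searched
against the *unfiltered* pair list — equivalent to a minimum block size
of 1 — and counted as remotely paired when some pair links them to any
other gene at a similarity inside the event cohort's window.  The reported
percentage is an upper bound on translocation as an alternative to
excision: pre-existing paralog triplets are not deconvolved, and a gene
that migrated *into* a block gap is flagged by the same logic (its pair
points back out), which is how the audit also covers the
retrotransposition counter-argument.  In validation we score an audit hit
for a simulated translocation if either end of the move is flagged — the
orphaned partner at the origin or the moved gene at its destination — and
count flags attached to no translocation event as false positives.

## Gene density comparison

For each genome, gene density inside unfractionated block regions is
Σ(spans)/Σ(genes) over the conserved gaps and the unfractionated sides of
deletion gaps, with each gap's span taken start-of-left-anchor to
start-of-right-anchor and its gene count as 1 (the left anchor) + the
annotated genes between.  Each gap-plus-anchor unit tiles the block, so the
quotient is exactly total bp over total genes of the unfractionated block
regions, directly comparable to the genome-wide bp per gene (total assembly
bp / gene count).  Summing deletion-interval spans alone would overweight
each interval by one flanking intergap (≈ +30% at mean L = 2) and sit off
the equality diagonal even for a perfectly homogeneous genome, which is why
conserved stretches and anchors enter the accounting.  In self-comparisons
the two homeologous sides pool into one point per genome.

## The simulator

`simgenome` generates the study conditions with known ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 10,000 | ancestral genes over `n_chromosomes` = 5 |
| `mean_gene_bp` / `sigma_gene` | 3,000 bp / 0.4 | lognormal gene lengths |
| `mean_intergenic_bp` / `sigma_intergenic` | 5,000 bp / 0.6 | lognormal intergaps |
| `event` | `wgd` | or `speciation` (two genomes) |
| `loss_fraction` | 0.30 | duplicate pairs losing one copy |
| `run_length_p` | 0.5 | geometric run lengths (mean 2) |
| `mechanism` | `excision` | or `pseudogenization` / `mixed` |
| `residual_mean_bp` | 400 | exponential residual per excision event |
| `similarity_recent` / `similarity_old` | N(92, 2) / N(75, 3) % | cohort identities |
| `old_pair_fraction` | 0.20 | genes carrying a pre-event duplicate pair |
| `n_inversions` | 20 | segments of 2–30 genes, order and strand reversed |
| `n_translocations` | 0 | single surviving pair members moved remotely |
| `intergenic_scale_b` | 1.0 | genome-size disproportion knob (e.g. 4.0) |

The layout mirrors a mid-size plant genome (8 kbp per gene, ~80 Mbp);
similarity cohorts are far enough apart (≥ 3 pooled SDs) for automatic
window selection, and 20 inversions is enough to exercise block breakage
(short fragments populate the threshold-3 sweep) while leaving ≥ 95% of
anchors chainable.  Loss runs are placed uniformly at random, never overlap,
and keep one intact pair between runs, so at most one member of each pair
is lost and every run's flanking pairs survive on both copies — each run
maps to at most one deletion interval, which is what makes the truth log a
usable oracle.  The excision residual is drawn once per *event*, not per
gene: that is precisely the data-generating assumption under which a zero
fractionated slope identifies excision.  A `residual_growth_bp_per_gene`
knob adds per-gene residual growth to emulate the slow post-speciation
sequence accretion some large genomes show; it defaults to 0 and no fitted
value is claimed.  Pseudogenization removes annotations (and their anchors)
but folds every base pair into the surrounding intergap; excision removes
the run and all intergenic DNA between the surviving flanks, replacing it
with the residual.  All randomness flows from one seed; emitted GFF3/TSV
fixtures are byte-stable and the truth log replays the ancestor into the
emitted genomes exactly (verified by an independent replay in the tests).

What the simulator does not model: nucleotide sequences, transposable
element dynamics and other repeat turnover, Ks-based dating, paralog
triplets, and gene-density inhomogeneity along chromosomes (intergaps are
i.i.d.).  Passing tests therefore show the *method* recovers the loss
mechanism under its own assumptions — flat-residual excision vs. in-place
pseudogenization with rank-local rearrangements — not that real genomes
satisfy those assumptions; in real data, repeat accumulation can inflate
fractionated spans in large genomes, which is exactly the case the
genome-size normalization (`genome_size_factor`, default basis bp per
gene) is provided for.

## Validation scheme

Tests validate each stage against an independent oracle: chaining against
brute-force exhaustive chain enumeration on ≤ 50-gene instances; interval
scanning against the simulator truth log (exact identity, length and side,
away from rearranged regions, where the log fully determines the
expectation; exact everywhere when rearrangements are off); OLS against
hand-evaluated normal equations; the audit against labeled translocation
events.  Acceptance-level checks assert the quantitative signatures at
n = 10,000 genes, three seeds: excision |slope| < 400 bp/gene (5% of the
per-gene layout) with the unfractionated slope within 10% of 8,000 bp/gene
and p < 10⁻⁶; pseudogenization slope ratio in [0.85, 1.15]; density points
within 10% of the diagonal; threshold-sweep monotonicity; and
post-normalization slope agreement within 10% for a 4× genome-size
contrast.  Problem sizes (10,000 genes, ~1,600 intervals per comparison)
were chosen to keep Monte Carlo noise well inside those bands while a full
suite run stays interactive.

## Known limitations

* Iterated extraction can pull one collinear anchor out of a short
  inverted fragment into the flanking main chain, splitting the fragment's
  remaining anchors below threshold; the visibility rule keeps this from
  fabricating intervals, but a few genuine runs adjacent to inversion
  boundaries are dropped as `mixed`/`ambiguous` (≈ 0.5% of runs at default
  rearrangement rates).
* Percent identity is taken as given; no sequence alignment or Ks
  estimation is performed (a Ks column can be used via the manual window).
* The audit upper-bounds translocation; it does not classify mechanism
  (DNA transposition vs. retrotransposition) and does not deconvolve
  pre-existing triplets.
* Interval spans assume assembled, gap-free coordinates; assembly gaps in
  real annotations would inflate spans on both sides.
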