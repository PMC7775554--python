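"""Gene annotations, gene-order indexing and genome-wide density summaries.

All coordinates are internally 0-based half-open; conversion from GFF3's
1-based inclusive convention happens only at the I/O boundary.  Rank order
within a chromosome is by start coordinate, ties broken by end then gene id,
so that interval scanning is deterministic even for overlapping gene models.
Strand is carried but never used in span arithmetic: the analysis measures
raw DNA amounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Tuple

__all__ = [
    "GeneRecord",
    "GeneTable",
    "GenomeSummary",
    "AnnotationError",
    "read_gff3",
    "read_bed",
    "write_bed",
    "write_gff3",
    "read_assembly_sizes",
    "write_assembly_sizes",
    "summarize_genome",
]


class AnnotationError(ValueError):
    """Malformed annotation input or an inconsistent gene table."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 0-based half-open interval on a chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"gene {self.gene_id!r}: negative start {self.start}")
        if self.end <= self.start:
            raise AnnotationError(
                f"gene {self.gene_id!r}: end {self.end} <= start {self.start}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise AnnotationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneTable:
    """Position-sorted, rank-indexed gene records for one genome.

    Within each chromosome, ranks run 0..n-1 in order of (start, end,
    gene_id); every gene id resolves to exactly one (chromosome, rank).
    """

    def __init__(self, genome_id: str, records: Iterable[GeneRecord]):
        self.genome_id = genome_id
        by_chrom: Dict[str, List[GeneRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chromosome, []).append(rec)
        self._chromosomes: Dict[str, Tuple[GeneRecord, ...]] = {}
        self._rank: Dict[str, Tuple[str, int]] = {}
        for chrom in sorted(by_chrom):
            recs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.gene_id))
            self._chromosomes[chrom] = tuple(recs)
            for i, rec in enumerate(recs):
                if rec.gene_id in self._rank:
                    raise AnnotationError(f"duplicate gene_id {rec.gene_id!r}")
                self._rank[rec.gene_id] = (chrom, i)

    @property
    def chromosomes(self) -> Mapping[str, Tuple[GeneRecord, ...]]:
        return self._chromosomes

    @property
    def n_genes(self) -> int:
        return len(self._rank)

    def __len__(self) -> int:
        return self.n_genes

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank

    def rank(self, gene_id: str) -> Tuple[str, int]:
        """(chromosome, ordinal position) of a gene; KeyError if absent."""
        try:
            return self._rank[gene_id]
        except KeyError:
            raise KeyError(
                f"gene_id {gene_id!r} not found in genome {self.genome_id!r}"
            ) from None

    def gene(self, gene_id: str) -> GeneRecord:
        chrom, i = self.rank(gene_id)
        return self._chromosomes[chrom][i]

    def record_at(self, chromosome: str, rank: int) -> GeneRecord:
        return self._chromosomes[chromosome][rank]

    def genes_between(self, chromosome: str, rank_lo: int, rank_hi: int) -> Tuple[GeneRecord, ...]:
        """Records with rank strictly between rank_lo and rank_hi (orderless)."""
        lo, hi = sorted((rank_lo, rank_hi))
        return self._chromosomes[chromosome][lo + 1 : hi]

    def iter_records(self) -> Iterator[GeneRecord]:
        for chrom in self._chromosomes:
            yield from self._chromosomes[chrom]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneTable):
            return NotImplemented
        return (
            self.genome_id == other.genome_id
            and self._chromosomes == other._chromosomes
        )

    def __repr__(self) -> str:
        return (
            f"GeneTable({self.genome_id!r}, {self.n_genes} genes, "
            f"{len(self._chromosomes)} chromosomes)"
        )


@dataclass(frozen=True)
class GenomeSummary:
    """Genome-wide bp-per-gene: the inverse of gene density."""

    genome_id: str
    total_bp: int
    gene_count: int
    bp_per_gene: Fraction = field(init=False)

    def __post_init__(self) -> None:
        if self.gene_count <= 0:
            raise AnnotationError("gene_count must be positive")
        if self.total_bp <= 0:
            raise AnnotationError("total_bp must be positive")
        object.__setattr__(self, "bp_per_gene", Fraction(self.total_bp, self.gene_count))


def _parse_gff3_attributes(attrs: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for item in attrs.strip().rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.strip().partition("=")
        out[key] = value
    return out


def read_gff3(path: str | Path, feature_type: str = "gene", genome_id: str | None = None) -> GeneTable:
    """Read gene-level features from a GFF3 file into a GeneTable.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    0-based half-open.  Only rows whose feature type matches
    ``feature_type`` are used; the gene id comes from the ID attribute
    (falling back to Name).
    """
    path = Path(path)
    records: List[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"{path.name}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            attributes = _parse_gff3_attributes(attrs)
            gene_id = attributes.get("ID") or attributes.get("Name")
            if not gene_id:
                raise AnnotationError(f"{path.name}:{lineno}: feature has no ID attribute")
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if end <= start:
                raise AnnotationError(
                    f"{path.name}:{lineno}: gene {gene_id!r} has end <= start after conversion"
                )
            records.append(
                GeneRecord(gene_id, chrom, start, end, strand if strand in "+-" else "unknown")
            )
    return GeneTable(genome_id or path.stem, records)


def read_bed(path: str | Path, genome_id: str | None = None) -> GeneTable:
    """Read BED4/BED6 gene intervals (native 0-based half-open) into a GeneTable."""
    path = Path(path)
    records: List[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(
                    f"{path.name}:{lineno}: BED needs >= 4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "unknown"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"{path.name}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            try:
                records.append(GeneRecord(name, chrom, start, end, strand))
            except AnnotationError as exc:
                raise AnnotationError(f"{path.name}:{lineno}: {exc}") from None
    return GeneTable(genome_id or path.stem, records)


def write_bed(table: GeneTable, path: str | Path) -> None:
    """Write a GeneTable as BED6 (score column 0; unknown strand written '.')."""
    with open(path, "w") as fh:
        for rec in table.iter_records():
            strand = rec.strand if rec.strand in "+-" else "."
            fh.write(
                f"{rec.chromosome}\t{rec.start}\t{rec.end}\t{rec.gene_id}\t0\t{strand}\n"
            )


def write_gff3(table: GeneTable, path: str | Path, source: str = "synfrac") -> None:
    """Write a GeneTable as GFF3 gene features (0-based half-open -> 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in table.iter_records():
            strand = rec.strand if rec.strand in "+-" else "."
            fh.write(
                f"{rec.chromosome}\t{source}\tgene\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{strand}\t.\tID={rec.gene_id}\n"
            )


def read_assembly_sizes(path: str | Path) -> Dict[str, int]:
    """Read chromosome sizes from a 2-column TSV (or .fai: extra columns ignored)."""
    path = Path(path)
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path.name}:{lineno}: need >= 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise AnnotationError(
                    f"{path.name}:{lineno}: non-integer length {fields[1]!r}"
                ) from None
    return sizes


def write_assembly_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def summarize_genome(table: GeneTable, assembly_sizes: Mapping[str, int]) -> GenomeSummary:
    """Genome-wide bp per gene over the chromosomes carrying annotated genes.

    Every chromosome with a gene must appear in ``assembly_sizes``; the
    total is the sum of the listed assembly sizes.
    """
    if table.n_genes == 0:
        raise AnnotationError(f"genome {table.genome_id!r} has no genes to summarize")
    for chrom in table.chromosomes:
        if chrom not in assembly_sizes:
            raise AnnotationError(
                f"chromosome {chrom!r} has genes but no assembly size entry"
            )
    total_bp = int(sum(assembly_sizes.values()))
    return GenomeSummary(table.genome_id, total_bp, table.n_genes)
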