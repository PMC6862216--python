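"""Gene-model geometry: exon unions and the intronic regions between them.

Every downstream normalization (FPKM on the exonic compartment, intronic
FPKM as a transcription-rate proxy) depends on two per-gene lengths: the
length of the union of all exons across transcripts, and the summed length
of the gaps (introns) between the merged exons.  This module parses GTF
exon records into :class:`GeneModel` objects carrying that geometry.

Coordinates are 0-based half-open internally; GTF's 1-based inclusive
convention is converted at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AnnotationError",
    "merge_intervals",
    "derive_introns",
    "build_gene_model",
    "parse_annotation",
    "write_gene_geometry",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene collapsed to its exon union, with derived intronic gaps.

    ``exons`` are the merged (non-overlapping, sorted) union of all exon
    records seen for the gene across transcripts; ``introns`` are exactly
    the gaps between consecutive merged exons.
    """

    gene_id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    gene_name: str | None = None
    exons: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)

    @property
    def exon_union_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def intron_length_sum(self) -> int:
        return sum(i.length for i in self.introns)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and union overlapping or book-ended intervals.

    Adjacent intervals ([0,100) + [100,200)) merge: a zero-length gap is
    not an intron.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise AnnotationError(
            f"gene model spans multiple chromosomes: {sorted(chroms)}"
        )
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def derive_introns(exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Return the maximal gaps between merged exons (the intronic region)."""
    if not exons:
        raise AnnotationError("cannot derive introns from an empty exon list")
    merged = merge_intervals(exons)
    return [
        GenomicInterval(a.chrom, a.end, b.start)
        for a, b in zip(merged, merged[1:])
    ]


def build_gene_model(
    gene_id: str,
    exons: Sequence[GenomicInterval],
    strand: str = "+",
    biotype: str = "protein_coding",
    gene_name: str | None = None,
) -> GeneModel:
    merged = merge_intervals(exons)
    return GeneModel(
        gene_id=gene_id,
        chrom=merged[0].chrom,
        strand=strand,
        biotype=biotype,
        gene_name=gene_name,
        exons=merged,
        introns=derive_introns(merged),
    )


def _attr_first(feature, key: str, default: str | None = None) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else default


def parse_annotation(path: str | Path) -> dict[str, GeneModel]:
    """Parse a GTF file into gene models keyed by gene_id.

    Only ``exon`` features are used; exons of all transcripts of a gene are
    collapsed to their union.  GTF coordinates (1-based inclusive) become
    0-based half-open.  A malformed line raises :class:`AnnotationError`
    naming the line number; a gene record carrying no exon features is
    skipped with a warning.
    """
    path = Path(path)
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    seen_gene_ids: set[str] = set()

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path.name} line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                feature = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - rewrap with line number
                raise AnnotationError(f"{path.name} line {lineno}: {exc}") from exc
            gene_id = _attr_first(feature, "gene_id")
            if gene_id is None:
                raise AnnotationError(
                    f"{path.name} line {lineno}: missing gene_id attribute"
                )
            seen_gene_ids.add(gene_id)
            if feature.featuretype != "exon":
                continue
            try:
                iv = GenomicInterval(feature.seqid, feature.start - 1, feature.end)
            except AnnotationError as exc:
                raise AnnotationError(f"{path.name} line {lineno}: {exc}") from exc
            exons_by_gene.setdefault(gene_id, []).append(iv)
            meta.setdefault(
                gene_id,
                {
                    "strand": feature.strand if feature.strand in "+-" else "+",
                    "biotype": _attr_first(feature, "gene_biotype", "protein_coding"),
                    "gene_name": _attr_first(feature, "gene_name"),
                },
            )

    for gene_id in sorted(seen_gene_ids - exons_by_gene.keys()):
        logger.warning("gene %s has no exon features; skipped", gene_id)

    models: dict[str, GeneModel] = {}
    for gene_id in sorted(exons_by_gene):
        m = meta[gene_id]
        models[gene_id] = build_gene_model(
            gene_id,
            exons_by_gene[gene_id],
            strand=m["strand"],
            biotype=m["biotype"],
            gene_name=m["gene_name"],
        )
    return models


def flag_overlapping_genes(models: dict[str, GeneModel]) -> set[str]:
    """Gene ids whose spans overlap another gene's span on the same chromosome.

    The exon/intron split convention is ambiguous for overlapping genes, so
    they are flagged in output rather than silently trusted.
    """
    flagged: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in models.values():
        by_chrom.setdefault(gm.chrom, []).append(gm)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.span.start)
        for a, b in zip(genes, genes[1:]):
            if b.span.start < a.span.end:
                flagged.update((a.gene_id, b.gene_id))
    return flagged


def write_gene_geometry(models: dict[str, GeneModel], path: str | Path) -> None:
    """Write the per-gene geometry TSV used in reports."""
    overlapping = flag_overlapping_genes(models)
    with Path(path).open("w") as fh:
        fh.write(
            "gene_id\tbiotype\tstrand\texon_union_length\t"
            "intron_length_sum\tn_exons\toverlaps_other_gene\n"
        )
        for gene_id in sorted(models):
            gm = models[gene_id]
            fh.write(
                f"{gm.gene_id}\t{gm.biotype}\t{gm.strand}\t{gm.exon_union_length}\t"
                f"{gm.intron_length_sum}\t{len(gm.exons)}\t"
                f"{int(gene_id in overlapping)}\n"
            )


def write_gtf(models: Iterable[GeneModel], path: str | Path, source: str = "mrnafate") -> None:
    """Write merged exon records back out as Ensembl-dialect GTF."""
    with Path(path).open("w") as fh:
        for gm in sorted(models, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
            name = gm.gene_name or gm.gene_id
            for iv in gm.exons:
                attrs = (
                    f'gene_id "{gm.gene_id}"; gene_name "{name}"; '
                    f'gene_biotype "{gm.biotype}";'
                )
                fh.write(
                    f"{gm.chrom}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{gm.strand}\t.\t{attrs}\n"
                )
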