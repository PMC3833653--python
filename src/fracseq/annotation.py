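"""Gene annotation model: stranded genes, exon unions, derived introns.

All coordinates are 0-based half-open on the genomic (plus-strand) axis,
regardless of gene strand. Transcription-oriented quantities (intron order,
5' offsets) are derived from the strand when needed.

Intron size classes used for metagene profiling:

========  ==================
class     intron length (bp)
========  ==================
S         [1 000, 10 000)
M         [10 000, 50 000)
L         [50 000, 100 000)
XL        [100 000, inf)
excluded  < 1 000
========  ==================

Boundaries are half-open on the left so every length lands in exactly one
class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: (lower bound inclusive, class label), descending
_SIZE_CLASS_BOUNDS = ((100_000, "XL"), (50_000, "L"), (10_000, "M"), (1_000, "S"))


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded, 0-based half-open interval on a reference sequence."""

    reference_name: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.reference_name}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.reference_name == other.reference_name
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene: exon union plus the introns derived from it.

    ``exons`` are disjoint, sorted by genomic position, and tile the gene
    span together with ``introns`` (the gaps between consecutive exons).
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...] = field(default=())

    @classmethod
    def from_exons(
        cls,
        gene_id: str,
        reference_name: str,
        strand: str,
        exons: Iterable[tuple[int, int]],
    ) -> "GeneModel":
        """Build a gene from raw exon coordinates: sort, merge overlaps,
        derive introns as the inter-exon gaps."""
        merged = merge_intervals(exons)
        if not merged:
            raise AnnotationError(f"gene {gene_id}: no exons")
        for s, e in merged:
            if e <= s:
                raise AnnotationError(f"gene {gene_id}: zero-length exon [{s},{e})")
        span = GenomicInterval(reference_name, merged[0][0], merged[-1][1], strand)
        exon_ivs = tuple(GenomicInterval(reference_name, s, e, strand) for s, e in merged)
        intron_ivs = tuple(
            GenomicInterval(reference_name, a.end, b.start, strand)
            for a, b in zip(exon_ivs, exon_ivs[1:])
        )
        return cls(gene_id=gene_id, interval=span, exons=exon_ivs, introns=intron_ivs)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def reference_name(self) -> str:
        return self.interval.reference_name


@dataclass(frozen=True)
class IntronRecord:
    """One intron with its profiling metadata.

    ``five_prime_offset`` is the distance from the gene's 5' end (in
    transcription orientation) to the intron's 5' end.
    """

    interval: GenomicInterval
    parent_gene: str
    five_prime_offset: int

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def size_class(self) -> str:
        return size_class(self.length)


def size_class(length: int) -> str:
    """Classify an intron length into S/M/L/XL; below 1 kb -> 'excluded'."""
    if length <= 0:
        raise ValueError(f"intron length must be positive, got {length}")
    for bound, label in _SIZE_CLASS_BOUNDS:
        if length >= bound:
            return label
    return "excluded"


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or bookended (start, end) pairs."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def extract_introns(gene: GeneModel) -> list[IntronRecord]:
    """Introns of one gene in transcription (5'->3') order.

    A single-exon gene yields an empty list. On the minus strand the
    genomic interval order is reversed and offsets are measured from the
    gene's rightmost coordinate leftward.
    """
    records = []
    for intron in gene.introns:
        if gene.strand == "+":
            offset = intron.start - gene.interval.start
        else:
            offset = gene.interval.end - intron.end
        records.append(
            IntronRecord(interval=intron, parent_gene=gene.gene_id, five_prime_offset=offset)
        )
    records.sort(key=lambda r: r.five_prime_offset)
    return records


def collect_introns(
    genes: Sequence[GeneModel],
    deduplicate: bool = True,
    exclude_exon_overlaps: bool = True,
) -> list[IntronRecord]:
    """All introns across genes, ready for profiling.

    Introns identical in coordinates+strand are deduplicated, and introns
    overlapping any same-strand exon of any gene are dropped by default so
    that mature-RNA signal from a nested or overlapping gene cannot leak
    into "intronic" coverage. Set ``exclude_exon_overlaps=False`` to keep
    them.
    """
    records: list[IntronRecord] = []
    seen: set[GenomicInterval] = set()
    for gene in genes:
        for rec in extract_introns(gene):
            if deduplicate:
                if rec.interval in seen:
                    continue
                seen.add(rec.interval)
            records.append(rec)
    if not exclude_exon_overlaps:
        return records

    from intervaltree import IntervalTree

    exon_trees: dict[tuple[str, str], IntervalTree] = {}
    for gene in genes:
        key = (gene.reference_name, gene.strand)
        tree = exon_trees.setdefault(key, IntervalTree())
        for ex in gene.exons:
            tree[ex.start : ex.end] = gene.gene_id
    kept = []
    for rec in records:
        tree = exon_trees.get((rec.interval.reference_name, rec.interval.strand))
        if tree is not None and tree.overlap(rec.interval.start, rec.interval.end):
            log.debug("intron %s excluded: overlaps a same-strand exon", rec.interval)
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# IO


def parse_annotation(path: str | Path, dialect: str | None = None) -> list[GeneModel]:
    """Parse a GTF or BED12 annotation into gene models.

    GTF (1-based inclusive) exons of all transcripts of a gene are unioned
    per strand into one model per gene_id. BED12 (0-based half-open) yields
    one model per record, exons given by blockSizes/blockStarts.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "GTF" if suffix in {".gtf", ".gff"} else "BED12"
    dialect = dialect.upper()
    if dialect == "GTF":
        return _parse_gtf(path)
    if dialect == "BED12":
        return _parse_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _parse_gtf(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    by_gene: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    order: list[tuple[str, str, str]] = []
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            raise AnnotationError(f"exon without gene_id at {feat.seqid}:{feat.start}")
        if feat.strand not in STRANDS:
            raise AnnotationError(
                f"gene {gene_ids[0]}: unstranded exon at {feat.seqid}:{feat.start}"
            )
        key = (gene_ids[0], feat.seqid, feat.strand)
        if key not in by_gene:
            by_gene[key] = []
            order.append(key)
        # gffutils keeps GFF 1-based inclusive coordinates
        by_gene[key].append((feat.start - 1, feat.end))
    return [
        GeneModel.from_exons(gene_id, seqid, strand, by_gene[(gene_id, seqid, strand)])
        for gene_id, seqid, strand in order
    ]


def _parse_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: blockCount disagrees with block lists")
            exons = []
            for bs, sz in zip(starts, sizes):
                if sz <= 0:
                    raise AnnotationError(f"{path}:{lineno}: zero-length block")
                exon = (start + bs, start + bs + sz)
                if exon[1] > end:
                    raise AnnotationError(f"{path}:{lineno}: block extends past record end")
                exons.append(exon)
            try:
                genes.append(GeneModel.from_exons(name, chrom, strand, exons))
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (one record per gene, exons as blocks)."""
    with open(path, "w") as fh:
        for g in genes:
            start = g.interval.start
            sizes = ",".join(str(e.length) for e in g.exons)
            starts = ",".join(str(e.start - start) for e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.reference_name,
                        str(start),
                        str(g.interval.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(start),
                        str(g.interval.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "fracseq") -> None:
    """Write gene models as GTF exon records (1-based inclusive), one
    transcript per gene (the exon union)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            for ex in g.exons:
                fh.write(
                    "\t".join(
                        [
                            g.reference_name,
                            source,
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_introns_bed6(introns: Sequence[IntronRecord], path: str | Path) -> None:
    """Write introns as BED6; the name field carries parent gene and size class."""
    with open(path, "w") as fh:
        for rec in introns:
            iv = rec.interval
            name = f"{rec.parent_gene}|{rec.size_class}"
            fh.write(
                f"{iv.reference_name}\t{iv.start}\t{iv.end}\t{name}\t{rec.length}\t{iv.strand}\n"
            )
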