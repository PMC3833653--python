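"""Exon/intron read partitioning, EI-ratios, and expressed-exon calling.

The EI-ratio of a library is E/(E+I), where E and I count reads whose
aligned blocks overlap exons and introns of same-strand genes. It runs
from 1 (all intragenic reads exonic — fully mature RNA) to 0 (all
intronic — nascent RNA). Reads antisense to every overlapping gene, or
intergenic, are unassigned.

Expressed exons are called against an empirical background null: the dcpm
of every exon measured on the antisense strand, whose 99th percentile
(nearest-rank) becomes the detection cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .annotation import GeneModel, GenomicInterval
from .coverage import AlignedRead, GenomeCoverage


@dataclass(frozen=True)
class EIResult:
    """Exonic/intronic read partition for one alignment set."""

    E: int
    I: int
    unassigned: int

    @property
    def total(self) -> int:
        return self.E + self.I + self.unassigned

    @property
    def ei_ratio(self) -> float:
        return ei_ratio(self.E, self.I)


@dataclass(frozen=True)
class ExonExpressionCall:
    exon: GenomicInterval
    sense_dcpm: float
    cutoff: float

    @property
    def expressed(self) -> bool:
        return self.sense_dcpm > self.cutoff


@dataclass(frozen=True)
class ExpressionSummary:
    """Per-sample expressed-exon calls plus the cutoff that produced them."""

    label: str
    calls: tuple[ExonExpressionCall, ...]
    cutoff: float

    @property
    def n_expressed(self) -> int:
        return sum(c.expressed for c in self.calls)


def ei_ratio(E: int, I: int) -> float:
    """E/(E+I); raises when no read is intragenic (ratio undefined)."""
    if E < 0 or I < 0:
        raise ValueError("counts must be non-negative")
    if E + I == 0:
        raise ZeroDivisionError("EI-ratio undefined: no exonic or intronic reads")
    return E / (E + I)


class _GeneIndex:
    """Same-strand interval lookup of exons and introns across genes."""

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("empty gene set")
        self.exons: dict[tuple[str, str], IntervalTree] = {}
        self.introns: dict[tuple[str, str], IntervalTree] = {}
        for gene in genes:
            key = (gene.reference_name, gene.strand)
            etree = self.exons.setdefault(key, IntervalTree())
            itree = self.introns.setdefault(key, IntervalTree())
            for ex in gene.exons:
                etree[ex.start : ex.end] = gene.gene_id
            for iv in gene.introns:
                itree[iv.start : iv.end] = gene.gene_id

    def hits(self, read: AlignedRead, trees: dict) -> set[str]:
        tree = trees.get((read.reference_name, read.strand))
        if tree is None:
            return set()
        out: set[str] = set()
        for s, e in read.blocks:
            for hit in tree.overlap(s, e):
                out.add(hit.data)
        return out


def assign_reads(
    reads: Sequence[AlignedRead],
    genes: Sequence[GeneModel],
    count_mode: str = "exon-priority",
    per_gene: bool = False,
) -> EIResult | tuple[EIResult, dict[str, EIResult]]:
    """Partition reads into exonic (E), intronic (I), and unassigned.

    Only same-strand overlaps count. Under the default ``exon-priority``
    mode each read lands in at most one category, exon first, so
    E + I + unassigned equals the input read count. Under ``both`` a read
    overlapping an exon and an intron increments both E and I (the naive
    two-pass intersection), so E + I can exceed the read count.

    With ``per_gene=True`` also returns per-gene results; a read touching
    several genes is attributed to the lexicographically first hit.
    """
    if count_mode not in {"exon-priority", "both"}:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    index = _GeneIndex(genes)
    E = I = unassigned = 0
    gene_counts: dict[str, list[int]] = {}

    def bump(gene_ids: set[str], slot: int) -> None:
        if per_gene and gene_ids:
            counts = gene_counts.setdefault(min(gene_ids), [0, 0])
            counts[slot] += 1

    for read in reads:
        exon_hits = index.hits(read, index.exons)
        intron_hits = index.hits(read, index.introns)
        if count_mode == "exon-priority":
            if exon_hits:
                E += 1
                bump(exon_hits, 0)
            elif intron_hits:
                I += 1
                bump(intron_hits, 1)
            else:
                unassigned += 1
        else:
            if exon_hits:
                E += 1
                bump(exon_hits, 0)
            if intron_hits:
                I += 1
                bump(intron_hits, 1)
            if not exon_hits and not intron_hits:
                unassigned += 1
    result = EIResult(E=E, I=I, unassigned=unassigned)
    if per_gene:
        per = {g: EIResult(E=c[0], I=c[1], unassigned=0) for g, c in sorted(gene_counts.items())}
        return result, per
    return result


def antisense_cutoff(antisense_dcpms: Sequence[float], percentile: float = 99.0) -> float:
    """Nearest-rank percentile of the antisense background distribution.

    Sort ascending and return the element at rank ceil(p/100 * n) — no
    interpolation, so the cutoff is always an observed background value and
    is reproducible across implementations.
    """
    values = np.sort(np.asarray(antisense_dcpms, dtype=float))
    if values.size == 0:
        raise ValueError("empty background distribution")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    rank = math.ceil(percentile / 100 * values.size)
    return float(values[rank - 1])


def call_expressed_exons(
    exons: Sequence[GenomicInterval],
    samples: Sequence[tuple[str, GenomeCoverage]],
    mode: str = "per_sample",
    percentile: float = 99.0,
) -> list[ExpressionSummary]:
    """Call expressed exons per sample against the antisense-strand null.

    The background for each sample is the dcpm of every exon measured on
    the antisense strand. ``mode='pooled'`` pools the backgrounds of all
    samples into one cutoff applied to every sample (requires >= 2
    samples); ``mode='per_sample'`` derives one cutoff per sample. An exon
    is expressed iff its sense dcpm is strictly above the cutoff, so an
    all-zero background never calls zero-coverage exons.
    """
    if mode not in {"pooled", "per_sample"}:
        raise ValueError(f"unknown mode {mode!r}")
    if not samples:
        raise ValueError("no samples supplied")
    if mode == "pooled" and len(samples) < 2:
        raise ValueError("pooled mode needs at least two samples")
    sense = {}
    antisense = {}
    for label, cov in samples:
        sense[label] = [cov.sense_dcpm(ex) for ex in exons]
        antisense[label] = [cov.antisense_dcpm(ex) for ex in exons]
    if mode == "pooled":
        pooled = [v for label, _ in samples for v in antisense[label]]
        cutoffs = {label: antisense_cutoff(pooled, percentile) for label, _ in samples}
    else:
        cutoffs = {
            label: antisense_cutoff(antisense[label], percentile) for label, _ in samples
        }
    out = []
    for label, _ in samples:
        cut = cutoffs[label]
        calls = tuple(
            ExonExpressionCall(exon=ex, sense_dcpm=v, cutoff=cut)
            for ex, v in zip(exons, sense[label])
        )
        out.append(ExpressionSummary(label=label, calls=calls, cutoff=cut))
    return out
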