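"""Strand-specific per-base coverage, dcpm normalization, and down-sampling.

A read is a set of aligned blocks on one strand; gaps between blocks
(spliced-out segments, CIGAR ``N``) contribute no coverage. Deletions
(CIGAR ``D``) are short reference gaps within an aligned segment and are
counted as covered.

dcpm — average depth of coverage per million mapped reads — is the mean
per-base depth over a region divided by (library mapped reads / 1e6). It
normalizes for library size and mapping efficiency, so values are
comparable across libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation import STRANDS, GenomicInterval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedRead:
    """One aligned single-end read as sorted, non-overlapping blocks."""

    reference_name: str
    blocks: tuple[tuple[int, int], ...]
    strand: str
    read_id: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"read {self.read_id}: strand must be '+' or '-'")
        prev_end = -1
        for s, e in self.blocks:
            if e <= s or s < prev_end:
                raise ValueError(f"read {self.read_id}: malformed blocks {self.blocks}")
            prev_end = e

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class CoverageTrack:
    """Per-base read depth on one strand of one reference sequence."""

    reference_name: str
    strand: str
    depth: np.ndarray
    total_mapped_reads: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def mean_depth(self, start: int, end: int) -> float:
        if not 0 <= start < end <= self.depth.size:
            raise ValueError(f"region [{start},{end}) outside reference of length {self.depth.size}")
        return float(self.depth[start:end].mean())


class GenomeCoverage:
    """Per-strand coverage of one library over all its references.

    Wraps the (+, -) track pairs so callers can ask for the sense or
    antisense dcpm of a stranded region without tracking which physical
    track is which.
    """

    def __init__(self, tracks: dict[tuple[str, str], CoverageTrack], total_mapped_reads: int):
        self.tracks = tracks
        self.total_mapped_reads = total_mapped_reads
        for track in tracks.values():
            track.total_mapped_reads = total_mapped_reads

    @classmethod
    def from_reads(
        cls,
        reads: Sequence[AlignedRead],
        reference_lengths: dict[str, int],
        total_mapped_reads: int | None = None,
    ) -> "GenomeCoverage":
        by_ref: dict[str, list[AlignedRead]] = {name: [] for name in reference_lengths}
        for read in reads:
            try:
                by_ref[read.reference_name].append(read)
            except KeyError:
                raise ValueError(
                    f"read {read.read_id} on unknown reference {read.reference_name!r}"
                ) from None
        total = len(reads) if total_mapped_reads is None else total_mapped_reads
        tracks: dict[tuple[str, str], CoverageTrack] = {}
        for name, length in reference_lengths.items():
            plus, minus = build_coverage(by_ref[name], length, name, total)
            tracks[(name, "+")] = plus
            tracks[(name, "-")] = minus
        return cls(tracks, total)

    def track(self, reference_name: str, strand: str) -> CoverageTrack:
        return self.tracks[(reference_name, strand)]

    def sense_dcpm(self, region: GenomicInterval) -> float:
        return dcpm(region, self.track(region.reference_name, region.strand))

    def antisense_dcpm(self, region: GenomicInterval) -> float:
        other = "-" if region.strand == "+" else "+"
        return dcpm(region, self.track(region.reference_name, other), check_strand=False)


def build_coverage(
    reads: Iterable[AlignedRead],
    reference_length: int,
    reference_name: str = "",
    total_mapped_reads: int | None = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Accumulate per-base, per-strand depth from aligned blocks.

    Returns a (plus, minus) pair of tracks. ``total_mapped_reads`` defaults
    to the number of input reads, the denominator used for dcpm.
    """
    # difference arrays: O(blocks) accumulation, one cumsum per strand
    delta = {s: np.zeros(reference_length + 1, dtype=np.int64) for s in STRANDS}
    n = 0
    for read in reads:
        n += 1
        if not reference_name:
            reference_name = read.reference_name
        d = delta[read.strand]
        for s, e in read.blocks:
            if s < 0 or e > reference_length:
                raise ValueError(
                    f"read {read.read_id}: block [{s},{e}) outside reference "
                    f"of length {reference_length}"
                )
            d[s] += 1
            d[e] -= 1
    if total_mapped_reads is None:
        total_mapped_reads = n
    plus = CoverageTrack(reference_name, "+", np.cumsum(delta["+"][:-1]), total_mapped_reads)
    minus = CoverageTrack(reference_name, "-", np.cumsum(delta["-"][:-1]), total_mapped_reads)
    return plus, minus


def dcpm(region: GenomicInterval, track: CoverageTrack, check_strand: bool = True) -> float:
    """Mean per-base depth over ``region`` per million mapped reads."""
    if check_strand and region.strand != track.strand:
        raise ValueError(f"region strand {region.strand} != track strand {track.strand}")
    if track.total_mapped_reads <= 0:
        raise ValueError("track has no mapped reads; dcpm undefined")
    mean = track.mean_depth(region.start, region.end)
    return mean / (track.total_mapped_reads / 1e6)


def subsample(reads: Sequence[AlignedRead], n: int, seed: int) -> list[AlignedRead]:
    """Uniform sample of exactly ``n`` reads without replacement.

    Deterministic for a given (seed, input); the input order of the kept
    reads is preserved.
    """
    if not 0 <= n <= len(reads):
        raise ValueError(f"cannot sample {n} reads from {len(reads)}")
    if n == len(reads):
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


# ---------------------------------------------------------------------------
# Alignment IO

_COVERED_OPS = {0, 2, 7, 8}  # M, D, =, X consume reference and count as covered
_GAP_OPS = {3}  # N: spliced gap, consumes reference, uncovered


def _blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    blocks: list[tuple[int, int]] = []
    cur = pos
    seg_start = pos
    open_seg = False
    for op, length in cigartuples:
        if op in _COVERED_OPS:
            if not open_seg:
                seg_start = cur
                open_seg = True
            cur += length
        elif op in _GAP_OPS:
            if open_seg:
                blocks.append((seg_start, cur))
                open_seg = False
            cur += length
        # I, S, H, P consume no reference
    if open_seg:
        blocks.append((seg_start, cur))
    return tuple(blocks)


def read_alignments(
    path: str | Path,
    dialect: str | None = None,
    flip_strand: bool = False,
    min_mapq: int = 0,
) -> tuple[list[AlignedRead], dict[str, int]]:
    """Read SAM/BAM or BED12 alignments.

    Returns (reads, reference lengths). ``flip_strand`` swaps the recorded
    strand at ingest for reverse-stranded library protocols. Reference
    lengths for BED12 input are lower bounds (max end seen per reference).
    """
    path = Path(path)
    if dialect is None:
        dialect = "SAM" if path.suffix.lower() in {".sam", ".bam", ".cram"} else "BED12"
    dialect = dialect.upper()
    flip = {"+": "-", "-": "+"}
    if dialect in {"SAM", "BAM"}:
        import pysam

        reads = []
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            ref_lengths = dict(zip(fh.references, fh.lengths))
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.mapping_quality < min_mapq:
                    continue
                strand = "-" if aln.is_reverse else "+"
                if flip_strand:
                    strand = flip[strand]
                reads.append(
                    AlignedRead(
                        reference_name=aln.reference_name,
                        blocks=_blocks_from_cigar(aln.reference_start, aln.cigartuples),
                        strand=strand,
                        read_id=aln.query_name,
                    )
                )
        return reads, ref_lengths
    if dialect == "BED12":
        reads = []
        ref_lengths: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 12:
                    raise ValueError(f"{path}:{lineno}: expected BED12, got {len(f)} fields")
                start = int(f[1])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                strand = f[5] if not flip_strand else flip[f[5]]
                blocks = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
                reads.append(AlignedRead(f[0], blocks, strand, f[3]))
                ref_lengths[f[0]] = max(ref_lengths.get(f[0], 0), int(f[2]))
        return reads, ref_lengths
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_alignments_bed12(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            start, end = r.start, r.end
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            starts = ",".join(str(s - start) for s, e in r.blocks)
            fh.write(
                f"{r.reference_name}\t{start}\t{end}\t{r.read_id}\t0\t{r.strand}"
                f"\t{start}\t{end}\t0\t{len(r.blocks)}\t{sizes}\t{starts}\n"
            )


def write_alignments_sam(
    reads: Iterable[AlignedRead], path: str | Path, reference_lengths: dict[str, int]
) -> None:
    """Write reads as an unsorted SAM file (sequence and qualities omitted)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.reference_name = r.reference_name
            a.reference_start = r.start
            a.mapping_quality = 255
            a.flag = 16 if r.strand == "-" else 0
            cigar = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None:
                    cigar.append((3, s - prev_end))  # N gap
                cigar.append((0, e - s))  # M
                prev_end = e
            a.cigartuples = cigar
            fh.write(a)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write non-zero runs of a coverage track as bedGraph."""
    depth = np.asarray(track.depth)
    change = np.flatnonzero(np.diff(depth)) + 1
    edges = np.concatenate(([0], change, [depth.size]))
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.reference_name}({track.strand})"\n')
        for s, e in zip(edges[:-1], edges[1:]):
            v = int(depth[s])
            if v:
                fh.write(f"{track.reference_name}\t{s}\t{e}\t{v}\n")
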