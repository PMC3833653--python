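"""Synthetic stranded RNA-seq from a mature/nascent transcript mixture.

The generative model mimics subcellular RNA fractions:

* A **mature** molecule is the fully spliced transcript (exons only).
  Reads from it never touch intronic bases; junction-spanning reads
  become multi-block alignments.
* A **nascent** molecule is a transcript caught mid-synthesis with RNA
  polymerase at position ``p`` along the gene. Introns are excised
  co-transcriptionally: an intron whose 3' end lies a distance ``d``
  behind the polymerase is still retained with probability
  ``exp(-d / lam)``, where ``lam`` (the splicing half-distance) is the
  characteristic polymerase travel distance over which excision
  completes. Introns the polymerase has not cleared are present up to
  ``p``. Uniform polymerase occupancy along the gene produces the
  declining 5'->3' intron coverage gradient characteristic of nuclear
  RNA.
* A **polyA-retained** molecule models polyadenylation before splicing
  has finished: full length, with each intron retained with the same
  distance kernel evaluated at the 3' end of the gene.

Reads are sampled the way a sequencer samples a fragment pool: within a
class, a molecule is drawn with probability proportional to the number
of read start positions it offers (its length minus read length + 1),
and the read start is uniform on the molecule. Under this model the
expected nascent read depth at gene offset x, with no splicing, is
proportional to (L - x)/L.

The class mixture is exact-multinomial at the configured proportions, so
the mature fraction ``m`` can be recovered from the observed EI-ratio via
``EI = m + (1 - m) * e_n``, where ``e_n`` is the probability that a
nascent read is called exonic (estimated by Monte Carlo).

Reads are emitted as already-aligned block records (no base calls, no
sequencing error): every downstream computation in this package consumes
alignments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .coverage import AlignedRead

log = logging.getLogger(__name__)

MATURE, NASCENT, POLYA = "mature", "nascent", "polyA_retained"

#: Fraction presets: relative shares of mature / polyA-retained molecules
#: (the remainder is nascent). Chosen to reproduce the characteristic
#: EI-ratio ordering cytoplasmic > polyA >= total > nuclear.
PRESETS: dict[str, dict] = {
    "cytoplasmic": {"mature_fraction": 0.95, "polya_retention": 0.0},
    "nuclear": {"mature_fraction": 0.10, "polya_retention": 0.0},
    "total": {"mature_fraction": 0.25, "polya_retention": 0.0},
    "polyA": {"mature_fraction": 0.30, "polya_retention": 0.70},
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulation run; identical config => identical output.

    Lengths are in bases. ``intron_length_range`` is sampled log-uniformly
    so all four size classes (S/M/L/XL) are populated.
    """

    n_genes: int = 60
    exon_count_range: tuple[int, int] = (2, 6)
    exon_length_range: tuple[int, int] = (100, 400)
    intron_length_range: tuple[int, int] = (1_500, 300_000)
    read_length: int = 75
    n_reads: int = 50_000
    mature_fraction: float = 1.0  # m: share of fully spliced molecules
    splicing_half_distance: float = 20_000.0  # lam; np.inf disables splicing
    polya_retention: float = 0.0  # share of polyA-retained molecules
    expression_sigma: float = 1.0  # lognormal spread of per-gene weights
    gene_spacing: int = 5_000
    reference_name: str = "chrS"
    reference_length: int | None = None  # None: sized to fit the genes
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mature_fraction <= 1.0:
            raise ValueError("mature_fraction must be in [0, 1]")
        if not 0.0 <= self.polya_retention <= 1.0:
            raise ValueError("polya_retention must be in [0, 1]")
        if self.mature_fraction + self.polya_retention > 1.0 + 1e-12:
            raise ValueError("mature_fraction + polya_retention must not exceed 1")
        if not self.splicing_half_distance > 0:
            raise ValueError("splicing_half_distance must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.n_genes < 1 or self.n_reads < 0:
            raise ValueError("n_genes must be >= 1 and n_reads >= 0")


@dataclass
class SimTruth:
    """Per-read ground truth plus the generating configuration."""

    reads: pd.DataFrame  # read_id, gene_id, cls, pol_position, n_introns_retained
    config: SimulationConfig
    n_resampled: int = 0

    def class_fractions(self) -> pd.Series:
        return self.reads["cls"].value_counts(normalize=True)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def expression_weights(config: SimulationConfig, n_genes: int | None = None) -> np.ndarray:
    """Per-gene expression weights (normalized lognormal), fixed by the seed."""
    n = config.n_genes if n_genes is None else n_genes
    w = _rng(config.seed, 1).lognormal(mean=0.0, sigma=config.expression_sigma, size=n)
    return w / w.sum()


def preset_config(name: str, **overrides) -> SimulationConfig:
    """A SimulationConfig for one of the RNA-fraction presets."""
    try:
        params = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return SimulationConfig(**{**params, **overrides})


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Lay out non-overlapping genes on both strands of one reference.

    Exon counts and lengths are uniform on their configured ranges; intron
    lengths are log-uniform so every size class is represented in a run of
    realistic size. Returns the gene models and the reference lengths.
    """
    rng = _rng(config.seed, 0)
    lo_i, hi_i = config.intron_length_range
    genes: list[GeneModel] = []
    cursor = config.gene_spacing
    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        exon_lens = rng.integers(
            config.exon_length_range[0], config.exon_length_range[1] + 1, size=n_exons
        )
        intron_lens = np.exp(
            rng.uniform(np.log(lo_i), np.log(hi_i), size=n_exons - 1)
        ).astype(np.int64)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        genes.append(GeneModel.from_exons(f"g{g:04d}", config.reference_name, strand, exons))
        cursor = pos + config.gene_spacing
    if config.reference_length is not None and cursor > config.reference_length:
        raise ValueError(
            f"genes need {cursor} bases but reference_length is {config.reference_length}; "
            "increase reference_length or reduce n_genes/intron lengths"
        )
    ref_len = config.reference_length if config.reference_length is not None else cursor
    return genes, {config.reference_name: int(ref_len)}


# ---------------------------------------------------------------------------
# Gene geometry in transcription coordinates


class _GeneGeometry:
    """A gene in transcription coordinates (0 at the 5' end)."""

    def __init__(self, gene: GeneModel):
        self.gene = gene
        self.L = gene.interval.length
        start, end = gene.interval.start, gene.interval.end
        if gene.strand == "+":
            exon_t = [(e.start - start, e.end - start) for e in gene.exons]
            intron_t = [(i.start - start, i.end - start) for i in gene.introns]
        else:
            exon_t = [(end - e.end, end - e.start) for e in gene.exons]
            intron_t = [(end - i.end, end - i.start) for i in gene.introns]
        self.exon_t = sorted(exon_t)
        intron_t = sorted(intron_t)
        self.intron_ts = np.array([a for a, _ in intron_t], dtype=np.int64)
        self.intron_te = np.array([b for _, b in intron_t], dtype=np.int64)
        self.intron_len = self.intron_te - self.intron_ts
        self.T = sum(b - a for a, b in self.exon_t)  # mature transcript length

    def to_genomic_blocks(self, t_blocks: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
        gene = self.gene
        if gene.strand == "+":
            start = gene.interval.start
            blocks = [(start + a, start + b) for a, b in t_blocks]
        else:
            end = gene.interval.end
            blocks = [(end - b, end - a) for a, b in t_blocks]
            blocks.reverse()
        return tuple(blocks)


def _kept_segments(
    p: int, intron_ts: np.ndarray, intron_te: np.ndarray, spliced: Sequence[int]
) -> list[tuple[int, int]]:
    """Transcribed segments [0, p) minus the spliced introns."""
    segs = []
    cur = 0
    for i in spliced:
        ts, te = int(intron_ts[i]), int(intron_te[i])
        if ts > cur:
            segs.append((cur, ts))
        cur = te
    if cur < p:
        segs.append((cur, p))
    return segs


def _read_blocks(segs: Sequence[tuple[int, int]], s: int, r: int) -> list[tuple[int, int]]:
    """Map molecule coordinates [s, s+r) through kept segments."""
    blocks = []
    off = 0
    lo, hi = s, s + r
    for a, b in segs:
        seg_len = b - a
        x0, x1 = max(lo, off), min(hi, off + seg_len)
        if x0 < x1:
            blocks.append((a + x0 - off, a + x1 - off))
        off += seg_len
        if off >= hi:
            break
    return blocks


# ---------------------------------------------------------------------------
# Reads


def _sample_molecules(
    geom: _GeneGeometry,
    k: int,
    read_length: int,
    lam: float,
    rng: np.random.Generator,
    full_length: bool,
) -> tuple[list[tuple[int, tuple[int, ...]]], int]:
    """Draw ``k`` (polymerase position, spliced intron set) pairs.

    Molecules are accepted with probability proportional to the number of
    read start positions they offer, implementing fragment-pool sampling;
    molecules shorter than the read are resampled. ``full_length`` pins
    the polymerase at the gene end (polyA-retained molecules).
    """
    out: list[tuple[int, tuple[int, ...]]] = []
    L, r = geom.L, read_length
    denom = max(L - r + 1, 1)
    n_introns = geom.intron_ts.size
    n_short = 0
    attempts = 0
    while len(out) < k:
        attempts += 1
        if attempts > 200 + 50 * k:
            raise RuntimeError(
                f"gene {geom.gene.gene_id}: molecule sampling acceptance too low "
                f"(lam={lam}, read_length={r})"
            )
        b = max(64, 2 * (k - len(out)))
        if full_length:
            p = np.full(b, L, dtype=np.int64)
        else:
            p = rng.integers(1, L + 1, size=b)
        if n_introns:
            cleared = geom.intron_te[None, :] <= p[:, None]
            with np.errstate(over="ignore"):
                retain_p = np.exp(
                    -np.maximum(p[:, None] - geom.intron_te[None, :], 0) / lam
                )
            spliced = cleared & (rng.random((b, n_introns)) >= retain_p)
            m_len = p - (spliced * geom.intron_len[None, :]).sum(axis=1)
        else:
            spliced = np.zeros((b, 0), dtype=bool)
            m_len = p
        accept_p = (m_len - r + 1) / denom
        n_short += int((m_len < r).sum())
        keep = rng.random(b) < np.clip(accept_p, 0.0, 1.0)
        for idx in np.flatnonzero(keep):
            if len(out) == k:
                break
            out.append((int(p[idx]), tuple(np.flatnonzero(spliced[idx]))))
    return out, n_short


def simulate_reads(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignedRead], SimTruth]:
    """Generate aligned reads and ground truth from the mixture model.

    Each read picks a gene proportional to its expression weight and a
    class (mature / nascent / polyA-retained) at the configured mixture,
    then a molecule and a uniform start on it; block coordinates are
    mapped back to the genome on the gene's strand.
    """
    if rng is None:
        rng = _rng(config.seed, 2)
    r = config.read_length
    lam = config.splicing_half_distance
    weights = expression_weights(config, len(genes))
    geoms = [_GeneGeometry(g) for g in genes]
    for geom in geoms:
        if geom.T < r:
            raise ValueError(
                f"gene {geom.gene.gene_id}: mature transcript ({geom.T} bases) is "
                f"shorter than the read length {r}"
            )
    p_nascent = 1.0 - config.mature_fraction - config.polya_retention
    counts = rng.multinomial(config.n_reads, weights)
    rows: list[tuple[str, str, float, int]] = []
    reads_raw: list[tuple[tuple[tuple[int, int], ...], str, str]] = []
    n_resampled = 0
    for geom, n_gene in zip(geoms, counts):
        if n_gene == 0:
            continue
        pvals = np.array(
            [config.mature_fraction, config.polya_retention, max(p_nascent, 0.0)]
        )
        k_mat, k_pa, k_nas = rng.multinomial(n_gene, pvals / pvals.sum())
        gene = geom.gene
        # mature: all molecules identical (the spliced transcript)
        if k_mat:
            starts = rng.integers(0, geom.T - r + 1, size=k_mat)
            for s in starts:
                t_blocks = _read_blocks(geom.exon_t, int(s), r)
                reads_raw.append((geom.to_genomic_blocks(t_blocks), gene.strand, MATURE))
                rows.append((gene.gene_id, MATURE, np.nan, len(gene.introns)))
        for k, full in ((k_pa, True), (k_nas, False)):
            if not k:
                continue
            mols, short = _sample_molecules(geom, int(k), r, lam, rng, full_length=full)
            n_resampled += short
            cls = POLYA if full else NASCENT
            for p, spliced in mols:
                segs = _kept_segments(p, geom.intron_ts, geom.intron_te, spliced)
                m_len = sum(b - a for a, b in segs)
                s = int(rng.integers(0, m_len - r + 1))
                t_blocks = _read_blocks(segs, s, r)
                reads_raw.append((geom.to_genomic_blocks(t_blocks), gene.strand, cls))
                n_cleared = int((geom.intron_te <= p).sum())
                rows.append((gene.gene_id, cls, float(p), n_cleared - len(spliced)))
    if n_resampled:
        log.debug("resampled %d molecules shorter than the read length", n_resampled)
    order = rng.permutation(len(reads_raw))
    reads = []
    truth_rows = []
    ref = config.reference_name
    for new_id, idx in enumerate(order):
        blocks, strand, _cls = reads_raw[idx]
        gene_id, cls, p, n_ret = rows[idx]
        rid = f"r{new_id:07d}"
        reads.append(AlignedRead(reference_name=ref, blocks=blocks, strand=strand, read_id=rid))
        truth_rows.append((rid, gene_id, cls, p, n_ret))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "gene_id", "cls", "pol_position", "n_introns_retained"]
    )
    return reads, SimTruth(reads=truth, config=config, n_resampled=n_resampled)


# ---------------------------------------------------------------------------
# Mature-fraction estimator


def expected_nascent_exonic_fraction(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    n: int = 100_000,
) -> tuple[float, float]:
    """Monte-Carlo estimate of e_n, P(a nascent read is called exonic).

    Simulates a nascent-only library on an independent random stream (same
    expression weights as the configured run) and applies the exon-priority
    assignment. Returns (estimate, binomial standard error).
    """
    from .metrics import assign_reads

    cfg = replace(config, mature_fraction=0.0, polya_retention=0.0, n_reads=n)
    reads, _ = simulate_reads(cfg, genes, rng=_rng(config.seed, 3))
    result = assign_reads(reads, list(genes))
    total = result.E + result.I
    if total == 0:
        return 0.0, 0.0
    e_n = result.E / total
    se = float(np.sqrt(e_n * (1.0 - e_n) / total))
    return e_n, se


def estimate_mature_fraction(ei_observed: float, e_n: float) -> float:
    """Invert EI = m + (1 - m) * e_n for the mature fraction m.

    ``e_n`` is the exonic probability of a purely nascent library; the
    estimate is clamped to [0, 1] with a warning when the observed ratio
    falls outside [e_n, 1].
    """
    if not 0.0 <= e_n <= 1.0:
        raise ValueError("e_n must be in [0, 1]")
    if e_n >= 1.0:
        raise ValueError("e_n == 1: mature fraction is unidentifiable")
    m_hat = (ei_observed - e_n) / (1.0 - e_n)
    if m_hat < 0.0 or m_hat > 1.0:
        warnings.warn(
            f"observed EI-ratio {ei_observed:.4f} outside [e_n={e_n:.4f}, 1]; "
            "estimate clamped",
            stacklevel=2,
        )
        m_hat = min(max(m_hat, 0.0), 1.0)
    return m_hat
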