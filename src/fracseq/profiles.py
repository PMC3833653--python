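"""Intron metagene coverage profiles and the 5'->3' slope statistic.

Each intron is divided into 100 equal-fraction bins plus 50 bp per-base
flanks, oriented so index 0 is the transcriptional 5' end (minus-strand
introns are reversed). Profiles are averaged within intron size classes
(S/M/L/XL); nascent transcription shows up as a negative 5'->3' gradient
across long introns, steepest where the fraction is richest in unspliced
pre-mRNA.

The slope statistic is an ordinary-least-squares fit of bin mean depth
against position (as a fraction of intron length traversed), divided by
the profile mean: the fractional change in coverage over the full intron.
It quantifies the gradient that coverage plots show graphically; it is a
derived summary of this package, not a published estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import IntronRecord
from .coverage import CoverageTrack, GenomeCoverage

log = logging.getLogger(__name__)

SIZE_CLASS_ORDER = ("XL", "L", "M", "S")


class IntronTooShort(ValueError):
    """Intron shorter than the number of bins; cannot be profiled."""


@dataclass
class IntronProfile:
    """Binned coverage for one intron or a size-class aggregate."""

    bins: np.ndarray  # 100 mean depths, 5'->3'
    left_flank: np.ndarray  # 50 per-base depths upstream (5') of the intron
    right_flank: np.ndarray  # 50 per-base depths downstream (3')
    n_introns: int
    size_class: str
    units: str = "raw_depth"

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        self.left_flank = np.asarray(self.left_flank, dtype=float)
        self.right_flank = np.asarray(self.right_flank, dtype=float)
        if (self.bins < 0).any() or (self.left_flank < 0).any() or (self.right_flank < 0).any():
            raise ValueError("negative coverage in profile")


@dataclass(frozen=True)
class SlopeStat:
    """Relative OLS slope of a profile: fractional change per intron length."""

    slope: float
    mean_level: float
    r_squared: float
    zero_coverage: bool = False


def bin_intron(
    intron: IntronRecord,
    track: CoverageTrack,
    nbins: int = 100,
    flank: int = 50,
) -> IntronProfile:
    """Profile one intron: ``nbins`` mean-depth bins plus per-base flanks.

    Bin b covers genomic offsets [floor(b*L/nbins), floor((b+1)*L/nbins)),
    so every base belongs to exactly one bin. For minus-strand introns the
    bin and flank vectors are reversed so index 0 is the transcriptional
    5' end; the 5' flank of a minus-strand intron lies genomically to the
    right.
    """
    iv = intron.interval
    L = iv.length
    if L < nbins:
        raise IntronTooShort(f"intron {iv} of length {L} has fewer bases than {nbins} bins")
    depth = np.asarray(track.depth)
    if iv.start - flank < 0 or iv.end + flank > depth.size:
        raise ValueError(f"flanks of intron {iv} extend outside the reference")
    seg = depth[iv.start : iv.end].astype(float)
    edges = (np.arange(nbins, dtype=np.int64) * L) // nbins
    widths = np.diff(np.append(edges, L))
    bins = np.add.reduceat(seg, edges) / widths
    upstream = depth[iv.start - flank : iv.start].astype(float)
    downstream = depth[iv.end : iv.end + flank].astype(float)
    if iv.strand == "-":
        bins = bins[::-1]
        upstream, downstream = downstream[::-1], upstream[::-1]
    return IntronProfile(
        bins=bins,
        left_flank=upstream,
        right_flank=downstream,
        n_introns=1,
        size_class=intron.size_class,
    )


def aggregate_profiles(
    profiles: Sequence[IntronProfile],
    class_filter: str | None = None,
    normalize: bool = False,
) -> IntronProfile:
    """Elementwise unweighted mean of per-intron profiles.

    ``normalize=True`` rescales each profile by its own bin mean before
    averaging so highly covered introns do not dominate; zero-coverage
    introns then contribute flat zeros.
    """
    selected = [p for p in profiles if class_filter is None or p.size_class == class_filter]
    if not selected:
        raise ValueError(f"no profiles selected (class_filter={class_filter!r})")
    shapes = {(p.bins.size, p.left_flank.size, p.units) for p in selected}
    if len(shapes) > 1:
        raise ValueError("profiles differ in binning or units; cannot aggregate")

    def scaled(p: IntronProfile) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not normalize:
            return p.bins, p.left_flank, p.right_flank
        m = p.bins.mean()
        if m == 0:
            return p.bins, np.zeros_like(p.left_flank), np.zeros_like(p.right_flank)
        return p.bins / m, p.left_flank / m, p.right_flank / m

    stacked = [scaled(p) for p in selected]
    return IntronProfile(
        bins=np.mean([s[0] for s in stacked], axis=0),
        left_flank=np.mean([s[1] for s in stacked], axis=0),
        right_flank=np.mean([s[2] for s in stacked], axis=0),
        n_introns=sum(p.n_introns for p in selected),
        size_class=class_filter or selected[0].size_class,
        units=selected[0].units + ("_normalized" if normalize else ""),
    )


def profile_slope(profile: IntronProfile) -> SlopeStat:
    """OLS slope of bin depth vs fraction of intron traversed, / mean depth.

    A constant profile has slope 0; an all-zero profile is flagged rather
    than divided by zero.
    """
    y = profile.bins
    mean = float(y.mean())
    if mean == 0:
        return SlopeStat(slope=0.0, mean_level=0.0, r_squared=0.0, zero_coverage=True)
    n = y.size
    x = (np.arange(n) + 0.5) / n
    beta, _ = np.polyfit(x, y, 1)
    resid = y - np.polyval(np.polyfit(x, y, 1), x)
    tss = float(((y - mean) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
    return SlopeStat(slope=float(beta) / mean, mean_level=mean, r_squared=r2)


def rank_fractions_by_slope(
    slopes: Sequence[tuple[str, SlopeStat]], use_raw: bool = False
) -> list[str]:
    """Labels ordered steepest (most negative slope) first; ties keep input order.

    The relative slope is scale-invariant, so fractions whose intron signal
    differs only in the *amount* of nascent RNA share the same expected
    relative slope; ``use_raw=True`` ranks by the slope in raw depth units
    (relative slope times mean level), which orders fractions by nascent
    content.
    """
    if len(slopes) < 2:
        raise ValueError("need at least two fractions to rank")

    def key(item: tuple[str, SlopeStat]) -> float:
        stat = item[1]
        return stat.slope * stat.mean_level if use_raw else stat.slope

    return [label for label, _ in sorted(slopes, key=key)]


def profile_size_classes(
    introns: Sequence[IntronRecord],
    coverage: GenomeCoverage,
    nbins: int = 100,
    flank: int = 50,
    normalize: bool = False,
) -> dict[str, tuple[IntronProfile, SlopeStat]]:
    """Aggregate profiles and slopes per size class for one library.

    Introns below the smallest class ('excluded') or shorter than the bin
    count are skipped with a logged reason.
    """
    per_class: dict[str, list[IntronProfile]] = {}
    for intron in introns:
        cls = intron.size_class
        if cls == "excluded":
            log.debug("intron %s skipped: below smallest size class", intron.interval)
            continue
        try:
            iv = intron.interval
            prof = bin_intron(intron, coverage.track(iv.reference_name, iv.strand), nbins, flank)
        except IntronTooShort as exc:
            log.debug("%s", exc)
            continue
        except ValueError as exc:  # flanks outside the reference
            log.debug("intron %s skipped: %s", intron.interval, exc)
            continue
        per_class.setdefault(cls, []).append(prof)
    out = {}
    for cls in SIZE_CLASS_ORDER:
        if cls in per_class:
            agg = aggregate_profiles(per_class[cls], normalize=normalize)
            out[cls] = (agg, profile_slope(agg))
    return out


def gene_body_gradient(
    genes,
    coverage: GenomeCoverage,
    nbins: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed read depth versus fractional position along the gene body.

    Each gene's strand-oriented depth is summed into ``nbins`` equal
    fractions of its span and the sums are added across genes, so every
    gene contributes in proportion to its read count. Under uniform
    polymerase occupancy with no splicing the expectation is linear in
    (1 - x). Returns (bin midpoints as fractions, summed depth).
    """
    agg = np.zeros(nbins)
    for gene in genes:
        iv = gene.interval
        d = coverage.track(iv.reference_name, iv.strand).depth[iv.start : iv.end]
        d = np.asarray(d, dtype=float)
        if iv.strand == "-":
            d = d[::-1]
        edges = (np.arange(nbins, dtype=np.int64) * d.size) // nbins
        agg += np.add.reduceat(d, edges)
    x = (np.arange(nbins) + 0.5) / nbins
    return x, agg


def plot_profiles(
    by_class: Mapping[str, tuple[IntronProfile, SlopeStat]] | Mapping[str, IntronProfile],
    path: str,
    title: str = "",
) -> None:
    """Four-panel (XL/L/M/S) metagene plot with flanks around the bins."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=False)
    for ax, cls in zip(axes.ravel(), SIZE_CLASS_ORDER):
        entry = by_class.get(cls)
        if entry is None:
            ax.set_visible(False)
            continue
        prof = entry[0] if isinstance(entry, tuple) else entry
        nb, nf = prof.bins.size, prof.left_flank.size
        x = np.arange(nf + nb + nf)
        y = np.concatenate([prof.left_flank, prof.bins, prof.right_flank])
        ax.plot(x, y, lw=1)
        ax.axvline(nf - 0.5, ls=":", c="grey")
        ax.axvline(nf + nb - 0.5, ls=":", c="grey")
        ax.set_title(f"{cls} (n={prof.n_introns})", fontsize=9)
        ax.set_ylabel(prof.units, fontsize=8)
        ax.set_xlabel("5' flank | intron bins | 3' flank", fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
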