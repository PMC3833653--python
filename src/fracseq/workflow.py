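"""End-to-end comparison of RNA-fraction libraries over one annotation.

`run_comparison` ties the stages together the way the fractions are
compared in practice: per library it reports the exon/intron read
partition and EI-ratio, expressed-exon counts under per-sample and pooled
antisense cutoffs, and the per-size-class intron profile slope. Outputs
are plain TSV with a commented ``# key=value`` header carrying the full
configuration, so identical inputs and seed give byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .annotation import GeneModel, IntronRecord, collect_introns
from .coverage import AlignedRead, GenomeCoverage, subsample
from .metrics import assign_reads, call_expressed_exons
from .profiles import SIZE_CLASS_ORDER, profile_size_classes

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one comparison run, echoed into every output header."""

    seed: int = 0
    equalize_depth: bool = False
    percentile: float = 99.0
    count_mode: str = "exon-priority"
    nbins: int = 100
    flank: int = 50
    normalize_profiles: bool = False
    exclude_exon_overlaps: bool = True
    extra: dict = field(default_factory=dict)

    def items(self) -> list[tuple[str, object]]:
        out = [
            ("fracseq_version", __version__),
            ("seed", self.seed),
            ("equalize_depth", self.equalize_depth),
            ("percentile", self.percentile),
            ("count_mode", self.count_mode),
            ("nbins", self.nbins),
            ("flank", self.flank),
            ("normalize_profiles", self.normalize_profiles),
            ("exclude_exon_overlaps", self.exclude_exon_overlaps),
        ]
        out.extend(sorted(self.extra.items()))
        return out


def write_tsv(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """TSV with a '# key=value' header block, deterministic formatting."""
    with open(path, "w") as fh:
        for key, value in config.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run_comparison(
    samples: Sequence[tuple[str, Sequence[AlignedRead]]],
    genes: Sequence[GeneModel],
    reference_lengths: Mapping[str, int],
    outdir: str | Path,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Compare libraries: EI-ratio, expressed exons, intron slopes per sample.

    Writes ``comparison.tsv`` plus one ``profile_<label>.tsv`` per sample
    under ``outdir`` and returns the comparison table. With
    ``equalize_depth`` every library is first down-sampled to the smallest
    library's read count so the fractions are compared at equal depth.
    """
    config = config or RunConfig()
    if not samples:
        raise ValueError("no samples supplied")
    for label, reads in samples:
        if len(reads) == 0:
            raise ValueError(f"sample {label!r}: empty alignment set")
        for read in reads:
            if read.reference_name not in reference_lengths:
                raise ValueError(
                    f"sample {label!r}: read {read.read_id} on reference "
                    f"{read.reference_name!r} absent from the annotation's namespace"
                )
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")

    if config.equalize_depth:
        floor = min(len(reads) for _, reads in samples)
        samples = [
            (label, subsample(list(reads), floor, config.seed)) for label, reads in samples
        ]
        log.info("equalized all libraries to %d reads", floor)

    introns: list[IntronRecord] = collect_introns(
        genes, exclude_exon_overlaps=config.exclude_exon_overlaps
    )
    exons = [ex for g in genes for ex in g.exons]
    coverages = {
        label: GenomeCoverage.from_reads(list(reads), dict(reference_lengths))
        for label, reads in samples
    }

    per_sample_calls = call_expressed_exons(
        exons, [(label, coverages[label]) for label, _ in samples], mode="per_sample",
        percentile=config.percentile,
    )
    pooled_calls = None
    if len(samples) >= 2:
        pooled_calls = call_expressed_exons(
            exons, [(label, coverages[label]) for label, _ in samples], mode="pooled",
            percentile=config.percentile,
        )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (label, reads) in enumerate(samples):
        ei = assign_reads(list(reads), genes, count_mode=config.count_mode)
        by_class = profile_size_classes(
            introns,
            coverages[label],
            nbins=config.nbins,
            flank=config.flank,
            normalize=config.normalize_profiles,
        )
        row = {
            "sample": label,
            "total_reads": len(reads),
            "E": ei.E,
            "I": ei.I,
            "unassigned": ei.unassigned,
            "ei_ratio": ei.ei_ratio if ei.E + ei.I else float("nan"),
            "expressed_exons": per_sample_calls[i].n_expressed,
            "expressed_cutoff": per_sample_calls[i].cutoff,
            "expressed_exons_pooled": pooled_calls[i].n_expressed if pooled_calls else None,
            "pooled_cutoff": pooled_calls[i].cutoff if pooled_calls else None,
        }
        for cls in SIZE_CLASS_ORDER:
            entry = by_class.get(cls)
            row[f"slope_{cls}"] = entry[1].slope if entry else float("nan")
            row[f"n_introns_{cls}"] = entry[0].n_introns if entry else 0
        rows.append(row)
        _write_profiles(by_class, outdir / f"profile_{label}.tsv", config)
    table = pd.DataFrame(rows)
    write_tsv(table, outdir / "comparison.tsv", config)
    return table


def _write_profiles(by_class, path: Path, config: RunConfig) -> None:
    rows = []
    for cls, (prof, slope) in by_class.items():
        for kind, values in (
            ("left_flank", prof.left_flank),
            ("bins", prof.bins),
            ("right_flank", prof.right_flank),
        ):
            for idx, v in enumerate(values):
                rows.append(
                    {
                        "size_class": cls,
                        "segment": kind,
                        "index": idx,
                        "mean_depth": v,
                        "n_introns": prof.n_introns,
                        "slope": slope.slope,
                    }
                )
    write_tsv(pd.DataFrame(rows), path, config)
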