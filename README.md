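# fracseq

Compare subcellular RNA-seq fractions — cytoplasmic, nuclear, total,
polyA+ — by how much mature versus nascent RNA they contain.

Bulk RNA-seq of total or polyA-selected RNA carries substantial intronic
signal from incompletely spliced transcripts, especially over long,
highly expressed genes; sequencing the cytoplasmic fraction enriches
mature mRNA, while the nuclear fraction enriches nascent RNA and its
co-transcriptional splicing signatures. `fracseq` implements the
computations used to quantify these differences from stranded alignments
(SAM/BAM or BED12) and a gene annotation (GTF or BED12):

* **EI-ratio** — reads overlapping exons (E) and introns (I) of
  same-strand genes, summarized as E/(E+I): 1 when all intragenic reads
  are exonic, 0 when all are intronic.
* **Expressed-exon detection** — per-exon expression in dcpm (average
  depth of coverage per million mapped reads), thresholded at the 99th
  percentile (nearest rank) of the dcpm of the same exon coordinates on
  the **antisense** strand, an empirical noise null; cutoffs per sample
  or pooled.
* **Intron metagene profiles** — each intron split into 100 bins with
  50 bp per-base flanks, oriented 5'→3' and averaged within size
  classes S [1,10) kb, M [10,50) kb, L [50,100) kb, XL ≥ 100 kb, with a
  relative OLS slope statistic quantifying the declining 5'→3' coverage
  gradient that nascent transcription leaves across long introns.
* **A generative simulator** — stranded 75 bp single-end reads from a
  mixture of mature molecules and nascent molecules with
  distance-dependent co-transcriptional intron excision
  (retention probability `exp(-d/λ)` at distance `d` past an intron's
  3' end), plus full-length polyA-retained molecules. Ground-truth
  labels make every stage testable, and the mixture identity
  `EI = m + (1-m)·e_n` lets the mature fraction `m` be recovered from
  an observed EI-ratio.

## Worked example

Simulate a nuclear-like library and measure it:

```bash
fracseq simulate --preset nuclear --n-reads 30000 --seed 1 --out-dir sim/
fracseq ei sim/alignments.bed12 sim/annotation.bed12 --out ei.tsv
```

The analysis scripts under `analysis/` run the full comparison on four
simulated fraction libraries (30,000 reads each over a 60-gene, 9.5 Mb
synthetic genome). `python analysis/02_ei_ratios.py` prints:

```
   fraction  total_reads     E     I  unassigned  ei_ratio
cytoplasmic        30000 28608  1392           0    0.9536
    nuclear        30000  3801 26199           0    0.1267
      total        30000  8280 21720           0    0.2760
      polyA        30000  9722 20278           0    0.3241
EI-ratio ranking (exon-richest first): cytoplasmic > polyA > total > nuclear
```

The cytoplasmic library is almost purely exonic (EI-ratio 0.95) while
the nuclear library is dominated by intronic reads from nascent
transcripts (0.13), with total and polyA+ in between — the ordering that
motivates sequencing cytoplasmic RNA for mRNA quantification and nuclear
RNA for transcription dynamics. `analysis/04_intron_profiles.py` shows
the matching coverage gradients (nuclear XL-intron slope −1.81 per
intron length, r² 0.97; cytoplasmic intron coverage near zero), and
`analysis/05_mature_fraction_recovery.py` inverts the EI-ratios to
recover the simulated mature fraction with mean absolute error 0.001:

```
 true_m  observed_ei  estimated_m  abs_error
    0.1       0.1169       0.1012     0.0012
    0.5       0.5105       0.5018     0.0018
    0.9       0.9020       0.9002     0.0002
```

## Layout

```
src/fracseq/    library: annotation, coverage, metrics, profiles,
                simulate, workflow, cli
analysis/       numbered narrative drivers writing tables to results/
tests/          pytest suite (unit, property and end-to-end checks)
docs/methods.md model, parameters, design choices, limitations
```

See `docs/methods.md` for the model and its assumptions, what the
simulator does and does not emulate, and the numerical conventions
(nearest-rank percentiles, strict thresholds, floor bin edges) that make
runs byte-reproducible.
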