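"""Shared study conditions for the numbered analysis scripts.

One synthetic genome (60 genes, introns spanning all four size classes)
and four RNA-fraction libraries of 30,000 stranded 75 bp reads each,
generated from the mixture presets. Every script regenerates what it
needs from these conditions so it can run standalone.
"""

from pathlib import Path

from fracseq import SimulationConfig, preset_config, simulate_genome, simulate_reads

GENOME_SEED = 11
READ_SEED = 1
N_READS = 30_000
FRACTIONS = ("cytoplasmic", "nuclear", "total", "polyA")

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def study_genome():
    config = SimulationConfig(seed=GENOME_SEED)
    genes, ref_lengths = simulate_genome(config)
    return config, genes, ref_lengths


def fraction_libraries(genes, n_reads=N_READS, seed=READ_SEED):
    """(label, reads, truth) per fraction preset."""
    out = []
    for name in FRACTIONS:
        cfg = preset_config(name, n_reads=n_reads, seed=seed)
        reads, truth = simulate_reads(cfg, genes)
        out.append((name, reads, truth))
    return out
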