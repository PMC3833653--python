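import numpy as np
import pytest

from fracseq import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def default_genome():
    """One synthetic genome shared across tests (annotation only)."""
    config = SimulationConfig(seed=11)
    genes, ref_lengths = simulate_genome(config)
    return config, genes, ref_lengths


def brute_force_depth(reads, reference_length, strand):
    """Per-base coverage by iterating every base of every block."""
    depth = np.zeros(reference_length, dtype=int)
    for read in reads:
        if read.strand != strand:
            continue
        for s, e in read.blocks:
            for x in range(s, e):
                depth[x] += 1
    return depth


def random_reads(rng, n, reference_length, read_length=75, spliced_fraction=0.3):
    """Random single-end reads, a fraction spliced into two blocks."""
    from fracseq import AlignedRead

    reads = []
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, reference_length - 10 * read_length))
        if rng.random() < spliced_fraction:
            half = read_length // 2
            gap = int(rng.integers(50, 500))
            blocks = ((start, start + half), (start + half + gap, start + read_length + gap))
        else:
            blocks = ((start, start + read_length),)
        reads.append(AlignedRead("ref", blocks, strand, f"q{i}"))
    return reads
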