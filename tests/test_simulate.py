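import numpy as np
import pandas as pd
import pytest

from fracseq import (
    GeneModel,
    GenomeCoverage,
    SimulationConfig,
    assign_reads,
    collect_introns,
    estimate_mature_fraction,
    expected_nascent_exonic_fraction,
    preset_config,
    simulate_genome,
    simulate_reads,
    size_class,
)


class TestSimulateGenome:
    def test_single_gene_two_exons_one_intron(self):
        cfg = SimulationConfig(n_genes=1, exon_count_range=(2, 2), seed=5)
        genes, ref_lengths = simulate_genome(cfg)
        assert len(genes) == 1
        assert len(genes[0].introns) == 1
        assert ref_lengths[cfg.reference_name] >= genes[0].interval.end

    def test_same_seed_identical_annotation(self):
        cfg = SimulationConfig(seed=3)
        assert simulate_genome(cfg)[0] == simulate_genome(cfg)[0]

    def test_all_size_classes_represented(self):
        cfg = SimulationConfig(n_genes=200, seed=4)
        genes, _ = simulate_genome(cfg)
        classes = {
            size_class(b.start - a.end)
            for g in genes
            for a, b in zip(g.exons, g.exons[1:])
        }
        assert {"S", "M", "L", "XL"} <= classes

    def test_genes_do_not_overlap(self):
        genes, _ = simulate_genome(SimulationConfig(seed=6))
        spans = sorted((g.interval.start, g.interval.end) for g in genes)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_fixed_reference_too_small_rejected(self):
        cfg = SimulationConfig(n_genes=10, reference_length=1_000, seed=0)
        with pytest.raises(ValueError, match="reference_length"):
            simulate_genome(cfg)


class TestSimulateReads:
    def test_determinism(self, default_genome):
        _, genes, _ = default_genome
        cfg = SimulationConfig(n_reads=5_000, mature_fraction=0.4, seed=9)
        r1, t1 = simulate_reads(cfg, genes)
        r2, t2 = simulate_reads(cfg, genes)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1.reads, t2.reads)

    def test_pure_mature_blocks_lie_in_exons(self, default_genome):
        _, genes, _ = default_genome
        cfg = SimulationConfig(n_reads=10_000, mature_fraction=1.0, seed=10)
        reads, truth = simulate_reads(cfg, genes)
        exon_sets = {}
        for g in genes:
            exon_sets[g.gene_id] = [(e.start, e.end) for e in g.exons]
        gene_of = dict(zip(truth.reads["read_id"], truth.reads["gene_id"]))
        for read in reads:
            exons = exon_sets[gene_of[read.read_id]]
            for s, e in read.blocks:
                assert any(es <= s and e <= ee for es, ee in exons)
        assert assign_reads(reads, genes).I == 0

    def test_class_proportions_converge(self, default_genome):
        _, genes, _ = default_genome
        cfg = SimulationConfig(
            n_reads=30_000, mature_fraction=0.5, polya_retention=0.2, seed=12
        )
        _, truth = simulate_reads(cfg, genes)
        frac = truth.class_fractions()
        assert frac["mature"] == pytest.approx(0.5, abs=0.02)
        assert frac["polyA_retained"] == pytest.approx(0.2, abs=0.02)
        assert frac["nascent"] == pytest.approx(0.3, abs=0.02)

    def test_read_lengths_honoured(self, default_genome):
        _, genes, _ = default_genome
        cfg = SimulationConfig(n_reads=2_000, mature_fraction=0.3, seed=13)
        reads, _ = simulate_reads(cfg, genes)
        assert all(r.aligned_length == cfg.read_length for r in reads)

    def test_instant_splicing_intron_coverage_tracks_occupancy_window(self):
        # Single gene, one intron: with lam -> 0 an intron position x is
        # covered only while the polymerase sits between x and the intron's
        # 3' end, so depth is linear in (intron_end - x).
        gene_cfg = SimulationConfig(
            n_genes=1,
            exon_count_range=(2, 2),
            exon_length_range=(300, 300),
            intron_length_range=(6_000, 6_001),
            splicing_half_distance=1e-9,
            mature_fraction=0.0,
            n_reads=150_000,
            seed=14,
        )
        genes, ref_lengths = simulate_genome(gene_cfg)
        reads, _ = simulate_reads(gene_cfg, genes)
        cov = GenomeCoverage.from_reads(reads, ref_lengths)
        (intron,) = collect_introns(genes)
        iv = intron.interval
        d = cov.track(iv.reference_name, iv.strand).depth[iv.start : iv.end].astype(float)
        if iv.strand == "-":
            d = d[::-1]
        trimmed = d[100:-100]  # avoid read-length edge effects
        expected = np.arange(trimmed.size, 0, -1, dtype=float)
        assert np.corrcoef(trimmed, expected)[0, 1] > 0.98


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mature_fraction": 1.2},
            {"mature_fraction": 0.8, "polya_retention": 0.4},
            {"splicing_half_distance": 0.0},
            {"read_length": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            preset_config("mitochondrial")


class TestMatureFractionEstimator:
    def test_trivial_inversions(self):
        assert estimate_mature_fraction(1.0, 0.05) == pytest.approx(1.0)
        assert estimate_mature_fraction(0.05, 0.05) == pytest.approx(0.0)

    def test_unidentifiable_and_clamped(self):
        with pytest.raises(ValueError):
            estimate_mature_fraction(0.9, 1.0)
        with pytest.warns(UserWarning):
            assert estimate_mature_fraction(0.01, 0.05) == 0.0

    def test_intronless_annotation_gives_en_one(self):
        gene = GeneModel.from_exons("flat", "chrS", "+", [(1_000, 9_000)])
        cfg = SimulationConfig(n_genes=1, seed=2)
        e_n, se = expected_nascent_exonic_fraction(cfg, [gene], n=2_000)
        assert e_n == 1.0

    def test_two_independent_monte_carlo_estimates_agree(self, default_genome):
        config, genes, _ = default_genome
        cfg = SimulationConfig(seed=31, splicing_half_distance=10_000.0)
        e_n, se = expected_nascent_exonic_fraction(cfg, genes, n=40_000)
        # independent second estimate through the ordinary read generator,
        # which draws from a different random stream of the same seed
        reads, _ = simulate_reads(
            SimulationConfig(
                seed=31,
                splicing_half_distance=10_000.0,
                mature_fraction=0.0,
                n_reads=40_000,
            ),
            genes,
        )
        res = assign_reads(reads, genes)
        e_n2 = res.E / (res.E + res.I)
        se2 = np.sqrt(e_n2 * (1 - e_n2) / (res.E + res.I))
        assert abs(e_n - e_n2) < 3 * np.sqrt(se**2 + se2**2) + 1e-9

    def test_recovery_loop_at_m_07(self, default_genome):
        _, genes, _ = default_genome
        cfg = SimulationConfig(n_reads=100_000, mature_fraction=0.7, seed=33)
        reads, _ = simulate_reads(cfg, genes)
        ei = assign_reads(reads, genes).ei_ratio
        e_n, _ = expected_nascent_exonic_fraction(cfg, genes, n=100_000)
        m_hat = estimate_mature_fraction(ei, e_n)
        assert abs(m_hat - 0.7) < 0.02
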