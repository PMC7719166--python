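"""Synthetic study generator: determinism, planted-signal fidelity, SAM validity."""

import numpy as np
import pysam
import pytest

from methsplice.annotation import GenomeAnnotation
from methsplice.genome import find_cpg_sites
from methsplice.annotation import write_gtf
from methsplice.simulate import (ConfigurationError, DmrSpec, SyntheticConfig,
                                 SyntheticTruth, make_genome_and_annotation,
                                 simulate_bisulfite_reads, simulate_expression,
                                 simulate_junction_reads)


class TestGenomeGeneration:
    def test_deterministic_outputs(self, tmp_path):
        cfg = SyntheticConfig(n_genes=5, seed=7, dmr_spec=[DmrSpec(300, -0.4)])
        files = []
        for run in ("a", "b"):
            genome, genes, truth = make_genome_and_annotation(cfg)
            fa = tmp_path / f"{run}.fa"
            gtf = tmp_path / f"{run}.gtf"
            genome.to_fasta(fa)
            write_gtf(genes, gtf)
            files.append((fa.read_bytes(), gtf.read_bytes()))
        assert files[0] == files[1]

    def test_planted_gene_body_dmrs_are_gene_body(self):
        cfg = SyntheticConfig(n_genes=5, seed=3,
                              dmr_spec=[DmrSpec(300, -0.4)] * 3)
        genome, genes, truth = make_genome_and_annotation(cfg)
        ann = GenomeAnnotation(genes, {cfg.chrom: truth.genome_length})
        for dmr in truth.dmrs:
            labels = {ann.classify(cfg.chrom, p)
                      for p in range(dmr.interval.start, dmr.interval.end, 11)}
            assert labels <= {"exon", "intron"}

    def test_cpg_density_higher_in_genes_than_intergenic(self):
        cfg = SyntheticConfig(n_genes=5, seed=9)
        genome, genes, truth = make_genome_and_annotation(cfg)
        seq = genome.sequences[cfg.chrom]
        genic = np.zeros(len(seq), dtype=bool)
        for g in genes:
            genic[g.start:g.end] = True
        cpg = np.zeros(len(seq), dtype=bool)
        cpg[find_cpg_sites(seq)] = True
        dens_genic = cpg[genic].mean()
        dens_inter = cpg[~genic].mean()
        assert dens_genic > 2 * dens_inter

    def test_infeasible_dmr_is_config_error(self):
        cfg = SyntheticConfig(n_genes=2, seed=0,
                              dmr_spec=[DmrSpec(10 ** 6, -0.4)])
        with pytest.raises(ConfigurationError, match="does not fit"):
            make_genome_and_annotation(cfg)

    def test_ko_target_mean_calibration(self):
        cfg = SyntheticConfig(n_genes=5, seed=2, wt_mcg=0.769,
                              ko_target_mean=0.664,
                              dmr_spec=[DmrSpec(400, -0.4)] * 2)
        _, _, truth = make_genome_and_annotation(cfg)
        assert truth.mean_mcg("ko") == pytest.approx(0.664, abs=1e-9)
        assert truth.mean_mcg("wt") == pytest.approx(0.769, abs=1e-9)

    def test_truth_json_round_trip(self, tmp_path):
        cfg = SyntheticConfig(n_genes=3, seed=4, dmr_spec=[DmrSpec(300, -0.3)])
        _, _, truth = make_genome_and_annotation(cfg)
        truth.skip_rates["gene1_e3"] = 0.3
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert np.array_equal(back.cpg_positions, truth.cpg_positions)
        assert np.allclose(back.ko_prob, truth.ko_prob)
        assert back.gene_dmr_length == truth.gene_dmr_length
        assert [d.interval for d in back.dmrs] == [d.interval for d in truth.dmrs]


class TestBisulfiteReads:
    @pytest.mark.parametrize("m,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_full_conversion_extremes(self, tmp_path, m, expected):
        cfg = SyntheticConfig(n_genes=2, seed=1, wt_mcg=m,
                              conversion_efficiency=1.0, bisulfite_coverage=10)
        genome, _, truth = make_genome_and_annotation(cfg)
        sam = tmp_path / "r.sam"
        simulate_bisulfite_reads(genome, truth, "wt", cfg, sam)
        from methsplice.methylation import call_methylation, global_mcg_percent
        track = call_methylation(sam, genome, min_coverage=1)
        assert global_mcg_percent(track) == pytest.approx(100 * expected)

    def test_site_fraction_within_binomial_tolerance(self, tmp_path):
        """At depth ~1000 a 0.6-methylated site reads C at a frequency
        within 3 binomial SEs of 0.6."""
        cfg = SyntheticConfig(n_genes=2, seed=12, wt_mcg=0.6,
                              conversion_efficiency=1.0,
                              bisulfite_coverage=1000, read_length=100)
        genome, _, truth = make_genome_and_annotation(cfg)
        sam = tmp_path / "deep.sam"
        simulate_bisulfite_reads(genome, truth, "wt", cfg, sam,
                                 np.random.default_rng(99))
        from methsplice.methylation import call_methylation
        track = call_methylation(sam, genome, min_coverage=100)
        mid = track.n_sites() // 2
        site = list(track.sites())[mid]
        se = np.sqrt(0.6 * 0.4 / site.n_total)
        assert abs(site.level - 0.6) < 3 * se

    def test_reads_match_fasta_coordinates(self, tmp_path):
        cfg = SyntheticConfig(n_genes=2, seed=8, bisulfite_coverage=5)
        genome, _, truth = make_genome_and_annotation(cfg)
        sam = tmp_path / "r.sam"
        simulate_bisulfite_reads(genome, truth, "wt", cfg, sam)
        L = truth.genome_length
        with pysam.AlignmentFile(str(sam)) as af:
            assert af.get_reference_length(cfg.chrom) == L
            for read in af:
                assert 0 <= read.reference_start
                assert read.reference_end <= L
                # non-C positions are copied verbatim from the reference
                ref = genome.sequences[cfg.chrom][
                    read.reference_start:read.reference_end]
                for rb, qb in zip(ref, read.query_sequence):
                    if rb not in "CG":
                        assert rb == qb

    def test_bad_coverage_is_error(self, tmp_path):
        cfg = SyntheticConfig(n_genes=2, seed=1)
        genome, _, truth = make_genome_and_annotation(cfg)
        cfg.bisulfite_coverage = 0
        with pytest.raises(ConfigurationError):
            simulate_bisulfite_reads(genome, truth, "wt", cfg, tmp_path / "x.sam")


@pytest.fixture(scope="module")
def gene():
    cfg = SyntheticConfig(n_genes=1, seed=5)
    _, genes, _ = make_genome_and_annotation(cfg)
    return cfg, genes[0]


class TestJunctionReads:
    @pytest.mark.parametrize("rate", [0.0, 1.0])
    def test_extreme_rates(self, tmp_path, gene, rate):
        cfg, g = gene
        labels = simulate_junction_reads(g, 3, rate, 300, cfg,
                                         tmp_path / "r.sam",
                                         np.random.default_rng(1))
        informative = labels[labels.label != "decoy"]
        n_skip = (informative.label == "skip").sum()
        assert n_skip == (0 if rate == 0.0 else len(informative))

    def test_skip_fraction_binomial(self, tmp_path, gene):
        cfg, g = gene
        labels = simulate_junction_reads(g, 3, 0.3, 2000, cfg,
                                         tmp_path / "r.sam",
                                         np.random.default_rng(2))
        informative = labels[labels.label != "decoy"]
        frac = (informative.label == "skip").mean()
        se = np.sqrt(0.3 * 0.7 / len(informative))
        assert abs(frac - 0.3) < 3 * se

    def test_split_blocks_match_exon_boundaries(self, tmp_path, gene):
        cfg, g = gene
        simulate_junction_reads(g, 3, 0.5, 200, cfg, tmp_path / "r.sam",
                                np.random.default_rng(3))
        starts = {e.start for e in g.exons}
        ends = {e.end for e in g.exons}
        with pysam.AlignmentFile(str(tmp_path / "r.sam"), check_sq=False) as af:
            for read in af:
                if "decoy" in read.query_name:
                    continue
                blocks = read.get_blocks()
                for (b1s, b1e), (b2s, b2e) in zip(blocks, blocks[1:]):
                    assert b1e in ends and b2s in starts

    def test_terminal_exon_is_error(self, tmp_path, gene):
        cfg, g = gene
        for idx in (0, len(g.exons) - 1):
            with pytest.raises(ValueError, match="internal"):
                simulate_junction_reads(g, idx, 0.2, 10, cfg, tmp_path / "x.sam")


class TestExpression:
    def test_zero_coupling_zero_noise_gives_zero_fc(self):
        cfg = SyntheticConfig(n_genes=4, seed=1, fc_coupling=0.0, noise_sd=0.0)
        df = simulate_expression({"g1": 0, "g2": 500, "g3": 1200}, cfg)
        assert np.allclose(np.log2(df.value_ko / df.value_wt), 0.0)

    def test_noiseless_fc_increases_with_length(self):
        cfg = SyntheticConfig(n_genes=4, seed=1, fc_coupling=0.002, noise_sd=0.0)
        lengths = {"g1": 100, "g2": 400, "g3": 900, "g4": 1600}
        df = simulate_expression(lengths, cfg)
        fc = np.log2(df.value_ko / df.value_wt).to_numpy()
        assert np.all(np.diff(fc) > 0)
        assert np.allclose(fc, 0.002 * np.array([100, 400, 900, 1600]))

    def test_emitted_table_carries_positive_correlation(self):
        cfg = SyntheticConfig(n_genes=4, seed=21, fc_coupling=0.001, noise_sd=0.5)
        rng = np.random.default_rng(21)
        lengths = {f"g{i}": int(rng.integers(50, 2000)) for i in range(400)}
        df = simulate_expression(lengths, cfg, rng)
        fc = np.log2(df.value_ko / df.value_wt)
        r = np.corrcoef(df.gene_id.map(lengths), fc)[0, 1]
        assert r > 0.3
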