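"""Methylation calling: retained-C frequency, strand folding, summaries."""

import numpy as np
import pysam
import pytest

from methsplice.genome import ReferenceGenome
from methsplice.intervals import GenomicInterval
from methsplice.methylation import (MethylomeTrack, call_methylation,
                                    global_mcg_percent, read_bedgraph,
                                    region_mean_level, write_bedgraph)
from methsplice.simulate import SyntheticConfig, make_genome_and_annotation, simulate_bisulfite_reads


def write_sam(path, chrom, chrom_len, records):
    """records: (name, flag, pos, seq) with a pure-match CIGAR."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": chrom_len}]})
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, flag, pos, seq in records:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = [(0, len(seq))]
            a.query_sequence = seq
            out.write(a)


class TestCallMethylation:
    def test_retained_c_frequency(self, tmp_path, tiny_genome):
        # 4 forward reads over the single CpG (pos 2): C,C,C,T -> 0.75
        sam = tmp_path / "r.sam"
        write_sam(sam, "chr1", 6, [
            ("r1", 0, 0, "AACGTT"), ("r2", 0, 0, "AACGTT"),
            ("r3", 0, 0, "AACGTT"), ("r4", 0, 0, "AATGTT"),
        ])
        track = call_methylation(sam, tiny_genome, min_coverage=4)
        site = next(track.sites())
        assert (site.pos, site.n_methylated, site.n_total) == (2, 3, 4)
        assert site.level == 0.75

    def test_all_converted_gives_zero(self, tmp_path, tiny_genome):
        sam = tmp_path / "r.sam"
        write_sam(sam, "chr1", 6, [(f"r{i}", 0, 0, "AATGTT") for i in range(4)])
        track = call_methylation(sam, tiny_genome, min_coverage=4)
        assert next(track.sites()).level == 0.0

    def test_strand_folding_onto_plus_c(self, tmp_path, tiny_genome):
        """2 forward reads (C,T) + 2 reverse reads (G,A at the CpG's G)
        fold to level 0.5 with n_total 4 at the plus-strand C position."""
        sam = tmp_path / "r.sam"
        write_sam(sam, "chr1", 6, [
            ("f1", 0, 0, "AACGTT"),   # retained C
            ("f2", 0, 0, "AATGTT"),   # converted C>T
            ("m1", 16, 0, "AACGTT"),  # retained G (minus-strand C)
            ("m2", 16, 0, "AACATT"),  # converted G>A
        ])
        track = call_methylation(sam, tiny_genome, min_coverage=4)
        site = next(track.sites())
        assert (site.pos, site.n_methylated, site.n_total) == (2, 2, 4)
        assert site.level == 0.5

    def test_anomalous_bases_are_uninformative(self, tmp_path, tiny_genome):
        # a G on a forward read at the C position is neither C nor T
        sam = tmp_path / "r.sam"
        write_sam(sam, "chr1", 6, [
            ("r1", 0, 0, "AACGTT"), ("r2", 0, 0, "AACGTT"),
            ("r3", 0, 0, "AACGTT"), ("r4", 0, 0, "AATGTT"),
            ("bad", 0, 0, "AAGGTT"),
        ])
        track = call_methylation(sam, tiny_genome, min_coverage=4)
        site = next(track.sites())
        assert (site.n_methylated, site.n_total) == (3, 4)

    def test_unknown_chromosome_is_error(self, tmp_path, tiny_genome):
        sam = tmp_path / "r.sam"
        write_sam(sam, "chrX", 6, [("r1", 0, 0, "AACGTT")])
        with pytest.raises(ValueError, match="unknown chromosome"):
            call_methylation(sam, tiny_genome)

    def test_min_coverage_gates_sites(self, tmp_path, tiny_genome):
        sam = tmp_path / "r.sam"
        write_sam(sam, "chr1", 6, [("r1", 0, 0, "AACGTT")])
        with pytest.warns(UserWarning, match="no CpG site"):
            track = call_methylation(sam, tiny_genome, min_coverage=4)
        assert track.n_sites() == 0
        track = call_methylation(sam, tiny_genome, min_coverage=1)
        assert track.n_sites() == 1


class TestSummaries:
    def test_global_mcg_is_call_weighted(self, make_track):
        track = MethylomeTrack.from_arrays({"chr1": (
            np.array([10, 20]), np.array([10, 0]), np.array([10, 10]))})
        assert global_mcg_percent(track) == 50.0

    def test_single_site(self):
        track = MethylomeTrack.from_arrays({"chr1": (
            np.array([5]), np.array([3]), np.array([4]))})
        assert global_mcg_percent(track) == 75.0

    def test_empty_track_is_error(self):
        with pytest.raises(ValueError, match="empty track"):
            global_mcg_percent(MethylomeTrack())

    def test_chromosome_order_invariance(self):
        data = {"chr2": (np.array([1]), np.array([1]), np.array([2])),
                "chr1": (np.array([3]), np.array([4]), np.array([8]))}
        a = MethylomeTrack.from_arrays(data)
        b = MethylomeTrack.from_arrays(dict(reversed(list(data.items()))))
        assert global_mcg_percent(a) == global_mcg_percent(b)

    def test_region_mean_is_site_weighted(self, make_track):
        track = make_track([100, 200], [1.0, 0.5], coverage=20)
        assert region_mean_level(track, GenomicInterval("chr1", 0, 300)) == 0.75

    def test_region_without_cpg_is_nan(self, make_track):
        track = make_track([100], [1.0])
        assert np.isnan(region_mean_level(track, GenomicInterval("chr1", 500, 600)))


class TestBedgraphIO:
    def test_round_trip_levels_and_counts(self, tmp_path):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(10000, 100, replace=False))
        total = rng.integers(4, 40, 100)
        meth = rng.binomial(total, 0.7)
        track = MethylomeTrack.from_arrays({"chr1": (pos, meth, total)}, sample="x")
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, path)
        back = read_bedgraph(path)
        assert np.array_equal(back.positions["chr1"], pos)
        assert np.array_equal(back.n_methylated["chr1"], meth)
        assert np.array_equal(back.n_total["chr1"], total)
        assert np.allclose(back.levels("chr1"), track.levels("chr1"))

    def test_empty_track_writes_header_only(self, tmp_path):
        path = tmp_path / "e.bedgraph"
        write_bedgraph(MethylomeTrack("empty"), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")

    def test_overlapping_records_error(self, tmp_path):
        path = tmp_path / "o.bedgraph"
        path.write_text("chr1\t10\t11\t0.5\t1\t2\nchr1\t10\t11\t0.5\t1\t2\n")
        with pytest.raises(ValueError, match="overlapping or unsorted"):
            read_bedgraph(path)


class TestEstimatorConsistency:
    def test_error_shrinks_with_depth(self, tmp_path):
        """Mean per-site absolute error shrinks roughly like 1/sqrt(depth)."""
        errs = {}
        for depth in (10, 90):
            cfg = SyntheticConfig(n_genes=2, seed=5, bisulfite_coverage=depth,
                                  conversion_efficiency=1.0, wt_mcg=0.6)
            genome, _, truth = make_genome_and_annotation(cfg)
            sam = tmp_path / f"d{depth}.sam"
            simulate_bisulfite_reads(genome, truth, "wt", cfg, sam,
                                     np.random.default_rng(depth))
            track = call_methylation(sam, genome, min_coverage=4)
            pos = track.positions["chr1"]
            idx = np.searchsorted(truth.cpg_positions, pos)
            errs[depth] = np.abs(track.levels("chr1") - truth.wt_prob[idx]).mean()
        # 9x depth -> ~3x error reduction; allow generous slack
        assert errs[90] < errs[10] / 1.8

    def test_both_strand_calling_matches_plus_only(self, tmp_path):
        """Folding reverse-strand G/A calls reproduces the same levels in
        expectation as plus-only calling of the same methylome."""
        est = {}
        for both in (False, True):
            cfg = SyntheticConfig(n_genes=2, seed=6, bisulfite_coverage=60,
                                  conversion_efficiency=1.0, wt_mcg=0.55,
                                  both_strands=both)
            genome, _, truth = make_genome_and_annotation(cfg)
            sam = tmp_path / f"b{both}.sam"
            simulate_bisulfite_reads(genome, truth, "wt", cfg, sam,
                                     np.random.default_rng(17))
            track = call_methylation(sam, genome, min_coverage=4)
            est[both] = global_mcg_percent(track)
        assert est[True] == pytest.approx(est[False], abs=1.0)
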