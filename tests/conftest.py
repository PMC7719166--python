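import numpy as np
import pytest

from methsplice.annotation import GeneModel, GenomeAnnotation
from methsplice.genome import ReferenceGenome
from methsplice.intervals import GenomicInterval
from methsplice.methylation import MethylomeTrack
from methsplice.simulate import DmrSpec, SyntheticConfig, make_genome_and_annotation


@pytest.fixture(scope="session")
def toy_two_genes():
    """Two hand-placed genes on a 30 kb chromosome, one per strand.

    geneA (+): exons (5000-5400, 6000-6400, 7000-7400, 8000-8400),
    CDS 5200-8200. geneB (-): exons (15000-15400, 16000-16400,
    17000-17400, 18000-18400), CDS 15200-18200 (promoter 18401-20401).
    """
    def mk(gene_id, strand, starts, cds):
        exons = [GenomicInterval("chr1", s, s + 400, strand) for s in starts]
        return GeneModel(gene_id, "chr1", strand, exons, cds[0], cds[1])

    gene_a = mk("geneA", "+", [5000, 6000, 7000, 8000], (5200, 8200))
    gene_b = mk("geneB", "-", [15000, 16000, 17000, 18000], (15200, 18200))
    return [gene_a, gene_b]


@pytest.fixture(scope="session")
def toy_annotation(toy_two_genes):
    return GenomeAnnotation(toy_two_genes, {"chr1": 30000})


@pytest.fixture(scope="session")
def small_study():
    """A 4-gene genome with two planted gene-body DMRs (no background shift)."""
    cfg = SyntheticConfig(
        n_genes=4, seed=11, wt_mcg=0.77, ko_background_mcg=0.77,
        dmr_spec=[DmrSpec(400, -0.40), DmrSpec(600, -0.40)],
    )
    genome, genes, truth = make_genome_and_annotation(cfg)
    return cfg, genome, genes, truth


def track_from_levels(positions, levels, coverage=20, chrom="chr1", sample="s"):
    """A MethylomeTrack with exact integer counts realising given levels."""
    positions = np.asarray(positions, dtype=np.int64)
    levels = np.asarray(levels, dtype=float)
    meth = np.rint(levels * coverage).astype(np.int64)
    total = np.full(positions.size, coverage, dtype=np.int64)
    return MethylomeTrack.from_arrays({chrom: (positions, meth, total)}, sample=sample)


@pytest.fixture
def make_track():
    return track_from_levels


@pytest.fixture
def tiny_genome():
    """6 bp reference 'AACGTT' with a single CpG at position 2."""
    return ReferenceGenome({"chr1": "AACGTT"})
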