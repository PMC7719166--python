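"""Synthetic two-condition (WT vs knockout) methylome/transcriptome study.

Generates, with full ground truth, the inputs of the analysis chain:

* a toy multi-gene genome whose promoters and gene bodies are CpG-enriched
  relative to intergenic background (so planted signal has sites to carry
  it), with a matching single-transcript annotation;
* a WT methylome with high CG methylation and a KO methylome with a
  globally reduced background plus contiguous planted hypomethylated
  regions (DMRs), concentrated on gene bodies by default;
* aligned bisulfite reads whose retained-C frequency at each CpG encodes
  the planted methylation probability, subject to a configurable bisulfite
  conversion efficiency;
* aligned split RNA-seq reads over a multi-exon gene with a configurable
  per-exon skipping rate, plus decoy intron-spanning reads that a correct
  counter must exclude;
* a per-gene expression table whose log2 fold change is coupled to the
  planted gene-body DMR length with Gaussian noise.

Reads are emitted pre-aligned (SAM): the analysis chain begins from mapped
data, and alignment is outside this package's scope. All generators are
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel
from .genome import ReferenceGenome
from .intervals import GenomicInterval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _T, _G, _A = (ord(b) for b in "CTGA")


class ConfigurationError(ValueError):
    """Raised when a synthetic study configuration is infeasible."""


@dataclass(frozen=True)
class DmrSpec:
    """One planted DMR: its length, methylation delta (KO minus WT inside
    the region) and the element class it is placed on."""

    length: int
    delta: float
    element: str = "gene_body"  # gene_body | promoter | intergenic

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigurationError("DMR length must be positive")
        if not -1.0 <= self.delta <= 1.0:
            raise ConfigurationError("DMR delta must be in [-1, 1]")
        if self.element not in ("gene_body", "promoter", "intergenic"):
            raise ConfigurationError(f"unknown DMR element target {self.element!r}")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic WT-vs-KO design.

    Methylation probabilities are fractions in [0, 1]; lengths are bp.
    ``conversion_efficiency`` is the probability that an unmethylated C is
    read as T. When ``ko_target_mean`` is set, the KO background outside
    planted DMRs is solved so the KO truth mean over all CpGs equals it.
    """

    n_genes: int = 6
    seed: int = 0
    chrom: str = "chr1"
    # gene architecture
    n_exons: int = 6
    exon_length: int = 300
    intron_length: int = 600
    utr5_length: int = 400
    utr3_length: int = 400
    intergenic_length: int = 3000
    # CpG placement (mean spacing between consecutive planted sites)
    cpg_spacing_genic: int = 10
    cpg_spacing_intergenic: int = 60
    # methylation truth
    wt_mcg: float = 0.77
    ko_background_mcg: float = 0.70
    ko_target_mean: float | None = None
    dmr_spec: list[DmrSpec] = field(default_factory=list)
    # bisulfite reads
    bisulfite_coverage: float = 30.0
    conversion_efficiency: float = 0.99
    read_length: int = 100
    both_strands: bool = False
    # RNA-seq junction reads
    decoy_fraction: float = 0.05
    rna_read_length: int = 80
    # expression
    fc_coupling: float = 0.001  # log2 fold change per bp of gene-body DMR
    noise_sd: float = 0.5
    expr_baseline_log_mean: float = math.log(100.0)
    expr_baseline_log_sd: float = 0.5

    def __post_init__(self):
        for name in ("wt_mcg", "ko_background_mcg", "conversion_efficiency",
                     "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_exons", "exon_length", "intron_length",
                     "read_length", "rna_read_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_exons < 4:
            raise ConfigurationError("need >= 4 exons so internal skip targets exist")
        if self.bisulfite_coverage <= 0:
            raise ConfigurationError("bisulfite_coverage must be positive")

    @property
    def gene_span_length(self) -> int:
        exonic = (self.utr5_length + self.utr3_length
                  + self.n_exons * self.exon_length)
        return exonic + (self.n_exons - 1) * self.intron_length


@dataclass
class PlantedDmr:
    interval: GenomicInterval
    delta: float
    element: str
    gene_id: str | None = None


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study, the oracle for recovery tests."""

    chrom: str
    genome_length: int
    cpg_positions: np.ndarray
    wt_prob: np.ndarray
    ko_prob: np.ndarray
    dmrs: list[PlantedDmr] = field(default_factory=list)
    gene_dmr_length: dict[str, int] = field(default_factory=dict)
    skip_rates: dict[str, float] = field(default_factory=dict)
    expression_log2fc: dict[str, float] = field(default_factory=dict)

    def prob(self, condition: str) -> np.ndarray:
        if condition == "wt":
            return self.wt_prob
        if condition == "ko":
            return self.ko_prob
        raise ValueError(f"unknown condition {condition!r}")

    def mean_mcg(self, condition: str) -> float:
        """Truth mean methylation over all CpG sites (fraction)."""
        return float(self.prob(condition).mean())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chrom": self.chrom,
            "genome_length": self.genome_length,
            "cpg_positions": self.cpg_positions.tolist(),
            "wt_prob": np.round(self.wt_prob, 6).tolist(),
            "ko_prob": np.round(self.ko_prob, 6).tolist(),
            "dmrs": [
                {"chrom": d.interval.chrom, "start": d.interval.start,
                 "end": d.interval.end, "delta": d.delta,
                 "element": d.element, "gene_id": d.gene_id}
                for d in self.dmrs
            ],
            "gene_dmr_length": self.gene_dmr_length,
            "skip_rates": self.skip_rates,
            "expression_log2fc": self.expression_log2fc,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            chrom=d["chrom"],
            genome_length=d["genome_length"],
            cpg_positions=np.array(d["cpg_positions"], dtype=np.int64),
            wt_prob=np.array(d["wt_prob"]),
            ko_prob=np.array(d["ko_prob"]),
            dmrs=[
                PlantedDmr(GenomicInterval(x["chrom"], x["start"], x["end"]),
                           x["delta"], x["element"], x.get("gene_id"))
                for x in d["dmrs"]
            ],
            gene_dmr_length={k: int(v) for k, v in d["gene_dmr_length"].items()},
            skip_rates=d["skip_rates"],
            expression_log2fc=d["expression_log2fc"],
        )


# -- genome + annotation ---------------------------------------------------


def make_genome_and_annotation(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceGenome, list[GeneModel], SyntheticTruth]:
    """Build the toy genome, its annotation and the methylation truth.

    Gene units alternate strand along one chromosome; each unit carries a
    2 kb promoter, UTR-bearing terminal exons and ``n_exons - 2`` internal
    exons. CpG sites are planted at a short mean spacing inside promoters
    and gene bodies and a long spacing in intergenic gaps (after removing
    every background CG), so the realised CpG index is exactly the planted
    one and site truth is fully controlled.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cfg = config
    prom = 2000
    unit_gap = cfg.intergenic_length
    span = cfg.gene_span_length

    genes: list[GeneModel] = []
    genic_regions: list[tuple[int, int]] = []  # promoter + gene body, CpG-rich
    cursor = unit_gap
    for i in range(cfg.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            gstart = cursor + prom
            genes.append(_build_gene(f"gene{i + 1}", cfg, gstart, strand))
            genic_regions.append((cursor, gstart + span))
        else:
            gstart = cursor
            genes.append(_build_gene(f"gene{i + 1}", cfg, gstart, strand))
            genic_regions.append((gstart, gstart + span + prom))
        cursor += prom + span + unit_gap
    genome_length = cursor

    seq = _random_cg_free_sequence(genome_length, rng)
    cpg_positions = _plant_cpgs(seq, genic_regions, genome_length, cfg, rng)

    genome = ReferenceGenome({cfg.chrom: seq.tobytes().decode("ascii")})
    realised = genome.cpg_index(cfg.chrom)
    assert np.array_equal(realised, cpg_positions), "CpG planting failed"

    dmrs = _plant_dmrs(cfg, genes, genome_length)
    wt = np.full(cpg_positions.size, cfg.wt_mcg)
    ko_bg = cfg.ko_background_mcg
    in_dmr = np.zeros(cpg_positions.size, dtype=bool)
    ko = np.full(cpg_positions.size, ko_bg)
    for d in dmrs:
        mask = (cpg_positions >= d.interval.start) & (cpg_positions < d.interval.end)
        ko[mask] = np.clip(cfg.wt_mcg + d.delta, 0.0, 1.0)
        in_dmr |= mask
    if cfg.ko_target_mean is not None:
        n, n_dmr = cpg_positions.size, int(in_dmr.sum())
        if n == n_dmr:
            raise ConfigurationError("cannot calibrate background: all CpGs in DMRs")
        bg = (cfg.ko_target_mean * n - ko[in_dmr].sum()) / (n - n_dmr)
        if not 0.0 <= bg <= 1.0:
            raise ConfigurationError(
                f"ko_target_mean {cfg.ko_target_mean} infeasible (background {bg:.3f})"
            )
        ko[~in_dmr] = bg

    truth = SyntheticTruth(
        chrom=cfg.chrom, genome_length=genome_length,
        cpg_positions=cpg_positions, wt_prob=wt, ko_prob=ko, dmrs=dmrs,
        gene_dmr_length=_gene_body_dmr_lengths(dmrs, genes),
    )
    return genome, genes, truth


def _build_gene(gene_id: str, cfg: SyntheticConfig, start: int, strand: str) -> GeneModel:
    exon_lens = ([cfg.utr5_length + cfg.exon_length]
                 + [cfg.exon_length] * (cfg.n_exons - 2)
                 + [cfg.exon_length + cfg.utr3_length])
    if strand == "-":
        exon_lens = exon_lens[::-1]
    exons, pos = [], start
    for ln in exon_lens:
        exons.append(GenomicInterval(cfg.chrom, pos, pos + ln, strand))
        pos += ln + cfg.intron_length
    if strand == "+":
        cds_start = exons[0].start + cfg.utr5_length
        cds_end = exons[-1].end - cfg.utr3_length
    else:
        cds_start = exons[0].start + cfg.utr3_length
        cds_end = exons[-1].end - cfg.utr5_length
    return GeneModel(gene_id, cfg.chrom, strand, exons, cds_start, cds_end)


def _random_cg_free_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    seq = _BASES[rng.integers(0, 4, length)].copy()
    bad = np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G))
    seq[bad + 1] = _A  # demote the G; cannot create a new CG
    return seq


def _plant_cpgs(seq: np.ndarray, genic: list[tuple[int, int]], genome_length: int,
                cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    regions = []
    prev_end = 0
    for s, e in genic:
        if s > prev_end:
            regions.append((prev_end, s, cfg.cpg_spacing_intergenic))
        regions.append((s, e, cfg.cpg_spacing_genic))
        prev_end = e
    if prev_end < genome_length:
        regions.append((prev_end, genome_length, cfg.cpg_spacing_intergenic))
    positions = []
    for s, e, spacing in regions:
        jitter_lo = max(4, spacing - max(1, spacing // 3))
        jitter_hi = spacing + max(1, spacing // 3) + 1
        p = s + int(rng.integers(jitter_lo, jitter_hi))
        while p + 1 < e:
            positions.append(p)
            p += int(rng.integers(jitter_lo, jitter_hi))
    positions = np.array(sorted(positions), dtype=np.int64)
    seq[positions] = _C
    seq[positions + 1] = _G
    return positions


def _plant_dmrs(cfg: SyntheticConfig, genes: list[GeneModel],
                genome_length: int) -> list[PlantedDmr]:
    out: list[PlantedDmr] = []
    body_cursor: dict[str, int] = {}
    prom_cursor: dict[str, int] = {}
    inter_cursor = 200
    gi = 0
    margin = 50  # keep planted edges clear of element boundaries
    for spec in cfg.dmr_spec:
        if spec.element == "gene_body":
            # target the CDS/intron stretch so member CpGs classify as
            # exon/intron rather than UTR under the element priority
            placed = False
            for _ in range(len(genes)):
                g = genes[gi % len(genes)]
                gi += 1
                lo = (g.cds_start if g.cds_start is not None else g.start) + margin
                hi = (g.cds_end if g.cds_end is not None else g.end) - margin
                cur = body_cursor.get(g.gene_id, lo)
                if cur + spec.length <= hi:
                    iv = GenomicInterval(cfg.chrom, cur, cur + spec.length)
                    out.append(PlantedDmr(iv, spec.delta, "gene_body", g.gene_id))
                    body_cursor[g.gene_id] = cur + spec.length + 2 * margin
                    placed = True
                    break
            if not placed:
                raise ConfigurationError(
                    f"gene-body DMR of {spec.length} bp does not fit in any gene body"
                )
        elif spec.element == "promoter":
            g = genes[gi % len(genes)]
            gi += 1
            prom = g.promoter()
            cur = prom_cursor.get(g.gene_id, prom.start + margin)
            if cur + spec.length > prom.end - margin:
                raise ConfigurationError("promoter DMR does not fit")
            iv = GenomicInterval(cfg.chrom, cur, cur + spec.length)
            out.append(PlantedDmr(iv, spec.delta, "promoter", g.gene_id))
            prom_cursor[g.gene_id] = cur + spec.length + 2 * margin
        else:  # intergenic: first gap before any gene unit
            if inter_cursor + spec.length > cfg.intergenic_length - 200:
                raise ConfigurationError("intergenic DMR does not fit in the leading gap")
            iv = GenomicInterval(cfg.chrom, inter_cursor, inter_cursor + spec.length)
            out.append(PlantedDmr(iv, spec.delta, "intergenic", None))
            inter_cursor += spec.length + 100
    return out


def _gene_body_dmr_lengths(dmrs: list[PlantedDmr],
                           genes: list[GeneModel]) -> dict[str, int]:
    out = {g.gene_id: 0 for g in genes}
    for g in genes:
        body = GenomicInterval(g.chrom, g.start, g.end)
        for d in dmrs:
            out[g.gene_id] += body.intersection_length(d.interval)
    return out


# -- bisulfite reads -------------------------------------------------------


def simulate_bisulfite_reads(
    genome: ReferenceGenome,
    truth: SyntheticTruth,
    condition: str,
    config: SyntheticConfig,
    path: str | Path,
    rng: np.random.Generator | None = None,
) -> int:
    """Write coordinate-sorted aligned bisulfite reads (SAM); returns count.

    Each read covering a CpG shows C at the site with probability
    ``m + (1 - m) * (1 - conversion_efficiency)`` (m = the site's true
    methylation), else T; non-CpG cytosines convert to T with probability
    ``conversion_efficiency``. With ``both_strands`` half the reads are
    flagged reverse and report the complementary strand: G (retained) vs A
    (converted) at the CpG's G position.
    """
    if config.bisulfite_coverage <= 0:
        raise ConfigurationError("bisulfite_coverage must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom = truth.chrom
    L = truth.genome_length
    R = config.read_length
    ce = config.conversion_efficiency
    probs = truth.prob(condition)
    n_reads = int(round(config.bisulfite_coverage * L / R))
    starts = np.sort(rng.integers(0, L - R + 1, n_reads))
    if config.both_strands:
        reverse = rng.random(n_reads) < 0.5
    else:
        reverse = np.zeros(n_reads, dtype=bool)

    seq = genome.seq_array(chrom)
    cpg = truth.cpg_positions
    is_cpg_c = np.zeros(L, dtype=bool)
    is_cpg_c[cpg] = True
    is_cpg_g = np.zeros(L, dtype=bool)
    is_cpg_g[cpg + 1] = True
    m_c = np.zeros(L)
    m_c[cpg] = probs
    m_g = np.zeros(L)
    m_g[cpg + 1] = probs

    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": chrom, "LN": L}]}
    )
    offsets = np.arange(R)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for lo in range(0, n_reads, 20000):
            hi = min(lo + 20000, n_reads)
            idx = starts[lo:hi, None] + offsets
            ref = seq[idx]
            bases = ref.copy()
            u = rng.random(idx.shape)
            fwd = ~reverse[lo:hi, None]
            m = m_c[idx]
            p_ret = np.where(is_cpg_c[idx], m + (1 - m) * (1 - ce), 1 - ce)
            bases[(ref == _C) & fwd & (u >= p_ret)] = _T
            m = m_g[idx]
            p_ret = np.where(is_cpg_g[idx], m + (1 - m) * (1 - ce), 1 - ce)
            bases[(ref == _G) & ~fwd & (u >= p_ret)] = _A
            for i in range(hi - lo):
                a = pysam.AlignedSegment(header)
                a.query_name = f"bs_{condition}_{lo + i}"
                a.flag = 16 if reverse[lo + i] else 0
                a.reference_id = 0
                a.reference_start = int(starts[lo + i])
                a.mapping_quality = 60
                a.cigartuples = [(0, R)]
                a.query_sequence = bases[i].tobytes().decode("ascii")
                out.write(a)
    return n_reads


# -- RNA-seq junction reads ------------------------------------------------


def simulate_junction_reads(
    gene: GeneModel,
    target_exon_index: int,
    true_skip_rate: float,
    n_reads: int,
    config: SyntheticConfig,
    path: str | Path,
    rng: np.random.Generator | None = None,
    genome: ReferenceGenome | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Write split-aligned RNA-seq reads around one internal target exon.

    Each of the ``n_reads`` informative reads is a skipping read (a
    junction joining the flanking exons) with probability
    ``true_skip_rate``, else an inclusion read (contained in the target, or
    spanning an annotated junction that includes it). A further
    ``decoy_fraction`` of reads straddles an exon/intron boundary; a
    correct counter must exclude these. Returns a frame of per-read truth
    labels (read name, label).
    """
    k = target_exon_index
    if k <= 0 or k >= len(gene.exons) - 1:
        raise ValueError("target exon must be internal (has flanking exons)")
    if not 0.0 <= true_skip_rate <= 1.0:
        raise ValueError("true_skip_rate must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    R = config.rna_read_length
    half = R // 2
    up, target, down = gene.exons[k - 1], gene.exons[k], gene.exons[k + 1]
    for ex in (up, target, down):
        if ex.length() < half:
            raise ConfigurationError("exons shorter than half a read length")

    records: list[tuple[str, list[tuple[int, int]]]] = []  # (label, blocks)
    is_skip = rng.random(n_reads) < true_skip_rate
    for i in range(n_reads):
        if is_skip[i]:
            blocks = [(up.end - half, up.end), (down.start, down.start + R - half)]
            records.append(("skip", blocks))
        else:
            variants = []
            if target.length() >= R:
                variants.append("contained")
            if target.length() >= R - half:
                variants.extend(["junc_up", "junc_down"])
            v = variants[int(rng.integers(0, len(variants)))]
            if v == "contained":
                s = int(rng.integers(target.start, target.end - R + 1))
                blocks = [(s, s + R)]
            elif v == "junc_up":
                blocks = [(up.end - half, up.end), (target.start, target.start + R - half)]
            else:
                blocks = [(target.end - half, target.end), (down.start, down.start + R - half)]
            records.append(("incl", blocks))
    n_decoy = int(round(config.decoy_fraction * n_reads))
    for _ in range(n_decoy):
        # straddle the donor boundary of the upstream or target exon
        ex = up if rng.random() < 0.5 else target
        blocks = [(ex.end - half, ex.end + (R - half))]
        records.append(("decoy", blocks))

    records.sort(key=lambda r: r[1][0][0])
    clen = chrom_length or (genome.chrom_length(gene.chrom) if genome
                            else gene.end + 100000)
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": gene.chrom, "LN": clen}]}
    )
    rows = []
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (label, blocks) in enumerate(records):
            a = pysam.AlignedSegment(header)
            name = f"{gene.gene_id}_e{k}_{label}_{i}"
            a.query_name = name
            a.flag = 0
            a.reference_id = 0
            a.reference_start = blocks[0][0]
            a.mapping_quality = 60
            cigar = []
            for j, (s, e) in enumerate(blocks):
                if j > 0:
                    cigar.append((3, s - blocks[j - 1][1]))  # N gap
                cigar.append((0, e - s))
            a.cigartuples = cigar
            if genome is not None:
                chrom_seq = genome.sequences[gene.chrom]
                a.query_sequence = "".join(chrom_seq[s:e] for s, e in blocks)
            else:
                a.query_sequence = "A" * sum(e - s for s, e in blocks)
            out.write(a)
            rows.append({"read": name, "label": label})
    return pd.DataFrame(rows)


# -- expression ------------------------------------------------------------


def simulate_expression(
    truth: SyntheticTruth | dict[str, int],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene two-condition expression with DMR-length-coupled fold change.

    log2 fold change = fc_coupling x planted gene-body DMR length + N(0,
    noise_sd); WT baselines are log-normal and always positive. Returns a
    frame (gene_id, value_wt, value_ko); when given a SyntheticTruth its
    ``expression_log2fc`` is filled in.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = truth.gene_dmr_length if isinstance(truth, SyntheticTruth) else truth
    gene_ids = list(lengths)
    n = len(gene_ids)
    dmr_len = np.array([lengths[g] for g in gene_ids], dtype=float)
    base = np.exp(rng.normal(config.expr_baseline_log_mean,
                             config.expr_baseline_log_sd, n))
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    log2fc = config.fc_coupling * dmr_len + noise
    df = pd.DataFrame({
        "gene_id": gene_ids,
        "value_wt": base,
        "value_ko": base * np.exp2(log2fc),
    })
    if isinstance(truth, SyntheticTruth):
        truth.expression_log2fc = dict(zip(gene_ids, log2fc.tolist()))
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
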