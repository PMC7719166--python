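"""End-to-end orchestration of the synthetic WT-vs-KO study.

``run_demo`` chains the stages — synthetic data, methylation calling,
metagene profiling, DMR detection/filtering/annotation, exon-skipping
quantification, expression integration — into one output directory with a
machine-readable summary comparing every estimate to the planted truth.

All randomness flows from a single root seed through per-stage spawned
substreams, so a fixed config and seed reproduce every output byte for
byte, and each stage can be re-run in isolation from the intermediate
files. Every output file carries a header naming the package version, the
config hash and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotation import GenomeAnnotation, write_gtf
from .dmr import DmrParams, annotate_dmrs, call_dmrs, filter_dmrs, gene_body_cpg_fraction, write_dmr_bed
from .integration import build_gene_dmr_expression, correlate_dmr_expression, records_to_frame
from .metagene import profile_elements, write_profiles
from .methylation import call_methylation, global_mcg_percent, write_bedgraph
from .simulate import (DmrSpec, SyntheticConfig, simulate_bisulfite_reads,
                       simulate_expression, simulate_junction_reads, write_expression)
from .splicing import cohort_skipping_summary, count_junction_reads, results_to_frame, skipping_rate

logger = logging.getLogger(__name__)


@dataclass
class SkipGroupSpec:
    """One sample group of the exon-skipping cohort."""

    n_samples: int = 6
    true_rate: float = 0.05
    reads_per_sample: int = 500


@dataclass
class PipelineConfig:
    """Resolved parameters of every stage; YAML round-trippable."""

    synthetic: SyntheticConfig = field(default_factory=lambda: SyntheticConfig(
        n_genes=8,
        wt_mcg=0.769,
        ko_target_mean=0.664,
        # mostly gene-body regions, with promoter/intergenic ones mixed in
        # so the element breakdown of the filtered set is non-trivial
        dmr_spec=[DmrSpec(400, -0.40), DmrSpec(600, -0.40), DmrSpec(300, -0.35),
                  DmrSpec(800, -0.45), DmrSpec(500, -0.40, "promoter"),
                  DmrSpec(350, -0.35, "intergenic")],
    ))
    min_coverage: int = 4
    n_bins: int = 50
    dmr: DmrParams = field(default_factory=DmrParams)
    min_dmr_length: int = 200
    dmr_direction: str = "hypo_in_b"
    target_exon_index: int = 3
    skip_groups: dict[str, SkipGroupSpec] = field(default_factory=lambda: {
        "normal": SkipGroupSpec(6, 0.05, 500),
        "tumor": SkipGroupSpec(6, 0.30, 500),
    })
    correlation_method: str = "spearman"
    seed: int = 1

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            syn["dmr_spec"] = [DmrSpec(**s) for s in syn.get("dmr_spec", [])]
            d["synthetic"] = SyntheticConfig(**syn)
        if "dmr" in d:
            d["dmr"] = DmrParams(**d["dmr"])
        if "skip_groups" in d:
            d["skip_groups"] = {k: SkipGroupSpec(**v) for k, v in d["skip_groups"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.md5(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def provenance(config: PipelineConfig) -> list[str]:
    return [f"methsplice {__version__}",
            f"config_hash {config.config_hash()}",
            f"seed {config.seed}"]


def run_demo(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full synthetic study; returns the summary dict.

    Writes genome.fa, genes.gtf, truth.json, reads_{wt,ko}.sam,
    {wt,ko}.bedgraph, profile_{wt,ko}.tsv, dmrs.bed, dmrs_filtered.bed,
    rates.tsv, expression.tsv, corr.tsv, summary.json and the resolved
    config.yaml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    hdr = provenance(config)
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_wt, rng_ko, rng_rna, rng_expr = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        t = stage("simulate")
        from .simulate import make_genome_and_annotation
        genome, genes, truth = make_genome_and_annotation(config.synthetic, rng_genome)
        genome.to_fasta(outdir / "genome.fa")
        write_gtf(genes, outdir / "genes.gtf")
        simulate_bisulfite_reads(genome, truth, "wt", config.synthetic,
                                 outdir / "reads_wt.sam", rng_wt)
        simulate_bisulfite_reads(genome, truth, "ko", config.synthetic,
                                 outdir / "reads_ko.sam", rng_ko)
        summary["truth_mcg_wt_percent"] = 100 * truth.mean_mcg("wt")
        summary["truth_mcg_ko_percent"] = 100 * truth.mean_mcg("ko")
        logger.info("simulate done in %.1fs", time.perf_counter() - t)

        t = stage("methcall")
        tracks = {}
        for cond in ("wt", "ko"):
            tracks[cond] = call_methylation(outdir / f"reads_{cond}.sam", genome,
                                            min_coverage=config.min_coverage,
                                            sample=cond)
            write_bedgraph(tracks[cond], outdir / f"{cond}.bedgraph", hdr)
            summary[f"global_mcg_{cond}_percent"] = global_mcg_percent(tracks[cond])
        summary["mcg_gap_points"] = (summary["global_mcg_wt_percent"]
                                     - summary["global_mcg_ko_percent"])
        logger.info("methcall done in %.1fs", time.perf_counter() - t)

        t = stage("metagene")
        clens = {c: genome.chrom_length(c) for c in genome.chroms}
        for cond in ("wt", "ko"):
            profiles = profile_elements(tracks[cond], genes, n_bins=config.n_bins,
                                        chrom_lengths=clens)
            write_profiles(profiles, outdir / f"profile_{cond}.tsv", hdr)
        logger.info("metagene done in %.1fs", time.perf_counter() - t)

        t = stage("dmr")
        annotation = GenomeAnnotation(genes, clens)
        dmrs = call_dmrs(tracks["wt"], tracks["ko"], config.dmr)
        annotate_dmrs(dmrs, annotation)
        write_dmr_bed(dmrs, outdir / "dmrs.bed", hdr)
        filtered = filter_dmrs(dmrs, config.min_dmr_length, config.dmr_direction)
        write_dmr_bed(filtered, outdir / "dmrs_filtered.bed", hdr)
        summary["n_dmrs_called"] = len(dmrs)
        summary["n_dmrs_filtered"] = len(filtered)
        summary["n_dmrs_planted"] = len(truth.dmrs)
        if filtered:
            summary["gene_body_cpg_percent"] = gene_body_cpg_fraction(filtered, annotation)
        logger.info("dmr done in %.1fs", time.perf_counter() - t)

        t = stage("skiprate")
        rna_dir = outdir / "rnaseq"
        rna_dir.mkdir(exist_ok=True)
        gene = genes[0]
        results = {}
        rates_by_group: dict[str, list[float]] = {}
        for group, spec in config.skip_groups.items():
            rates_by_group[group] = []
            for s in range(spec.n_samples):
                sam = rna_dir / f"{group}_{s + 1}.sam"
                simulate_junction_reads(gene, config.target_exon_index,
                                        spec.true_rate, spec.reads_per_sample,
                                        config.synthetic, sam, rng_rna, genome)
                counts = count_junction_reads(sam, gene, config.target_exon_index)
                res = skipping_rate(counts)
                results[f"{group}_{s + 1}"] = res
                rates_by_group[group].append(res.rate)
            truth.skip_rates[f"{gene.gene_id}_e{config.target_exon_index}_{group}"] = spec.true_rate
        with open(outdir / "rates.tsv", "w") as fh:
            for line in hdr:
                fh.write(f"# {line}\n")
            results_to_frame(results).to_csv(fh, sep="\t", index=False,
                                             float_format="%.6g")
        cohort = cohort_skipping_summary(rates_by_group)
        for row in cohort.groups.itertuples():
            summary[f"skip_rate_{row.group}"] = float(row.mean)
            summary[f"skip_rate_{row.group}_true"] = config.skip_groups[row.group].true_rate
        summary["skip_anova_p"] = cohort.anova_p
        logger.info("skiprate done in %.1fs", time.perf_counter() - t)

        t = stage("integrate")
        expr = simulate_expression(truth, config.synthetic, rng_expr)
        write_expression(expr, outdir / "expression.tsv")
        records = build_gene_dmr_expression(filtered, genes, expr)
        with open(outdir / "corr.tsv", "w") as fh:
            for line in hdr:
                fh.write(f"# {line}\n")
            records_to_frame(records).to_csv(fh, sep="\t", index=False,
                                             float_format="%.6g")
        try:
            rho, p, n = correlate_dmr_expression(records,
                                                 method=config.correlation_method)
            summary.update({"correlation_rho": rho, "correlation_p": p,
                            "correlation_n": n})
        except ValueError as exc:
            summary["correlation_note"] = str(exc)
        logger.info("integrate done in %.1fs", time.perf_counter() - t)

        truth.to_json(outdir / "truth.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current['stage']!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
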