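"""Quantify exon skipping from split-aligned RNA-seq reads.

Simulates two sample groups with different true skipping rates for one
internal exon, counts inclusion (Ri) and skipping (Rs) reads — excluding
intron-overlapping reads — and summarises the cohort with group means,
s.e.m. and Tukey-adjusted pairwise comparisons.
"""

from pathlib import Path

import numpy as np

from methsplice import (SyntheticConfig, cohort_skipping_summary,
                        count_junction_reads, make_genome_and_annotation,
                        simulate_junction_reads, skipping_rate)

out = Path("scratch_example_study")
out.mkdir(exist_ok=True)
config = SyntheticConfig(n_genes=1, seed=3)
genome, genes, _ = make_genome_and_annotation(config)
gene, target_exon = genes[0], 3

rng = np.random.default_rng(1)
rates = {}
for group, true_rate in (("normal", 0.05), ("tumor", 0.30)):
    rates[group] = []
    for sample in range(6):
        sam = out / f"rna_{group}_{sample}.sam"
        simulate_junction_reads(gene, target_exon, true_rate, 500, config,
                                sam, rng, genome)
        counts = count_junction_reads(sam, gene, target_exon)
        result = skipping_rate(counts)
        rates[group].append(result.rate)
    print(f"{group}: true rate {true_rate}, per-sample estimates "
          f"{[round(r, 3) for r in rates[group]]}")
    print(f"  last sample: Ri={counts.Ri} Rs={counts.Rs} "
          f"excluded={counts.n_excluded} -> rate {result.rate:.3f} "
          f"[{result.ci_low:.3f}, {result.ci_high:.3f}]")

summary = cohort_skipping_summary(rates)
print(summary.groups.to_string(index=False))
print(summary.pairwise.to_string(index=False))
# Rs/(Ri+Rs) recovers each group's planted rate; the excluded column counts
# the decoy intron-overlapping reads, which never enter Ri or Rs; the Tukey
# comparison separates the groups decisively.
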