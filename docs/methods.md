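# Methods

## Coordinates and data model

All internal coordinates are 0-based half-open (the BED convention); GTF
input/output converts at the boundary (GTF is 1-based inclusive). A single
internal convention avoids off-by-one drift across the format zoo.

A CpG site is indexed by its plus-strand C; reverse-strand evidence (the G
one base downstream) is folded onto it, the standard symmetric-CpG
convention. Each gene is one dominant transcript: sorted non-overlapping
exons, an optional CDS span from which UTRs derive, a strand-aware 2 kb
promoter upstream of the TSS (kept at reduced length when truncated by a
chromosome end). Where annotations overlap, a position gets one label by
the fixed priority **promoter > 5′UTR > 3′UTR > exon > intron >
intergenic**; promoter methylation is the usual interpretive frame for
regulatory analyses, hence promoters first. "Gene body" means the labels
{exon, intron}.

## Methylation calling

For each CpG, informative read bases are C/T on forward reads and G/A on
reverse reads; any other base at the informative position is a sequencing
anomaly and is discarded from both counts rather than scored unmethylated.
The site level is methylated / total informative calls; sites below
`min_coverage` (default 4 — low, because the toy genomes are CpG-dense and
shallowly covered relative to production WGBS) are not emitted.

Two weightings are used deliberately: the genome-wide mCG percentage is
**call-weighted** (Σ methylated calls / Σ calls), matching how global WGBS
levels are reported, while regional means are **site-weighted** (each
covered CpG contributes equally), matching how a small region's per-CpG
panel is averaged.

No conversion-rate correction is applied: the reported level is the raw
retained-C frequency. With conversion efficiency c and true level m the
expected estimate is m + (1 − m)(1 − c), i.e. an upward bias of at most
(1 − m)(1 − c) ≈ 0.2 percentage points at the default c = 0.99. The
simulator's efficiency knob exists to study that bias, not to remove it.

## Metagene profiles

Each element instance is split into `n_bins` (50) equal-width bins (the
last bin absorbs the remainder); a CpG at proportional position p goes to
bin ⌊n_bins · p⌋, half-open, so a site exactly on an internal boundary
goes downstream. Minus-strand genes reverse bin order so bin 1 is always
5′. Default averaging pools all (gene, CpG) observations within a bin;
the alternative reading — per-gene means first, then across genes — is
implemented as `mode="per_gene"` since aggregate curves are computed both
ways in practice. Multi-instance elements (each exon, each intron) are
binned independently and pooled into one curve per element class.

## DMR caller

A deliberately simple single-replicate caller: with one methylome per
condition there is no biological dispersion to estimate, so pooled counts
and an exact test are the natural region statistic at this design scale
(no smoothing- or HMM-based inference, no replicate dispersion model).

Only CpGs covered in both tracks enter. Sliding windows of
`window_cpgs` = 5 consecutive co-covered sites are tested by two-sided
Fisher's exact test on the pooled 2×2 (methylated, unmethylated) table;
windows with p < α = 0.01 and |pooled Δ| ≥ 0.2 are marked. Same-sign
marked windows merge when they share a CpG or lie within 100 bp with no
opposite-sign marked window between. A region spans its first to last
member CpG, so its length is last − first + 1 (which is why few-site
regions have lengths of tens of bp); its p is the minimum member-window p
and its q the minimum member-window Benjamini–Hochberg q over all tested
windows. Regions with fewer than `min_cpgs` = 4 members are dropped.

Downstream filters mirror the published workflow: keep regions strictly
longer than 200 bp ("longer than" read as a strict inequality; a region of
exactly 200 bp is dropped) and, optionally, only those hypomethylated in
the second condition (Δ < 0). Recovery benchmarks are scored on this
filtered set — the unit every downstream analysis consumes — because the
raw window scan also emits occasional single-window ~45 bp specks that the
length filter exists to remove.

## Exon skipping

Read classification works on split-alignment blocks. "Reads that overlap
intronic sequence are excluded" is interpreted as intron-retention and
boundary-spanning reads: a skipping read necessarily *jumps* introns via
its junction, so the excluded class can only mean reads whose aligned
blocks touch intronic bases. Inclusion does not require a junction — reads
fully contained in the target exon count toward Ri (junction-only counting
would undercount inclusion for long exons); a junction-only sensitivity
mode can be had by filtering `classify_read` labels on block count. The
inspected neighbourhood runs from the start of the nearest upstream exon
to the end of the nearest downstream exon. The Wilson score interval is
attached to each rate (robust at extreme p̂ and small n) but is reported,
never used for exclusion; the only sample-exclusion rule is Ri + Rs = 0.

Cohorts are summarised as group mean ± s.e.m. over per-sample rates with
one-way ANOVA and Tukey HSD. When within-group variance is exactly zero
(degenerate toy inputs) the studentized range is undefined; pairwise p is
then set to 0 for unequal and 1 for equal group means.

## Integration

Gene-body DMR burden is the summed bp intersection of filtered DMR
intervals with the transcribed span (exons + introns); a DMR straddling
two genes contributes its respective overlap to each. Fold change is
log2(value_b / value_a) with a configurable pseudocount (default 0;
records with a non-positive value are flagged and dropped). Spearman rank
correlation is the default because DMR-length distributions are
heavy-tailed and the association is not assumed linear; Pearson is a flag.
The default analysis population is genes carrying at least one filtered
DMR; an all-genes mode (zeros included) is provided for sensitivity.

## Synthetic study generator

The generator emulates the WT-vs-KO design: a one-chromosome genome of
alternating-strand gene units (2 kb promoter; UTR-bearing terminal exons;
six exons by default), with CpG sites planted at ~10 bp mean spacing in
promoters and gene bodies and ~60 bp intergenically (after removing all
background CGs), so the realised CpG index equals the planted one and
per-site truth is exact. WT sites share one methylation probability
(default 0.769); KO has a reduced background plus contiguous planted DMRs
at configured lengths and deltas, targeted at the CDS/intron stretch of
gene bodies (or at promoters/intergenic gaps). When a KO target mean is
requested, the background outside DMRs is solved analytically so the KO
truth mean equals it exactly.

Bisulfite reads are emitted pre-aligned (SAM) — alignment is upstream of
this package — with per-read per-site independent methylation states, C
retained with probability m + (1 − m)(1 − c), non-CpG cytosines converted
with probability c, plus-strand only by default (an option adds
reverse-flagged reads observing G/A). RNA-seq junction reads around one
internal exon are skip-form with the configured probability, else one of
three inclusion forms; 5% decoy reads straddle an exon/intron boundary to
exercise the exclusion rule, and every read's truth label rides in its
name. Expression tables couple log2 fold change to planted gene-body DMR
length (slope `fc_coupling`, Gaussian noise `noise_sd`) over log-normal
baselines.

What the generator does **not** model: sequencing errors and quality
scores, PCR duplicates, read-level methylation haplotypes (states are
independent per read), CpG islands/shores structure, non-CG methylation,
multiple isoforms per gene, and biological replicate variation. Passing
recovery tests therefore demonstrates estimator correctness under clean
mapping and the stated noise model, not robustness to alignment artefacts
or inter-individual variation in real tissue.

## Problem sizes and numerical choices

The bundled benchmarks run at desk scale, chosen so binomial noise is well
inside each tolerance: the global-contrast study uses a ~56 kb 5-gene
genome at 30× (≈4,100 CpGs; global-mCG standard error ≈ 0.15 points); the
DMR-recovery benchmark a ~1 Mb 80-gene genome at 30× with 20 planted
hypomethylated regions of 300–1000 bp (Δ = −0.4), which also serves as the
uniform-methylome metagene flatness check (~190+ observations per bin, so
the expected maximum bin deviation ≈ 0.016 stays under the 0.02 check);
per-site recovery uses a 2-gene genome at 100×; the skipping cohort two
groups of 10 samples × 500 reads; the correlation closure 400 genes.

All generators and the pipeline draw from `numpy.random.default_rng`
seeded from a single root `SeedSequence`, with per-stage spawned
substreams, so identical config + seed reproduce outputs byte for byte and
stages remain individually re-runnable. Ties and degenerate inputs:
empty tracks raise on global summaries and return NaN for regional means;
a region report of a single site returns identical per-site and overall
values; Wilson bounds are clamped to contain the point estimate against
floating-point fuzz at p̂ ∈ {0, 1}.
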