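"""Exon-skipping quantification from split-aligned RNA-seq reads.

For a target internal exon, reads in its neighbourhood (from the start of
the nearest upstream exon to the end of the nearest downstream exon) are
partitioned into four classes:

* ``skipping`` — the read carries a splice junction whose donor is the 3'
  end of an exon upstream of the target and whose acceptor is the 5' start
  of an exon downstream: the target is absent between matched blocks;
* ``inclusion`` — the read's aligned blocks lie entirely in annotated
  exons and either a block overlaps the target with every junction
  matching annotated adjacent-exon boundaries, or the read is fully
  contained in the target exon;
* ``excluded`` — an aligned block overlaps intronic (non-exonic)
  sequence: intron-retaining or boundary-spanning reads carry no isoform
  information and are discarded;
* ``uninformative`` — anything else (e.g. a read wholly inside a flanking
  exon, or an unannotated junction).

The skipping rate is Rs / (Ri + Rs) over the inclusion (Ri) and skipping
(Rs) counts; a sample with no reads of either class around the exon is
flagged and dropped from cohort summaries. A Wilson score interval
quantifies the binomial uncertainty of each rate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.proportion import proportion_confint

from .annotation import GeneModel

logger = logging.getLogger(__name__)

LABELS = ("inclusion", "skipping", "excluded", "uninformative")


@dataclass
class JunctionCounts:
    """Read tallies around one target exon."""

    gene_id: str
    target_exon_index: int
    Ri: int = 0
    Rs: int = 0
    n_excluded: int = 0
    n_uninformative: int = 0

    @property
    def n_inspected(self) -> int:
        return self.Ri + self.Rs + self.n_excluded + self.n_uninformative


@dataclass
class ExonSkippingResult:
    """Skipping rate with Wilson confidence bounds.

    ``status`` is ``excluded_no_reads`` exactly when Ri + Rs = 0, in which
    case the rate is NaN and the sample is dropped from cohort summaries.
    """

    counts: JunctionCounts
    rate: float
    ci_low: float
    ci_high: float
    status: str


def classify_read(read: pysam.AlignedSegment, gene: GeneModel,
                  target_exon_index: int) -> str:
    """Assign one of inclusion / skipping / excluded / uninformative."""
    k = target_exon_index
    if not 0 <= k < len(gene.exons):
        raise ValueError(f"no exon index {k} in gene {gene.gene_id}")
    if read.reference_name != gene.chrom:
        raise ValueError(
            f"read {read.query_name} on {read.reference_name}, gene on {gene.chrom}"
        )
    exons = gene.exons
    target = exons[k]
    blocks = read.get_blocks()

    # excluded: any aligned base outside annotated exons (intron overlap)
    for bs, be in blocks:
        if not _within_exons(bs, be, exons):
            return "excluded"

    junctions = [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]

    # skipping: a junction from an upstream exon 3' end to a downstream
    # exon 5' start, with the target absent in between
    for donor, acceptor in junctions:
        up = [i for i, e in enumerate(exons) if e.end == donor]
        down = [j for j, e in enumerate(exons) if e.start == acceptor]
        if any(i < k for i in up) and any(j > k for j in down):
            return "skipping"

    overlaps_target = any(bs < target.end and be > target.start for bs, be in blocks)
    if len(blocks) == 1 and target.start <= blocks[0][0] and blocks[0][1] <= target.end:
        return "inclusion"
    if overlaps_target and junctions:
        if all(_is_adjacent_junction(d, a, exons) for d, a in junctions):
            return "inclusion"
        logger.debug("read %s: unannotated junction", read.query_name)
        return "uninformative"
    if junctions and not all(_is_adjacent_junction(d, a, exons) for d, a in junctions):
        logger.debug("read %s: unannotated junction", read.query_name)
    return "uninformative"


def _within_exons(start: int, end: int, exons) -> bool:
    return any(e.start <= start and end <= e.end for e in exons)


def _is_adjacent_junction(donor: int, acceptor: int, exons) -> bool:
    return any(
        exons[i].end == donor and exons[i + 1].start == acceptor
        for i in range(len(exons) - 1)
    )


def count_junction_reads(reads: str | Path, gene: GeneModel,
                         target_exon_index: int) -> JunctionCounts:
    """Tally inclusion/skipping/excluded/uninformative reads around an exon.

    Only reads overlapping the neighbourhood (upstream flanking exon start
    to downstream flanking exon end) are inspected.
    """
    k = target_exon_index
    if k <= 0 or k >= len(gene.exons) - 1:
        raise ValueError("target exon must be internal (has flanking exons)")
    lo = gene.exons[k - 1].start
    hi = gene.exons[k + 1].end
    counts = JunctionCounts(gene.gene_id, k)
    with pysam.AlignmentFile(str(reads), check_sq=False) as af:
        for read in af:
            if read.is_unmapped:
                continue
            if read.reference_start >= hi or read.reference_end <= lo:
                continue
            label = classify_read(read, gene, k)
            if label == "inclusion":
                counts.Ri += 1
            elif label == "skipping":
                counts.Rs += 1
            elif label == "excluded":
                counts.n_excluded += 1
            else:
                counts.n_uninformative += 1
    return counts


def skipping_rate(counts: JunctionCounts) -> ExonSkippingResult:
    """Rs / (Ri + Rs), with Wilson CI; no-read samples flagged excluded."""
    if counts.Ri < 0 or counts.Rs < 0:
        raise ValueError("negative read counts")
    n = counts.Ri + counts.Rs
    if n == 0:
        return ExonSkippingResult(counts, math.nan, math.nan, math.nan,
                                  "excluded_no_reads")
    rate = counts.Rs / n
    lo, hi = proportion_confint(counts.Rs, n, alpha=0.05, method="wilson")
    # guard against floating-point fuzz at the boundaries
    return ExonSkippingResult(counts, rate, min(float(lo), rate),
                              max(float(hi), rate), "ok")


@dataclass
class CohortSummary:
    groups: pd.DataFrame     # group, n, mean, sem
    pairwise: pd.DataFrame   # group1, group2, mean_diff, p_adj
    anova_p: float


def cohort_skipping_summary(rates_by_group: dict[str, list[float]]) -> CohortSummary:
    """Group means +/- s.e.m. with one-way ANOVA and Tukey HSD pairwise tests.

    NaN rates (excluded samples) are omitted; groups left with fewer than
    two usable samples are dropped with a warning. With zero within-group
    variance the studentized range is degenerate, so pairwise p is set to
    0 for unequal and 1 for equal group means.
    """
    usable: dict[str, np.ndarray] = {}
    for group, rates in rates_by_group.items():
        arr = np.asarray([r for r in rates if not math.isnan(r)], dtype=float)
        if arr.size < 2:
            warnings.warn(f"group {group!r} has < 2 usable samples; dropped")
            continue
        usable[group] = arr
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 usable samples")

    groups_df = pd.DataFrame({
        "group": list(usable),
        "n": [v.size for v in usable.values()],
        "mean": [v.mean() for v in usable.values()],
        "sem": [stats.sem(v) for v in usable.values()],
    })
    names = list(usable)
    values = np.concatenate([usable[g] for g in names])
    labels = np.concatenate([[g] * usable[g].size for g in names])

    within_ss = sum(((v - v.mean()) ** 2).sum() for v in usable.values())
    pairs = []
    if within_ss == 0.0:
        anova_p = 0.0 if len({v.mean() for v in usable.values()}) > 1 else 1.0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = usable[names[j]].mean() - usable[names[i]].mean()
                pairs.append({"group1": names[i], "group2": names[j],
                              "mean_diff": diff,
                              "p_adj": 0.0 if diff != 0 else 1.0})
    else:
        anova_p = float(stats.f_oneway(*usable.values()).pvalue)
        tukey = pairwise_tukeyhsd(values, labels)
        order = [str(g) for g in tukey.groupsunique]
        from itertools import combinations
        for (i, j), diff, p in zip(combinations(range(len(order)), 2),
                                   tukey.meandiffs, tukey.pvalues):
            pairs.append({"group1": order[i], "group2": order[j],
                          "mean_diff": float(diff), "p_adj": float(p)})
    return CohortSummary(groups_df, pd.DataFrame(pairs), anova_p)


def results_to_frame(results: dict[str, ExonSkippingResult]) -> pd.DataFrame:
    """Per-sample TSV-ready table of counts, rates and CIs."""
    rows = []
    for sample, res in results.items():
        c = res.counts
        rows.append({
            "sample": sample, "gene": c.gene_id, "exon": c.target_exon_index,
            "Ri": c.Ri, "Rs": c.Rs, "n_excluded": c.n_excluded,
            "n_uninformative": c.n_uninformative, "rate": res.rate,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "status": res.status,
        })
    return pd.DataFrame(rows)
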