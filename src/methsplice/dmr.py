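"""Differentially methylated region (DMR) detection and annotation.

The caller scans sliding windows of consecutive co-covered CpGs, tests the
pooled (methylated, unmethylated) counts of the two conditions with
Fisher's exact test, marks windows passing the significance and
effect-size thresholds, and merges overlapping or nearby same-sign marked
windows into regions. Window p-values are Benjamini-Hochberg adjusted
across all tested windows. A region's span is bounded by its first and
last member CpG, so its length is last - first + 1 (CpG-bounded, which is
why very short regions of a few sites have lengths of tens of bp).

The design is a deliberate single-replicate pooled-count caller: with one
methylome per condition there is no dispersion to model, and the exact
test on pooled counts is the natural region statistic at that design
scale. Downstream, regions can be filtered by a strict minimum length
(``length > 200`` bp by default) and by direction (hypomethylated in the
second condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .annotation import GENE_BODY_LABELS, GenomeAnnotation
from .intervals import GenomicInterval
from .methylation import MethylomeTrack


@dataclass
class DmrParams:
    """Window-scan parameters of the Fisher-exact DMR caller."""

    window_cpgs: int = 5
    min_delta: float = 0.2
    alpha: float = 0.01
    min_cpgs: int = 4
    merge_gap: int = 100  # bp between marked windows that may still merge


@dataclass
class DMR:
    """A contiguous differentially methylated interval.

    ``level_a``/``level_b`` are site-weighted mean levels of the member
    CpGs; ``delta = level_b - level_a``. ``p_value`` is the smallest
    member-window Fisher p; ``q_value`` the smallest member-window BH q.
    """

    interval: GenomicInterval
    cpg_positions: np.ndarray
    level_a: float
    level_b: float
    p_value: float
    q_value: float
    genes: list[str] = field(default_factory=list)
    element_breakdown: dict[str, int] = field(default_factory=dict)

    @property
    def n_cpgs(self) -> int:
        return int(self.cpg_positions.size)

    @property
    def delta(self) -> float:
        return self.level_b - self.level_a

    def length(self) -> int:
        return self.interval.length()


def window_scan(track_a: MethylomeTrack, track_b: MethylomeTrack,
                params: DmrParams | None = None) -> pd.DataFrame:
    """Per-window Fisher tests over co-covered CpGs of both tracks.

    Returns one row per sliding window: chrom, the member-CpG index range
    and positions, pooled delta (b minus a), p, BH q and the marked flag.
    Raises if the tracks share no covered site (different genomes).
    """
    params = params or DmrParams()
    w = params.window_cpgs
    rows = []
    shared_any = False
    for chrom in track_a.chroms:
        if chrom not in track_b.positions:
            continue
        pos_a, pos_b = track_a.positions[chrom], track_b.positions[chrom]
        common, ia, ib = np.intersect1d(pos_a, pos_b, return_indices=True)
        if common.size == 0:
            continue
        shared_any = True
        if common.size < w:
            continue
        ma = track_a.n_methylated[chrom][ia]
        ta = track_a.n_total[chrom][ia]
        mb = track_b.n_methylated[chrom][ib]
        tb = track_b.n_total[chrom][ib]
        # pooled window counts via cumulative sums
        cma, cta = np.concatenate([[0], np.cumsum(ma)]), np.concatenate([[0], np.cumsum(ta)])
        cmb, ctb = np.concatenate([[0], np.cumsum(mb)]), np.concatenate([[0], np.cumsum(tb)])
        n_win = common.size - w + 1
        Ma = cma[w:] - cma[:-w]
        Ta = cta[w:] - cta[:-w]
        Mb = cmb[w:] - cmb[:-w]
        Tb = ctb[w:] - ctb[:-w]
        delta = Mb / Tb - Ma / Ta
        for i in range(n_win):
            _, p = fisher_exact(
                [[Ma[i], Ta[i] - Ma[i]], [Mb[i], Tb[i] - Mb[i]]],
                alternative="two-sided",
            )
            rows.append({
                "chrom": chrom, "i_start": i, "i_end": i + w,
                "start_pos": int(common[i]), "end_pos": int(common[i + w - 1]),
                "delta": float(delta[i]), "p": float(p),
            })
    if not shared_any:
        raise ValueError("tracks share no covered CpG site (different genomes?)")
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "i_start", "i_end", "start_pos",
                                   "end_pos", "delta", "p", "q", "marked"])
        return df
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["marked"] = (df["p"] < params.alpha) & (df["delta"].abs() >= params.min_delta)
    return df


def call_dmrs(track_a: MethylomeTrack, track_b: MethylomeTrack,
              params: DmrParams | None = None) -> list[DMR]:
    """Detect DMRs between two methylomes (condition b relative to a).

    Overlapping marked windows of the same sign merge, as do same-sign
    marked windows separated by less than ``merge_gap`` bp with no
    opposite-sign marked window between them. Regions with fewer than
    ``min_cpgs`` member CpGs are dropped.
    """
    params = params or DmrParams()
    windows = window_scan(track_a, track_b, params)
    dmrs: list[DMR] = []
    for chrom, chrom_win in windows.groupby("chrom", sort=False):
        marked = chrom_win[chrom_win["marked"]]
        if marked.empty:
            continue
        pos_a = track_a.positions[chrom]
        pos_b = track_b.positions[chrom]
        common, ia, ib = np.intersect1d(pos_a, pos_b, return_indices=True)
        lev_a = track_a.levels(chrom)[ia]
        lev_b = track_b.levels(chrom)[ib]
        clusters = _merge_windows(marked, params.merge_gap)
        for cl in clusters:
            lo, hi = cl["i_start"], cl["i_end"]  # member CpG index range
            member = common[lo:hi]
            dmrs.append(DMR(
                interval=GenomicInterval(chrom, int(member[0]), int(member[-1]) + 1),
                cpg_positions=member,
                level_a=float(lev_a[lo:hi].mean()),
                level_b=float(lev_b[lo:hi].mean()),
                p_value=cl["p"], q_value=cl["q"],
            ))
    return [d for d in dmrs if d.n_cpgs >= params.min_cpgs]


def _merge_windows(marked: pd.DataFrame, merge_gap: int) -> list[dict]:
    """Cluster same-sign marked windows that overlap or sit within merge_gap."""
    clusters: list[dict] = []
    cur: dict | None = None
    for row in marked.itertuples():
        sign = 1 if row.delta > 0 else -1
        if cur is not None and sign == cur["sign"] and (
            row.i_start < cur["i_end"]  # shares a CpG
            or row.start_pos - cur["end_pos"] < merge_gap
        ):
            cur["i_end"] = max(cur["i_end"], row.i_end)
            cur["end_pos"] = max(cur["end_pos"], row.end_pos)
            cur["p"] = min(cur["p"], row.p)
            cur["q"] = min(cur["q"], row.q)
        else:
            if cur is not None:
                clusters.append(cur)
            cur = {"i_start": row.i_start, "i_end": row.i_end,
                   "end_pos": row.end_pos, "sign": sign, "p": row.p, "q": row.q}
    if cur is not None:
        clusters.append(cur)
    return clusters


def filter_dmrs(dmrs: list[DMR], min_length: int = 200,
                direction: str | None = "hypo_in_b") -> list[DMR]:
    """Length and direction filters, order preserved.

    Retains regions strictly longer than ``min_length`` bp. Direction
    ``"hypo_in_b"`` keeps regions with delta < 0 (lower methylation in the
    second condition), ``"hyper_in_b"`` keeps delta > 0, None keeps both.
    """
    out = [d for d in dmrs if d.length() > min_length]
    if direction == "hypo_in_b":
        out = [d for d in out if d.delta < 0]
    elif direction == "hyper_in_b":
        out = [d for d in out if d.delta > 0]
    elif direction is not None:
        raise ValueError(f"unknown direction {direction!r}")
    return out


def annotate_dmrs(dmrs: list[DMR], annotation: GenomeAnnotation) -> list[DMR]:
    """Fill each DMR's overlapping genes and per-element member-CpG counts."""
    for d in dmrs:
        d.genes = annotation.genes_overlapping(d.interval)
        breakdown: dict[str, int] = {}
        for p in d.cpg_positions:
            label = annotation.classify(d.interval.chrom, int(p))
            breakdown[label] = breakdown.get(label, 0) + 1
        d.element_breakdown = breakdown
    return dmrs


def gene_body_cpg_fraction(dmrs: list[DMR], annotation: GenomeAnnotation) -> float:
    """Percentage of DMR member CpGs classified exon or intron."""
    total = body = 0
    for d in dmrs:
        for p in d.cpg_positions:
            total += 1
            if annotation.classify(d.interval.chrom, int(p)) in GENE_BODY_LABELS:
                body += 1
    if total == 0:
        raise ValueError("no member CpGs: gene-body fraction undefined")
    return 100.0 * body / total


def dmr_region_report(dmr: DMR, track_a: MethylomeTrack,
                      track_b: MethylomeTrack) -> pd.DataFrame:
    """Per-CpG levels in both conditions across one region, plus means.

    The last row (pos = -1) carries the region means; per-site rows list
    each member CpG of the region.
    """
    pos_a, lev_a = track_a.query(dmr.interval)
    pos_b, lev_b = track_b.query(dmr.interval)
    common, ia, ib = np.intersect1d(pos_a, pos_b, return_indices=True)
    df = pd.DataFrame({
        "pos": common,
        "level_a": lev_a[ia],
        "level_b": lev_b[ib],
    })
    mean_row = pd.DataFrame({
        "pos": [-1],
        "level_a": [df["level_a"].mean()],
        "level_b": [df["level_b"].mean()],
    })
    return pd.concat([df, mean_row], ignore_index=True)


def write_dmr_bed(dmrs: list[DMR], path: str | Path,
                  header_lines: list[str] | None = None) -> None:
    """BED6+ per region: chrom, start, end, name, delta, '.', n_cpgs,
    level_a, level_b, p, q, genes."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for i, d in enumerate(dmrs, start=1):
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}"
                f"\tDMR_{i}\t{d.delta:.4f}\t.\t{d.n_cpgs}"
                f"\t{d.level_a:.4f}\t{d.level_b:.4f}"
                f"\t{d.p_value:.3e}\t{d.q_value:.3e}\t{','.join(d.genes) or '.'}\n"
            )


def read_dmr_bed(path: str | Path) -> list[DMR]:
    """Read regions written by :func:`write_dmr_bed` (member positions are
    not serialised; intervals, levels and statistics are)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            out.append(DMR(
                interval=GenomicInterval(chrom, start, end),
                cpg_positions=np.array([start, end - 1], dtype=np.int64),
                level_a=float(f[7]), level_b=float(f[8]),
                p_value=float(f[9]), q_value=float(f[10]),
                genes=[] if f[11] == "." else f[11].split(","),
            ))
    return out
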