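"""Methylome-transcriptome integration and small study utilities.

Links the filtered DMR set to expression: for each gene, the total length
of DMR sequence intersecting its gene body (exons plus introns, i.e. the
transcribed span) is correlated with the gene's expression log2 fold
change. Spearman rank correlation is the default since DMR lengths are
heavy-tailed; Pearson is available. Also provides the ellipsoid tumor
volume formula (length x width^2 / 2) used in xenograft/autochthonous
tumor burden measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .dmr import DMR
from .intervals import GenomicInterval


@dataclass
class GeneDmrExpression:
    """Per-gene record linking gene-body DMR burden to expression change."""

    gene_id: str
    total_dmr_length: int
    value_a: float
    value_b: float
    log2_fold_change: float  # NaN when either value is not positive


def dmr_length_per_gene(dmrs: list[DMR], genes: list[GeneModel]) -> dict[str, int]:
    """Total bp of each gene body covered by (filtered) DMR intervals.

    A DMR overlapping two gene bodies contributes its respective overlap
    to each; genes without overlap map to 0.
    """
    out = {g.gene_id: 0 for g in genes}
    for g in genes:
        body = GenomicInterval(g.chrom, g.start, g.end)
        for d in dmrs:
            out[g.gene_id] += body.intersection_length(d.interval)
    return out


def build_gene_dmr_expression(
    dmrs: list[DMR],
    genes: list[GeneModel],
    expression: pd.DataFrame,
    pseudocount: float = 0.0,
) -> list[GeneDmrExpression]:
    """Join gene-body DMR lengths with a two-condition expression table.

    ``expression`` needs columns gene_id, value_wt, value_ko (condition a
    and b). With the default zero pseudocount, genes where either value is
    not positive get a NaN fold change and are dropped by the correlation.
    """
    lengths = dmr_length_per_gene(dmrs, genes)
    records = []
    for row in expression.itertuples():
        va, vb = float(row.value_wt), float(row.value_ko)
        if va + pseudocount > 0 and vb + pseudocount > 0:
            l2fc = float(np.log2((vb + pseudocount) / (va + pseudocount)))
        else:
            l2fc = float("nan")
        records.append(GeneDmrExpression(
            gene_id=row.gene_id,
            total_dmr_length=lengths.get(row.gene_id, 0),
            value_a=va, value_b=vb, log2_fold_change=l2fc,
        ))
    return records


def correlate_dmr_expression(
    records: list[GeneDmrExpression],
    restrict_to_dmr_genes: bool = True,
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlation between gene-body DMR length and log2 fold change.

    Returns (coefficient, two-sided p, n). By default only genes carrying
    at least one DMR (length > 0) enter; set ``restrict_to_dmr_genes=False``
    to include zero-length genes as a sensitivity analysis.
    """
    rows = [r for r in records if not np.isnan(r.log2_fold_change)]
    if restrict_to_dmr_genes:
        rows = [r for r in rows if r.total_dmr_length > 0]
    if len(rows) < 3:
        raise ValueError(f"need >= 3 valid records, have {len(rows)}")
    x = np.array([r.total_dmr_length for r in rows], dtype=float)
    y = np.array([r.log2_fold_change for r in rows])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p), len(rows)


def records_to_frame(records: list[GeneDmrExpression]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "total_dmr_length": r.total_dmr_length,
        "value_wt": r.value_a, "value_ko": r.value_b,
        "log2_fold_change": r.log2_fold_change,
    } for r in records])


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid tumor volume in mm^3: length x width^2 / 2.

    Length is the longest diameter, width the perpendicular one; if given
    in the wrong order they are swapped with a warning.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor dimensions must be positive")
    if width_mm > length_mm:
        warnings.warn("width exceeds length; swapping dimensions")
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm ** 2 / 2.0
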