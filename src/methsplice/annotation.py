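"""Gene models, GTF I/O, BED I/O and positional element classification.

A gene is represented by a single dominant transcript: an ordered list of
non-overlapping exons plus an optional CDS span from which UTRs are derived.
The promoter is the 2 kb window immediately upstream of the TSS (strand
aware); promoters truncated at a chromosome boundary are kept at reduced
length.

Element classification assigns exactly one label per position using the
fixed priority promoter > 5utr > 3utr > exon > intron > intergenic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

PROMOTER_LENGTH = 2000

#: classification labels, highest priority first
ELEMENT_PRIORITY = ("promoter", "5utr", "3utr", "exon", "intron")
ELEMENTS = ("promoter", "5utr", "exon", "intron", "3utr")
GENE_BODY_LABELS = frozenset({"exon", "intron"})


@dataclass
class GeneModel:
    """A gene's strand-aware element structure.

    ``exons`` are sorted in genomic order and non-overlapping. ``cds_start``
    / ``cds_end`` (0-based half-open over genomic coordinates) are optional;
    when absent the gene has no annotated UTRs and every exonic base is
    labelled ``exon``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"gene {self.gene_id}: partial CDS specification")

    # -- derived structure -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, chrom_length: int | None = None) -> GenomicInterval | None:
        """The 2 kb window upstream of the TSS, truncated at chromosome ends.

        Returns None when the promoter would be empty (TSS at the boundary).
        """
        if self.strand == "+":
            start, end = max(0, self.tss - PROMOTER_LENGTH), self.tss
        else:
            start = self.tss + 1
            end = start + PROMOTER_LENGTH
            if chrom_length is not None:
                end = min(end, chrom_length)
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end, self.strand)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def elements(self, chrom_length: int | None = None) -> dict[str, list[GenomicInterval]]:
        """Element instances per class: promoter, 5utr, exon, intron, 3utr.

        With a CDS, the 5'UTR is the exonic sequence transcribed before the
        CDS and the 3'UTR the exonic sequence after it; the ``exon`` class
        then holds only the CDS-overlapping exon segments. Without a CDS the
        UTR lists are empty.
        """
        out: dict[str, list[GenomicInterval]] = {e: [] for e in ELEMENTS}
        prom = self.promoter(chrom_length)
        if prom is not None:
            out["promoter"].append(prom)
        out["intron"] = self.introns()
        if self.cds_start is None:
            out["exon"] = list(self.exons)
            return out
        left_utr = "5utr" if self.strand == "+" else "3utr"
        right_utr = "3utr" if self.strand == "+" else "5utr"
        for ex in self.exons:
            pieces = (
                (left_utr, ex.start, min(ex.end, self.cds_start)),
                ("exon", max(ex.start, self.cds_start), min(ex.end, self.cds_end)),
                (right_utr, max(ex.start, self.cds_end), ex.end),
            )
            for label, s, e in pieces:
                if s < e:
                    out[label].append(GenomicInterval(self.chrom, s, e, self.strand))
        return out


# -- GTF -------------------------------------------------------------------


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF2.2 file into GeneModels (exon + optional CDS features).

    GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. Genes with zero exon features are skipped
    with a warning; a malformed line raises ValueError naming the line.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: expected 9 fields")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(start_s) - 1  # GTF is 1-based inclusive
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: bad coordinates") from exc
            gene_id = _parse_gene_id(attrs)
            if gene_id is None:
                raise ValueError(f"{path}: malformed GTF line {lineno}: missing gene_id")
            if gene_id not in meta:
                meta[gene_id] = (chrom, strand)
                order.append(gene_id)
            if feature == "exon":
                exons.setdefault(gene_id, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
            else:
                cds.setdefault(gene_id, []).append((start, end))
    genes = []
    for gene_id in order:
        if gene_id not in exons:
            warnings.warn(f"gene {gene_id} has no exon features; skipped")
            continue
        chrom, strand = meta[gene_id]
        cds_start = cds_end = None
        if gene_id in cds:
            cds_start = min(s for s, _ in cds[gene_id])
            cds_end = max(e for _, e in cds[gene_id])
        genes.append(
            GeneModel(gene_id, chrom, strand, _merge_overlapping(exons[gene_id]),
                      cds_start, cds_end)
        )
    return genes


def _parse_gene_id(attrs: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith("gene_id"):
            return chunk.split(None, 1)[1].strip().strip('"')
    return None


def _merge_overlapping(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    ivs = sorted(intervals, key=lambda e: e.start)
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def write_gtf(genes: list[GeneModel], path: str | Path, source: str = "methsplice") -> None:
    """Write exon and CDS features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                if g.cds_start is not None:
                    s = max(ex.start, g.cds_start)
                    e = min(ex.end, g.cds_end)
                    if s < e:
                        fh.write(
                            f"{g.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{attrs}\n"
                        )


# -- BED -------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>=3 columns; strand from column 6 when present)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path,
              names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# -- classification --------------------------------------------------------


class GenomeAnnotation:
    """Position -> element lookup over a set of gene models.

    Builds one interval tree per (chromosome, element class). When a
    position falls in several annotations the highest-priority label wins:
    promoter > 5utr > 3utr > exon > intron > intergenic.
    """

    def __init__(self, genes: list[GeneModel],
                 chrom_lengths: dict[str, int] | None = None):
        self.genes = genes
        self.by_id = {g.gene_id: g for g in genes}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._gene_tree: dict[str, IntervalTree] = {}
        for g in genes:
            clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
            for label, ivs in g.elements(clen).items():
                for iv in ivs:
                    tree = self._trees.setdefault((g.chrom, label), IntervalTree())
                    tree.addi(iv.start, iv.end, g.gene_id)
            self._gene_tree.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )

    def classify(self, chrom: str, pos: int) -> str:
        """Single element label for a position; 'intergenic' is the fallback."""
        for label in ELEMENT_PRIORITY:
            tree = self._trees.get((chrom, label))
            if tree is not None and tree.overlaps_point(pos):
                return label
        return "intergenic"

    def genes_overlapping(self, interval: GenomicInterval) -> list[str]:
        tree = self._gene_tree.get(interval.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(interval.start, interval.end))
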