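"""Per-CpG methylation calling from aligned bisulfite reads.

After bisulfite conversion an unmethylated cytosine reads as T while a
methylated cytosine is protected and reads as C, so the methylation level
at a locus is the frequency with which the C is retained. On reads from
the original top strand the informative base is the C of the CpG
(methylated = C, converted = T); on reads from the original bottom strand
the informative base, seen in reference orientation, is the G one base
downstream (methylated = G, converted = A). Both strands are folded onto
the plus-strand C position of the CpG. Any other base at the informative
position (a sequencing anomaly) is discarded from both counts rather than
counted as unmethylated.

No conversion-rate correction is applied: the reported level is the raw
retained-C frequency, so incomplete conversion biases levels upward by at
most (1 - level) x (1 - conversion efficiency).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .genome import ReferenceGenome
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

_C, _T, _G, _A = (ord(b) for b in "CTGA")


@dataclass(frozen=True)
class SiteCall:
    """One CpG site: counts and level, indexed by the plus-strand C."""

    chrom: str
    pos: int
    n_methylated: int
    n_total: int

    @property
    def level(self) -> float:
        return self.n_methylated / self.n_total


class MethylomeTrack:
    """Per-CpG coverage and methylated-call counts for one sample.

    Per chromosome the track stores three parallel arrays: sorted unique
    site positions, methylated-call counts and total informative counts.
    """

    def __init__(self, sample: str = "sample"):
        self.sample = sample
        self.positions: dict[str, np.ndarray] = {}
        self.n_methylated: dict[str, np.ndarray] = {}
        self.n_total: dict[str, np.ndarray] = {}

    @classmethod
    def from_arrays(cls, chrom_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                    sample: str = "sample") -> "MethylomeTrack":
        """Build from {chrom: (positions, n_methylated, n_total)} arrays."""
        track = cls(sample)
        for chrom, (pos, meth, total) in chrom_data.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            meth = np.asarray(meth, dtype=np.int64)
            total = np.asarray(total, dtype=np.int64)
            if np.any(meth > total) or np.any(meth < 0) or np.any(total < 1):
                raise ValueError(f"{chrom}: invalid counts")
            track.positions[chrom] = pos
            track.n_methylated[chrom] = meth
            track.n_total[chrom] = total
        return track

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    def n_sites(self) -> int:
        return sum(p.size for p in self.positions.values())

    @property
    def total_calls(self) -> int:
        return int(sum(t.sum() for t in self.n_total.values()))

    @property
    def total_methylated(self) -> int:
        return int(sum(m.sum() for m in self.n_methylated.values()))

    def levels(self, chrom: str) -> np.ndarray:
        return self.n_methylated[chrom] / self.n_total[chrom]

    def query(self, interval: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
        """(positions, levels) of covered sites inside an interval."""
        pos = self.positions.get(interval.chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64), np.empty(0)
        lo, hi = np.searchsorted(pos, [interval.start, interval.end])
        return pos[lo:hi], self.levels(interval.chrom)[lo:hi]

    def sites(self):
        """Iterate SiteCalls in coordinate order."""
        for chrom in self.positions:
            for p, m, t in zip(self.positions[chrom], self.n_methylated[chrom],
                               self.n_total[chrom]):
                yield SiteCall(chrom, int(p), int(m), int(t))


def call_methylation(reads: str | Path, genome: ReferenceGenome,
                     min_coverage: int = 4, sample: str | None = None) -> MethylomeTrack:
    """Call per-CpG methylation levels from an aligned SAM/BAM file.

    For every CpG of the reference, informative read bases are tallied:
    C (forward reads) or G (reverse reads) as methylated, T or A as
    unmethylated. Sites with fewer than ``min_coverage`` informative calls
    are not emitted.
    """
    reads = str(reads)
    meth: dict[str, np.ndarray] = {}
    total: dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(reads, check_sq=False) as af:
        for read in af:
            if read.is_unmapped:
                continue
            chrom = read.reference_name
            if chrom not in genome:
                raise ValueError(f"read {read.query_name}: unknown chromosome {chrom}")
            cpgs = genome.cpg_index(chrom)
            if chrom not in meth:
                meth[chrom] = np.zeros(cpgs.size, dtype=np.int64)
                total[chrom] = np.zeros(cpgs.size, dtype=np.int64)
            _tally_read(read, cpgs, meth[chrom], total[chrom])
    chrom_data = {}
    for chrom in genome.chroms:
        if chrom not in meth:
            continue
        keep = total[chrom] >= min_coverage
        if not keep.any():
            continue
        chrom_data[chrom] = (
            genome.cpg_index(chrom)[keep], meth[chrom][keep], total[chrom][keep]
        )
    if not chrom_data:
        warnings.warn(f"no CpG site reached coverage {min_coverage}; track is empty")
    return MethylomeTrack.from_arrays(chrom_data, sample=sample or Path(reads).stem)


def _tally_read(read: pysam.AlignedSegment, cpgs: np.ndarray,
                meth: np.ndarray, total: np.ndarray) -> None:
    """Add one read's informative calls to the per-site counters."""
    seq = read.query_sequence
    if seq is None:
        return
    qarr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    reverse = read.is_reverse
    # offset of the informative base relative to the CpG's C position
    shift = 1 if reverse else 0
    meth_base, unmeth_base = (_G, _A) if reverse else (_C, _T)
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X: consumes query and reference
            lo = np.searchsorted(cpgs, rpos - shift)
            hi = np.searchsorted(cpgs, rpos + length - shift)
            if hi > lo:
                idx = np.arange(lo, hi)
                bases = qarr[cpgs[idx] + shift - rpos + qpos]
                is_meth = bases == meth_base
                informative = is_meth | (bases == unmeth_base)
                idx = idx[informative]
                np.add.at(total, idx, 1)
                np.add.at(meth, idx[is_meth[informative]], 1)
            qpos += length
            rpos += length
        elif op in (1, 4):  # I, S: query only
            qpos += length
        elif op in (2, 3):  # D, N: reference only
            rpos += length
        # 5 (H), 6 (P): consume neither


def global_mcg_percent(track: MethylomeTrack) -> float:
    """Genome-wide mCG percentage, call-weighted.

    100 x (total methylated calls) / (total informative calls); the
    standard global WGBS summary.
    """
    if track.total_calls == 0:
        raise ValueError("empty track: global mCG undefined")
    return 100.0 * track.total_methylated / track.total_calls


def region_mean_level(track: MethylomeTrack, interval: GenomicInterval) -> float:
    """Unweighted mean of per-site levels inside an interval.

    Site-weighted (each covered CpG contributes equally, regardless of its
    coverage); NaN when the interval contains no covered CpG.
    """
    _, levels = track.query(interval)
    if levels.size == 0:
        return float("nan")
    return float(levels.mean())


# -- serialisation ---------------------------------------------------------

_LEVEL_DECIMALS = 6


def write_bedgraph(track: MethylomeTrack, path: str | Path,
                   header_lines: list[str] | None = None) -> None:
    """Serialise a track: bedGraph of levels plus per-site counts.

    Columns: chrom, start, end (start+1), level, n_methylated, n_total.
    The two count columns ride along after the standard four so that the
    file round-trips losslessly while remaining bedGraph-parseable.
    """
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(f'track type=bedGraph name="{track.sample}"\n')
        for chrom in track.positions:
            levels = np.round(track.levels(chrom), _LEVEL_DECIMALS)
            for p, lv, m, t in zip(track.positions[chrom], levels,
                                   track.n_methylated[chrom], track.n_total[chrom]):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{lv:.6f}\t{m}\t{t}\n")


def read_bedgraph(path: str | Path, sample: str | None = None) -> MethylomeTrack:
    """Read a track written by :func:`write_bedgraph`.

    Plain 4-column bedGraphs are accepted too, but without count columns
    coverage defaults to 1 and the level is rounded to 0/1 — lossy; the
    6-column form written by this package round-trips exactly.
    """
    data: dict[str, list[tuple[int, int, int]]] = {}
    last: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start = fields[0], int(fields[1])
            if chrom in last and start <= last[chrom]:
                raise ValueError(f"{path}: overlapping or unsorted records at {chrom}:{start}")
            last[chrom] = start
            if len(fields) >= 6:
                m, t = int(fields[4]), int(fields[5])
            else:
                level = float(fields[3])
                t = 1
                m = int(round(level))
            data.setdefault(chrom, []).append((start, m, t))
    chrom_data = {
        chrom: (np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
                np.array([r[2] for r in rows], dtype=np.int64))
        for chrom, rows in data.items()
    }
    return MethylomeTrack.from_arrays(chrom_data, sample=sample or Path(str(path)).stem)
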