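"""Reference genome container, FASTA I/O and the CpG-site index.

A CpG site is indexed by the position of its plus-strand C; calls on the
complementary strand (the G one base downstream) are folded onto it by the
methylation caller. This is the standard symmetric-CpG convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ReferenceGenome:
    """Nucleotide sequences keyed by chromosome, with a CpG index.

    Sequences are stored uppercase. The CpG index per chromosome is the
    strictly increasing array of positions ``p`` with ``seq[p:p+2] == "CG"``;
    dinucleotides containing N are never indexed.
    """

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self._cpg_index: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        records = SeqIO.parse(str(path), "fasta")
        return cls({rec.id: str(rec.seq) for rec in records})

    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(records)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def cpg_index(self, chrom: str) -> np.ndarray:
        """Sorted positions of plus-strand Cs of CpG dinucleotides."""
        if chrom not in self._cpg_index:
            self._cpg_index[chrom] = find_cpg_sites(self.sequences[chrom])
        return self._cpg_index[chrom]

    def seq_array(self, chrom: str) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (read-only view)."""
        return np.frombuffer(self.sequences[chrom].encode("ascii"), dtype=np.uint8)


def find_cpg_sites(sequence: str) -> np.ndarray:
    """All positions p with sequence[p:p+2] == "CG" (case-insensitive).

    Returns an int64 array, strictly increasing; empty for sequences with
    no CG dinucleotide.
    """
    if len(sequence) < 2:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr[:-1] == ord("C")
    is_g = arr[1:] == ord("G")
    return np.flatnonzero(is_c & is_g).astype(np.int64)
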