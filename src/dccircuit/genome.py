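"""In-memory genome with FASTA I/O and bounds-checked sequence fetch."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class Genome:
    def __init__(self, sequences: dict[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if start < 0 or end > len(self.sequences[chrom]) or start >= end:
            raise ValueError(
                f"region {chrom}:{start}-{end} outside genome bounds "
                f"(size {len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][start:end]

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Genome":
        return cls({r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")})
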