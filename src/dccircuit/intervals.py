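"""Genomic intervals and peak sets.

All coordinates are 0-based half-open (BED convention). A :class:`PeakSet`
bundles the intervals observed for one (cell state, mark) pair and provides
the overlap queries the rest of the pipeline is built on. Overlap everywhere
means >=1 shared base under half-open arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

VALID_MARKS = ("H3K4me1", "H3K4me3", "H3K27me3", "PU.1", "footprint")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    score: float = 1.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if not np.isfinite(self.score) or self.score < 0:
            raise ValueError(f"interval score must be finite and >=0, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """Sorted collection of peaks for one cell state and mark."""

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        cell_state: str = "",
        mark: str = "",
    ):
        self.cell_state = cell_state
        self.mark = mark
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self.intervals: list[GenomicInterval] = ivs
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for idx, iv in enumerate(self.intervals):
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
            self._trees = trees
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All peaks overlapping [start, end) on chrom, in genomic order."""
        hits = self._tree(chrom).overlap(start, end)
        return [self.intervals[h.data] for h in sorted(hits, key=lambda h: h.begin)]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        return self._tree(chrom).overlaps(start, end)

    def total_score(self) -> float:
        return float(sum(iv.score for iv in self.intervals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
            }
        )

    # ---- BED I/O -------------------------------------------------------

    def write_bed(self, path: str | Path) -> None:
        df = self.to_frame()
        df["strand"] = "."
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed(
        cls, path: str | Path, cell_state: str = "", mark: str = ""
    ) -> "PeakSet":
        """Read BED3/BED6; a missing score column defaults to 1.0."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else "."
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 1.0
                rows.append(GenomicInterval(chrom, start, end, score, name))
        return cls(rows, cell_state=cell_state, mark=mark)


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[tuple[str, int, int]]:
    """Union of possibly-overlapping intervals as maximal merged regions."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s < cur_e:  # strict: touching intervals stay separate
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


@dataclass
class GeneAnnotation:
    """Gene records with a unique TSS per gene."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("gene_id", "chrom", "strand", "tss")

    def __post_init__(self) -> None:
        if len(self.table):
            missing = set(self.REQUIRED) - set(self.table.columns)
            if missing:
                raise ValueError(f"annotation missing columns: {sorted(missing)}")
            if self.table["gene_id"].duplicated().any():
                raise ValueError("duplicate gene_id in annotation")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def tss_of(self, gene_id: str) -> tuple[str, int]:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return str(row["chrom"].iloc[0]), int(row["tss"].iloc[0])

    def iter_genes(self):
        for row in self.table.itertuples(index=False):
            yield row

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneAnnotation":
        return cls(pd.read_csv(path, sep="\t"))
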