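"""Genomic interval primitives and BED I/O.

Coordinates are 0-based half-open throughout the library, matching the BED
convention.  Variant tables (see :mod:`panelseeker.variant_model`) are the
only place 1-based positions appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Role",
    "GenomicInterval",
    "merge_intervals",
    "total_length",
    "intersect_length",
    "read_bed",
    "write_bed",
]


class Role(str, Enum):
    """What an interval represents in a capture design."""

    EXON = "exon"
    TARGET = "target"
    BAIT = "bait"
    REPEAT = "repeat"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    role: Role | None = field(default=None, compare=False)
    name: str | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.chrom}:{self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval (end <= start): {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersects(self, other: "GenomicInterval") -> bool:
        return self.overlap(other) > 0

    def contains(self, chrom: str, pos: int) -> bool:
        """``pos`` is a 0-based coordinate."""
        return chrom == self.chrom and self.start <= pos < self.end

    def with_role(self, role: Role) -> "GenomicInterval":
        return replace(self, role=role)


def merge_intervals(
    intervals: Iterable[GenomicInterval], role: Role | None = None
) -> list[GenomicInterval]:
    """Union of intervals: sorted, disjoint, with adjacent intervals merged."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(replace(iv, role=role if role is not None else iv.role))
    if role is not None:
        out = [replace(iv, role=role) for iv in out]
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total number of bases in the union of ``intervals``."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def intersect_length(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Number of bases in union(a) ∩ union(b)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    total = 0
    for iva in ma:
        for ivb in mb:
            total += iva.overlap(ivb)
    return total


def read_bed(path: str | Path, role: Role | None = None) -> list[GenomicInterval]:
    """Read a 3- to 6-column BED file (only the first three columns required)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
        skip_blank_lines=True,
    )
    out = []
    for row in df.itertuples(index=False):
        vals = list(row)
        name = str(vals[3]) if len(vals) > 3 and pd.notna(vals[3]) else None
        strand = str(vals[5]) if len(vals) > 5 and pd.notna(vals[5]) else "."
        out.append(
            GenomicInterval(
                chrom=str(vals[0]),
                start=int(vals[1]),
                end=int(vals[2]),
                role=role,
                name=name,
                strand=strand,
            )
        )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as 6-column BED (name/score/strand filled with defaults)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else (iv.role.value if iv.role else ".")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
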