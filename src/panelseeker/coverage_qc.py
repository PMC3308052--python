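"""Capture-performance statistics: depth-of-coverage summaries and on-target rate.

"Covered by more than 10 / 30 reads" is a strict inequality: a base at depth
exactly 10 does not count toward ``frac_gt10``.  A read is on-target when it
overlaps the bait-covered target region by at least one base.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, merge_intervals

__all__ = ["CoverageStats", "coverage_stats", "on_target_rate", "read_depth_tsv"]


@dataclass(frozen=True)
class CoverageStats:
    median_depth: float
    frac_gt10: float
    frac_gt30: float
    on_target_rate: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_gt30 <= self.frac_gt10 <= 1.0):
            raise ValueError("expected 0 <= frac_gt30 <= frac_gt10 <= 1")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _concat_depths(depths) -> np.ndarray:
    if isinstance(depths, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in depths.values()]
    elif isinstance(depths, (list, tuple)) and depths and not np.isscalar(depths[0]):
        try:
            arrays = [np.asarray(v, dtype=float) for v in depths]
        except (TypeError, ValueError):
            arrays = [np.asarray(depths, dtype=float)]
    else:
        arrays = [np.asarray(depths, dtype=float)]
    return np.concatenate(arrays) if arrays else np.empty(0)


def coverage_stats(depths, thresholds: tuple[int, int] = (10, 30)) -> CoverageStats:
    """Median depth and strictly-greater-than threshold fractions over target bases.

    ``depths`` may be a flat array of per-base depths, a list of per-target
    arrays, or a mapping from target to array.
    """
    d = _concat_depths(depths)
    if d.size == 0:
        raise ValueError("no target bases: empty depth input")
    if (d < 0).any():
        raise ValueError("depth values must be >= 0")
    lo, hi = thresholds
    return CoverageStats(
        median_depth=float(np.median(d)),
        frac_gt10=float((d > lo).mean()),
        frac_gt30=float((d > hi).mean()),
    )


def on_target_rate(
    reads: Sequence[GenomicInterval], targets: Iterable[GenomicInterval]
) -> float:
    """Fraction of reads overlapping any target base by >= 1 bp."""
    reads = list(reads)
    if not reads:
        return 0.0
    trees: dict[str, IntervalTree] = {}
    for t in merge_intervals(targets):
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end)
    if not trees:
        return 0.0
    hits = sum(
        1
        for r in reads
        if r.chrom in trees and trees[r.chrom].overlaps(r.start, r.end)
    )
    return hits / len(reads)


def read_depth_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read a (chrom, pos, depth) TSV into per-chromosome depth arrays.

    Positions within a chromosome must be contiguous runs; only the depth
    column order is preserved (suited to dumps of per-target profiles).
    """
    df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "depth"], dtype={0: str})
    return {
        str(chrom): grp["depth"].to_numpy(dtype=float)
        for chrom, grp in df.groupby("chrom", sort=False)
    }
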