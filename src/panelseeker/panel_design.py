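"""Capture-panel design: target expansion and centered bait tiling.

Exons (coding and UTR) are grown by a fixed intronic flank into capture
targets, and each target is tiled with fixed-length baits in a k-fold
centered tiling: baits are laid at step ``bait_length / tiling_factor`` on a
grid anchored so that one bait is centered on the target midpoint, keeping
every placement that overlaps the target.  Interior target bases are then
covered by exactly ``tiling_factor`` baits.  A candidate bait is rejected
when its total overlap with repeat-masked sequence exceeds a per-bait
budget; a small budget (20 bp by default) is allowed so that short exons
closely flanked by interspersed repeats remain capturable.  Segmentally
duplicated regions are not excluded — the repeat budget is the only bait
filter.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval, Role, merge_intervals, total_length

__all__ = [
    "DesignReport",
    "expand_targets",
    "tile_baits",
    "tile_panel",
    "summarize_design",
]

DEFAULT_FLANK = 40
DEFAULT_BAIT_LENGTH = 120
DEFAULT_TILING_FACTOR = 3
DEFAULT_MAX_REPEAT_OVERLAP = 20


@dataclass(frozen=True)
class DesignReport:
    """Summary of a capture design.

    ``capture_size_bp`` counts target bases covered by at least one accepted
    bait; ``failed_fraction`` is the fraction of target bases with zero
    accepted baits, and ``failed_region_fraction`` the fraction of whole
    target regions with zero accepted baits (both are reported because
    "failed regions" can be counted either way).
    """

    capture_size_bp: int
    n_baits: int
    n_regions: int
    failed_fraction: float
    failed_region_fraction: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        text = "\t".join(d) + "\n" + "\t".join(str(v) for v in d.values()) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def expand_targets(
    exons: Iterable[GenomicInterval], flank: int = DEFAULT_FLANK
) -> list[GenomicInterval]:
    """Grow each exon by ``flank`` bases on both sides and merge overlaps.

    The growth is clipped at coordinate 0.  Overlapping or book-ended grown
    intervals on the same chromosome are merged; the result is sorted and
    disjoint, with role ``target``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    grown = [
        GenomicInterval(e.chrom, max(0, e.start - flank), e.end + flank, role=Role.TARGET)
        for e in exons
    ]
    return merge_intervals(grown, role=Role.TARGET)


def _repeat_overlap(bait: GenomicInterval, repeats: Sequence[GenomicInterval]) -> int:
    # repeats are disjoint, so summing pairwise overlaps counts each base once
    return sum(bait.overlap(r) for r in repeats)


def tile_baits(
    target: GenomicInterval,
    bait_length: int = DEFAULT_BAIT_LENGTH,
    tiling_factor: int = DEFAULT_TILING_FACTOR,
    repeats: Sequence[GenomicInterval] = (),
    max_repeat_overlap: int = DEFAULT_MAX_REPEAT_OVERLAP,
) -> list[GenomicInterval]:
    """Lay candidate baits over one target and drop repeat-heavy placements.

    Candidates sit on a grid of step ``s = bait_length // tiling_factor``
    anchored so that one candidate is centered on the target midpoint; every
    grid placement overlapping the target by at least one base is a
    candidate, which covers each target base with exactly ``tiling_factor``
    candidates.  Targets shorter than a bait still receive ``tiling_factor``
    staggered candidates overhanging both sides.  A candidate is rejected iff
    its total overlap with repeat bases exceeds ``max_repeat_overlap``.
    """
    if bait_length <= 0 or tiling_factor <= 0:
        raise ValueError("bait_length and tiling_factor must be positive")
    step, rem = divmod(bait_length, tiling_factor)
    if rem:
        warnings.warn(
            f"bait_length {bait_length} not divisible by tiling_factor "
            f"{tiling_factor}; using step {step}",
            stacklevel=2,
        )
    reps = sorted(
        (r for r in repeats if r.chrom == target.chrom),
        key=lambda r: (r.start, r.end),
    )
    mid = (target.start + target.end) // 2
    anchor = mid - bait_length // 2
    # candidate [c, c+L) overlaps target iff c > start - L and c < end
    k_min = math.ceil((target.start - bait_length + 1 - anchor) / step)
    k_max = math.floor((target.end - 1 - anchor) / step)
    accepted: list[GenomicInterval] = []
    for k in range(k_min, k_max + 1):
        c = anchor + k * step
        if c < 0:
            # contig edge: clipping would break the fixed bait length
            continue
        bait = GenomicInterval(target.chrom, c, c + bait_length, role=Role.BAIT)
        if _repeat_overlap(bait, reps) <= max_repeat_overlap:
            accepted.append(bait)
    return accepted


def tile_panel(
    targets: Iterable[GenomicInterval],
    bait_length: int = DEFAULT_BAIT_LENGTH,
    tiling_factor: int = DEFAULT_TILING_FACTOR,
    repeats: Sequence[GenomicInterval] = (),
    max_repeat_overlap: int = DEFAULT_MAX_REPEAT_OVERLAP,
) -> list[GenomicInterval]:
    """Tile every target in a panel; returns all accepted baits, sorted."""
    baits: list[GenomicInterval] = []
    for t in targets:
        baits.extend(
            tile_baits(
                t,
                bait_length=bait_length,
                tiling_factor=tiling_factor,
                repeats=repeats,
                max_repeat_overlap=max_repeat_overlap,
            )
        )
    return sorted(baits, key=lambda b: (b.chrom, b.start, b.end))


def summarize_design(
    targets: Sequence[GenomicInterval], accepted_baits: Sequence[GenomicInterval]
) -> DesignReport:
    """Compute capture size, bait/region counts and failed fractions."""
    merged_baits = merge_intervals(accepted_baits)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for b in merged_baits:
        by_chrom.setdefault(b.chrom, []).append(b)

    covered_bp = 0
    total_bp = 0
    n_covered_regions = 0
    n_regions_total = 0
    for t in targets:
        n_regions_total += 1
        cov = sum(t.overlap(b) for b in by_chrom.get(t.chrom, ()))
        if cov > 0:
            n_covered_regions += 1
    merged_targets = merge_intervals(targets)
    for t in merged_targets:
        total_bp += len(t)
        covered_bp += sum(t.overlap(b) for b in by_chrom.get(t.chrom, ()))

    failed_fraction = 0.0 if total_bp == 0 else (total_bp - covered_bp) / total_bp
    failed_region_fraction = (
        0.0 if n_regions_total == 0 else (n_regions_total - n_covered_regions) / n_regions_total
    )
    return DesignReport(
        capture_size_bp=covered_bp,
        n_baits=len(accepted_baits),
        n_regions=n_covered_regions,
        failed_fraction=failed_fraction,
        failed_region_fraction=failed_region_fraction,
    )
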