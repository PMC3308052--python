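"""Toy gene models with codon-level effect classification.

A :class:`GeneModel` carries exon structure, a CDS span with a defined
reading frame, and the underlying reference sequence, which is enough to
classify a variant's predicted effect: codon translation decides
nonsense/missense/synonymous for coding SNVs, indel length mod 3 decides
frameshift vs in-frame, and proximity to an exon boundary on the intronic
side (within ``splice_window`` bases, default 2 — the canonical
donor/acceptor dinucleotides) flags splice-junction variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from Bio.Seq import Seq

from .variant_model import VariantObservation

__all__ = ["Effect", "GeneModel", "classify_effect", "gene_at", "FUNCTIONAL_EFFECTS"]

DEFAULT_SPLICE_WINDOW = 2


class Effect(str, Enum):
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE_JUNCTION = "splice_junction"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    UTR = "utr"
    INTRONIC = "intronic"


#: Effects counted as "potentially functional" (the four tabulated classes;
#: synonymous, UTR, intronic and in-frame indels are excluded).
FUNCTIONAL_EFFECTS = frozenset(
    {Effect.NONSENSE, Effect.MISSENSE, Effect.SPLICE_JUNCTION, Effect.FRAMESHIFT}
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class GeneModel:
    """One transcript on a toy reference contig.

    ``exons`` are 0-based half-open, sorted, non-overlapping; ``cds_start``
    and ``cds_end`` bound the coding sequence in genomic coordinates (frame 0
    at ``cds_start`` for '+' genes, at ``cds_end`` for '-').  ``seq`` is the
    contig sequence starting at genomic coordinate ``seq_offset``.
    """

    name: str
    chrom: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    seq: str
    strand: str = "+"
    seq_offset: int = 0
    _coding_positions: list[int] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if e <= s or s < prev_end:
                raise ValueError(f"{self.name}: exons must be sorted and disjoint")
            prev_end = e
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (self.exons[0][0] <= self.cds_start < self.cds_end <= self.exons[-1][1]):
            raise ValueError(f"{self.name}: CDS outside exon span")

    # -- coordinate helpers (all 0-based genomic) -----------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def base(self, pos: int) -> str:
        return self.seq[pos - self.seq_offset]

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def splice_distance(self, pos: int) -> int | None:
        """Distance from an intronic position to the nearest exon edge; None in exons."""
        if self.in_exon(pos):
            return None
        best: int | None = None
        for s, e in self.exons:
            for d in (s - pos, pos - (e - 1)):
                if d > 0 and (best is None or d < best):
                    best = d
        return best

    def coding_positions(self) -> list[int]:
        """Genomic positions of CDS bases in 5'→3' transcript order."""
        if self._coding_positions is None:
            pos = [
                p
                for s, e in self.exons
                for p in range(max(s, self.cds_start), min(e, self.cds_end))
            ]
            if self.strand == "-":
                pos.reverse()
            self._coding_positions = pos
        return self._coding_positions

    def in_cds(self, pos: int) -> bool:
        return self.cds_start <= pos < self.cds_end and self.in_exon(pos)

    def transcript_base(self, pos: int) -> str:
        b = self.base(pos)
        return b.translate(_COMPLEMENT) if self.strand == "-" else b

    def codon_at(self, cds_index: int) -> str:
        """The reference codon containing CDS base ``cds_index`` (0-based)."""
        positions = self.coding_positions()
        c0 = (cds_index // 3) * 3
        return "".join(self.transcript_base(positions[c0 + i]) for i in range(3))

    def coding_sequence(self) -> str:
        return "".join(self.transcript_base(p) for p in self.coding_positions())


def classify_effect(
    variant: VariantObservation,
    gene: GeneModel,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> Effect:
    """Predicted effect of a variant on a gene's transcript/protein."""
    pos0 = variant.pos - 1
    if variant.chrom != gene.chrom or not (gene.start - 10_000 <= pos0 <= gene.end + 10_000):
        return Effect.INTRONIC  # outside any transcript

    if variant.is_indel:
        ref, alt = variant.ref_allele, variant.alt_allele
        # footprint of the changed bases on the reference
        foot_lo, foot_hi = pos0, pos0 + max(len(ref) - 1, 0)
        touches_cds = any(
            gene.in_cds(p) for p in range(foot_lo, foot_hi + 1)
        )
        if touches_cds:
            return (
                Effect.FRAMESHIFT
                if abs(len(ref) - len(alt)) % 3
                else Effect.INFRAME_INDEL
            )
        if any(gene.in_exon(p) for p in range(foot_lo, foot_hi + 1)):
            return Effect.UTR
        d = gene.splice_distance(pos0)
        return Effect.SPLICE_JUNCTION if d is not None and d <= splice_window else Effect.INTRONIC

    if not gene.in_exon(pos0):
        d = gene.splice_distance(pos0)
        if d is not None and d <= splice_window:
            return Effect.SPLICE_JUNCTION
        return Effect.INTRONIC
    if not gene.in_cds(pos0):
        return Effect.UTR

    positions = gene.coding_positions()
    cds_index = positions.index(pos0)
    within = cds_index % 3
    ref_codon = gene.codon_at(cds_index)
    alt_base = variant.alt_allele
    if gene.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        return Effect.SYNONYMOUS
    if alt_aa == "*":
        return Effect.NONSENSE
    return Effect.MISSENSE


def gene_at(genes: Sequence[GeneModel], chrom: str, pos: int) -> GeneModel | None:
    """The gene whose exon span (with captured flank) contains 0-based ``pos``."""
    for g in genes:
        if g.chrom == chrom and g.start - 40 <= pos < g.end + 40:
            return g
    return None
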