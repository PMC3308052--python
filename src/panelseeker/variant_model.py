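"""Variant observations, zygosity from allele fractions, and cryptic indels.

A variant's zygosity is a step function of its variant allele fraction
(VAF = variant reads / total reads): homozygous above ``hom_min`` (default
0.80, observed homozygotes show ~100% variant reads), heterozygous between
``het_min`` (default 0.30) and ``hom_min`` (observed heterozygotes show
~48–51%), and *weak support* below ``het_min``.  Weak support is
diagnostically important: two adjacent or nearly adjacent substitutions each
supported by ~25% of reads often reflect an underlying insertion or deletion
misread by the aligner, so such runs are grouped into indel candidates for
local resolution or Sanger-style confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Zygosity",
    "VariantObservation",
    "ZygosityCall",
    "IndelCandidate",
    "call_zygosity",
    "detect_cryptic_indels",
    "resolve_indel",
    "partition_observations",
    "read_variant_table",
    "write_variant_table",
    "read_vcf",
    "write_vcf",
    "HET_MIN",
    "HOM_MIN",
    "MIN_DEPTH",
]

HET_MIN = 0.30
HOM_MIN = 0.80
MIN_DEPTH = 10  # the looser of the two published depth cutoffs; 30 also supported


class Zygosity(str, Enum):
    REFERENCE = "reference"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    WEAK_SUPPORT = "weak_support"


@dataclass(frozen=True)
class VariantObservation:
    """One site's read support in one proband.  ``pos`` is 1-based."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_reads: int
    var_reads: int
    proband_id: str = ""

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.var_reads < 0:
            raise ValueError("read counts must be >= 0")
        if self.ref_reads + self.var_reads == 0:
            raise ValueError(f"zero total reads at {self.chrom}:{self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty allele string")

    @property
    def total_reads(self) -> int:
        return self.ref_reads + self.var_reads

    @property
    def vaf(self) -> float:
        return self.var_reads / self.total_reads

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class ZygosityCall:
    state: Zygosity
    vaf: float
    depth_ok: bool


@dataclass(frozen=True)
class IndelCandidate:
    """A run of weak-support SNVs suspected to hide an indel.

    ``span`` is 1-based inclusive over the member sites.
    """

    chrom: str
    span: tuple[int, int]
    member_sites: tuple[VariantObservation, ...]
    status: str = "candidate"  # candidate | resolved
    resolved_allele: str | None = None


def call_zygosity(
    obs: VariantObservation,
    min_depth: int = MIN_DEPTH,
    het_min: float = HET_MIN,
    hom_min: float = HOM_MIN,
) -> ZygosityCall:
    """Classify a site from its allele fraction; flag shallow sites via ``depth_ok``."""
    vaf = obs.vaf
    if obs.var_reads == 0:
        state = Zygosity.REFERENCE
    elif vaf >= hom_min:
        state = Zygosity.HOMOZYGOUS
    elif vaf >= het_min:
        state = Zygosity.HETEROZYGOUS
    else:
        state = Zygosity.WEAK_SUPPORT
    return ZygosityCall(state=state, vaf=vaf, depth_ok=obs.total_reads >= min_depth)


def detect_cryptic_indels(
    observations: Sequence[VariantObservation],
    max_gap: int = 3,
    ratio_tol: float = 1.5,
    het_min: float = HET_MIN,
) -> list[IndelCandidate]:
    """Group runs of nearby weak-support SNVs into indel candidates.

    A maximal run of >= 2 weak-support SNVs on one chromosome, with
    successive position gaps <= ``max_gap`` and pairwise variant-read ratios
    <= ``ratio_tol``, becomes one candidate.  Sites with VAF >= ``het_min``
    (clean het/hom calls) are never consumed.
    """
    weak = sorted(
        (
            o
            for o in observations
            if o.is_snv
            and call_zygosity(o, het_min=het_min).state is Zygosity.WEAK_SUPPORT
        ),
        key=lambda o: (o.chrom, o.pos),
    )
    candidates: list[IndelCandidate] = []
    run: list[VariantObservation] = []

    def flush() -> None:
        if len(run) >= 2:
            candidates.append(
                IndelCandidate(
                    chrom=run[0].chrom,
                    span=(run[0].pos, run[-1].pos),
                    member_sites=tuple(run),
                )
            )

    for o in weak:
        if run:
            reads = [m.var_reads for m in run] + [o.var_reads]
            similar = max(reads) <= ratio_tol * max(1, min(reads))
            if o.chrom == run[-1].chrom and o.pos - run[-1].pos <= max_gap and similar:
                run.append(o)
                continue
            flush()
            run = []
        run.append(o)
    flush()
    return candidates


def partition_observations(
    observations: Sequence[VariantObservation],
    max_gap: int = 3,
    ratio_tol: float = 1.5,
    het_min: float = HET_MIN,
) -> tuple[list[VariantObservation], list[IndelCandidate]]:
    """Split a proband's stream into SNVs and indel candidates.

    Member sites of each candidate are removed from the SNV stream and
    replaced by the candidate.
    """
    candidates = detect_cryptic_indels(
        observations, max_gap=max_gap, ratio_tol=ratio_tol, het_min=het_min
    )
    consumed = {id(m) for c in candidates for m in c.member_sites}
    remaining = [o for o in observations if id(o) not in consumed]
    return remaining, candidates


def resolve_indel(
    candidate: IndelCandidate,
    window_start: int,
    window_seq: str,
    truth: Iterable[tuple[str, int, str, str]] | None = None,
) -> IndelCandidate:
    """Resolve a candidate against a truth/realignment source.

    ``window_start`` is the 1-based position of ``window_seq``'s first base;
    the window must cover the candidate span.  When ``truth`` (an iterable of
    (chrom, pos, ref, alt) planted indels, as produced by synthetic runs)
    contains an indel overlapping the span, the candidate is resolved to that
    allele; otherwise it is returned unchanged for external (Sanger-style)
    confirmation.
    """
    if candidate.status == "resolved":
        raise ValueError("candidate already resolved")
    lo, hi = candidate.span
    window_end = window_start + len(window_seq) - 1
    if window_start > lo or window_end < hi:
        raise ValueError(
            f"reference window [{window_start},{window_end}] does not cover span [{lo},{hi}]"
        )
    if truth is not None:
        for chrom, pos, ref, alt in truth:
            if chrom != candidate.chrom or len(ref) == len(alt):
                continue
            # indel footprint on the reference, 1-based inclusive
            foot = (pos, pos + max(len(ref), 1) - 1)
            if foot[0] <= hi + 1 and foot[1] >= lo - 1:
                allele = f"{chrom}:{pos}:{ref}>{alt}"
                return replace(
                    candidate, status="resolved", resolved_allele=allele
                )
    return candidate


# -- variant table I/O --------------------------------------------------------

_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_reads", "var_reads", "proband"]


def read_variant_table(path: str | Path) -> list[VariantObservation]:
    """Read a headered TSV (chrom, pos, ref, alt, ref_reads, var_reads, proband)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "proband": str})
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return [
        VariantObservation(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            ref_reads=int(r.ref_reads),
            var_reads=int(r.var_reads),
            proband_id=str(r.proband),
        )
        for r in df.itertuples(index=False)
    ]


def write_variant_table(
    observations: Iterable[VariantObservation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            (o.chrom, o.pos, o.ref_allele, o.alt_allele, o.ref_reads, o.var_reads, o.proband_id)
            for o in observations
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, sample: str | None = None) -> list[VariantObservation]:
    """Minimal VCF reader mapping AD-style counts to ref/var reads (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if sample is None:
        if len(samples) != 1:
            raise ValueError("multi-sample VCF: pass sample=")
        sample = samples[0]
    idx = samples.index(sample)
    out = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            continue
        ref_reads = int(ad[idx][0])
        for j, alt in enumerate(rec.ALT):
            out.append(
                VariantObservation(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                    ref_reads=ref_reads,
                    var_reads=int(ad[idx][1 + j]),
                    proband_id=sample,
                )
            )
    return out


def write_vcf(
    observations: Iterable[VariantObservation], path: str | Path, sample: str = "SAMPLE"
) -> None:
    """Write observations as a minimal VCF 4.2 with AD/DP in the sample column."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for o in sorted(observations, key=lambda x: (x.chrom, x.pos)):
            call = call_zygosity(o)
            gt = {
                Zygosity.HOMOZYGOUS: "1/1",
                Zygosity.HETEROZYGOUS: "0/1",
                Zygosity.WEAK_SUPPORT: "0/1",
                Zygosity.REFERENCE: "0/0",
            }[call.state]
            fh.write(
                f"{o.chrom}\t{o.pos}\t.\t{o.ref_allele}\t{o.alt_allele}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{o.ref_reads},{o.var_reads}:{o.total_reads}\n"
            )
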