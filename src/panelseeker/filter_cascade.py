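"""Rare-variant filter cascade and per-proband tabulation.

Raw calls are reduced to rare, conserved, potentially functional candidates
by four filters applied in order:

1. **dbSNP** — a variant known to dbSNP is discarded unless it is flagged as
   clinically associated (dbSNP contains both disease and benign alleles).
2. **conservation** — an SNV whose PhyloP score is below 0.9 is considered
   non-conserved and discarded.  Indels are exempt (the score is defined for
   the consensus nucleotide of an SNV).
3. **cohort recurrence** — a variant carried by more than ``max_probands``
   probands (default 3, i.e. present in >= 4 of the cohort) is treated as a
   population polymorphism of the sequenced ethnic groups and discarded,
   whether or not dbSNP knows it.
4. **1000 Genomes / hearing genomes** — a variant passing recurrence that is
   nonetheless reported in the 1000 Genomes project, or in other published
   genomes from hearing individuals, is discarded.

Survivors are classified by predicted effect; "potentially functional" means
nonsense, missense, splice junction or frameshift.  PolyPhen-2/SIFT scores
are attached as annotations only — they never filter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genes import FUNCTIONAL_EFFECTS, Effect, GeneModel, classify_effect, gene_at
from .variant_model import VariantObservation

__all__ = [
    "AnnotationStubs",
    "AnnotatedVariant",
    "ProbandSummary",
    "filter_dbsnp",
    "filter_conservation",
    "filter_recurrence",
    "filter_1000g",
    "classify_effect",
    "compute_recurrence",
    "run_cascade",
    "summaries_to_frame",
]

logger = logging.getLogger(__name__)

Key = tuple[str, int, str, str]

DEFAULT_MAX_PROBANDS = 3
PHYLOP_MIN = 0.9


@dataclass
class AnnotationStubs:
    """Annotation lookups keyed by (chrom, pos, ref, alt).

    ``dbsnp`` maps a variant key to its clinical-association flag; ``phylop``
    maps (chrom, pos) to a conservation score; ``kgenomes`` and
    ``hearing_genomes`` are membership sets; ``scores`` maps a key to
    (PolyPhen-2 HumVar, SIFT).
    """

    dbsnp: dict[Key, bool] = field(default_factory=dict)
    phylop: dict[tuple[str, int], float] = field(default_factory=dict)
    kgenomes: set[Key] = field(default_factory=set)
    hearing_genomes: set[Key] = field(default_factory=set)
    scores: dict[Key, tuple[float | None, float | None]] = field(default_factory=dict)

    # -- TSV round trip -------------------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [(c, p, r, a, f"rs{i:07d}", int(flag)) for i, ((c, p, r, a), flag) in enumerate(sorted(self.dbsnp.items()))],
            columns=["chrom", "pos", "ref", "alt", "id", "clinical_flag"],
        ).to_csv(out / "dbsnp.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(c, p, s) for (c, p), s in sorted(self.phylop.items())],
            columns=["chrom", "pos", "phylop"],
        ).to_csv(out / "phylop.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.kgenomes), columns=["chrom", "pos", "ref", "alt"]
        ).to_csv(out / "kgenomes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(c, p, r, a, pp, sf) for (c, p, r, a), (pp, sf) in sorted(self.scores.items())],
            columns=["chrom", "pos", "ref", "alt", "polyphen2_humvar", "sift"],
        ).to_csv(out / "scores.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "AnnotationStubs":
        d = Path(in_dir)
        stubs = cls()
        db = pd.read_csv(d / "dbsnp.tsv", sep="\t", dtype={"chrom": str})
        for r in db.itertuples(index=False):
            stubs.dbsnp[(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))] = bool(r.clinical_flag)
        ph = pd.read_csv(d / "phylop.tsv", sep="\t", dtype={"chrom": str})
        for r in ph.itertuples(index=False):
            stubs.phylop[(str(r.chrom), int(r.pos))] = float(r.phylop)
        kg = pd.read_csv(d / "kgenomes.tsv", sep="\t", dtype={"chrom": str})
        for r in kg.itertuples(index=False):
            stubs.kgenomes.add((str(r.chrom), int(r.pos), str(r.ref), str(r.alt)))
        sc = pd.read_csv(d / "scores.tsv", sep="\t", dtype={"chrom": str})
        for r in sc.itertuples(index=False):
            stubs.scores[(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))] = (
                None if pd.isna(r.polyphen2_humvar) else float(r.polyphen2_humvar),
                None if pd.isna(r.sift) else float(r.sift),
            )
        return stubs


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant with its annotations and the ordered filter verdict trail."""

    observation: VariantObservation
    gene: str
    effect: Effect | None
    in_dbsnp: bool
    clinically_associated: bool
    phylop: float | None
    in_1000g: bool
    recurrence: int
    polyphen2_humvar: float | None
    sift: float | None
    verdict_trail: tuple[tuple[str, bool], ...]

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.verdict_trail)

    @property
    def is_functional(self) -> bool:
        return self.passed and self.effect in FUNCTIONAL_EFFECTS


@dataclass(frozen=True)
class ProbandSummary:
    """Per-proband counts in the layout of a rare-variant summary table."""

    proband_id: str
    n_rare_snv: int
    n_private_indel: int
    n_rare_total: int
    n_nonsense: int
    n_missense: int
    n_splice: int
    n_frameshift: int
    n_functional_total: int

    def __post_init__(self) -> None:
        if self.n_rare_total != self.n_rare_snv + self.n_private_indel:
            raise ValueError("rare total must equal SNV + indel counts")
        if self.n_functional_total != (
            self.n_nonsense + self.n_missense + self.n_splice + self.n_frameshift
        ):
            raise ValueError("functional total must equal the sum of effect counts")


# -- individual filters -------------------------------------------------------


def filter_dbsnp(key: Key, dbsnp: Mapping[Key, bool]) -> bool:
    """Pass unless the variant is in dbSNP without a clinical association."""
    if key not in dbsnp:
        return True
    return bool(dbsnp[key])


def filter_conservation(
    obs: VariantObservation,
    phylop: Mapping[tuple[str, int], float],
    threshold: float = PHYLOP_MIN,
    missing_passes: bool = True,
) -> bool:
    """Discard SNVs with PhyloP < threshold; indels are exempt."""
    if obs.is_indel:
        return True
    score = phylop.get((obs.chrom, obs.pos))
    if score is None:
        if missing_passes:
            logger.info("no PhyloP score at %s:%d; passing", obs.chrom, obs.pos)
            return True
        return False
    return score >= threshold


def filter_recurrence(recurrence: int, max_probands: int = DEFAULT_MAX_PROBANDS) -> bool:
    """Pass variants present in up to ``max_probands`` cohort probands."""
    return recurrence <= max_probands


def filter_1000g(
    key: Key, kgenomes: set[Key], hearing_genomes: set[Key] = frozenset()
) -> bool:
    """Discard variants reported in 1000 Genomes or published hearing genomes."""
    return key not in kgenomes and key not in hearing_genomes


def compute_recurrence(
    tables: Mapping[str, Sequence[VariantObservation]]
) -> Counter:
    """Number of probands carrying each variant key, in any zygosity."""
    counts: Counter = Counter()
    for observations in tables.values():
        for key in {o.key for o in observations}:
            counts[key] += 1
    return counts


# -- the cascade --------------------------------------------------------------


def run_cascade(
    observations: Sequence[VariantObservation],
    stubs: AnnotationStubs,
    genes: Sequence[GeneModel],
    recurrence: Mapping[Key, int],
    proband_id: str | None = None,
    max_probands: int = DEFAULT_MAX_PROBANDS,
    phylop_min: float = PHYLOP_MIN,
    splice_window: int = 2,
) -> tuple[list[AnnotatedVariant], ProbandSummary]:
    """Apply dbSNP → conservation → recurrence → 1000G, then classify survivors."""
    annotated: list[AnnotatedVariant] = []
    pid = proband_id
    for obs in observations:
        if pid is None:
            pid = obs.proband_id
        key = obs.key
        rec = int(recurrence.get(key, 1))
        trail: list[tuple[str, bool]] = []
        ok = filter_dbsnp(key, stubs.dbsnp)
        trail.append(("dbsnp", ok))
        if ok:
            ok = filter_conservation(obs, stubs.phylop, threshold=phylop_min)
            trail.append(("conservation", ok))
        if ok:
            ok = filter_recurrence(rec, max_probands=max_probands)
            trail.append(("recurrence", ok))
        if ok:
            ok = filter_1000g(key, stubs.kgenomes, stubs.hearing_genomes)
            trail.append(("1000g", ok))

        gene = gene_at(genes, obs.chrom, obs.pos - 1)
        effect = None
        if ok:
            effect = (
                classify_effect(obs, gene, splice_window=splice_window)
                if gene is not None
                else Effect.INTRONIC
            )
        pp2, sift = stubs.scores.get(key, (None, None))
        annotated.append(
            AnnotatedVariant(
                observation=obs,
                gene=gene.name if gene is not None else "",
                effect=effect,
                in_dbsnp=key in stubs.dbsnp,
                clinically_associated=bool(stubs.dbsnp.get(key, False)),
                phylop=stubs.phylop.get((obs.chrom, obs.pos)),
                in_1000g=key in stubs.kgenomes,
                recurrence=rec,
                polyphen2_humvar=pp2,
                sift=sift,
                verdict_trail=tuple(trail),
            )
        )

    survivors = [a for a in annotated if a.passed]
    n_snv = sum(1 for a in survivors if a.observation.is_snv)
    n_indel = sum(1 for a in survivors if not a.observation.is_snv)
    eff = Counter(a.effect for a in survivors)
    summary = ProbandSummary(
        proband_id=pid or "",
        n_rare_snv=n_snv,
        n_private_indel=n_indel,
        n_rare_total=n_snv + n_indel,
        n_nonsense=eff[Effect.NONSENSE],
        n_missense=eff[Effect.MISSENSE],
        n_splice=eff[Effect.SPLICE_JUNCTION],
        n_frameshift=eff[Effect.FRAMESHIFT],
        n_functional_total=eff[Effect.NONSENSE]
        + eff[Effect.MISSENSE]
        + eff[Effect.SPLICE_JUNCTION]
        + eff[Effect.FRAMESHIFT],
    )
    return annotated, summary


def summaries_to_frame(summaries: Iterable[ProbandSummary]) -> pd.DataFrame:
    """Wide-form table of per-proband counts (one row per proband)."""
    rows = [
        (
            s.proband_id,
            s.n_rare_snv,
            s.n_private_indel,
            s.n_rare_total,
            s.n_nonsense,
            s.n_missense,
            s.n_splice,
            s.n_frameshift,
            s.n_functional_total,
        )
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "proband",
            "rare_snv",
            "private_indels",
            "rare_total",
            "nonsense",
            "missense",
            "splice_junctions",
            "frameshift",
            "functional_total",
        ],
    )
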