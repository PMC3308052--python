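"""Pedigree co-segregation checks for candidate disease alleles.

A candidate allele (or compound-heterozygous allele pair) co-segregates with
a phenotype under full penetrance when every affected member carries the
causal genotype and no unaffected member does.  Members with unknown
genotypes abstain — they never create violations.  Compound heterozygotes
require the two alleles *in trans* (one per homologue); phase is inferred
from parental genotypes where possible, and an affected member het for both
alleles with unresolvable phase is counted consistent-with-warning, since a
lone pair of hets is insufficient evidence either way.

The model is deliberately simple: full penetrance, no phenocopies, no de
novo events, autosomal inheritance only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Genotype",
    "Phase",
    "PedigreeMember",
    "SegregationResult",
    "check_recessive",
    "check_dominant",
    "phase_compound_het",
    "read_ped",
    "read_genotypes",
    "write_ped",
    "write_genotypes",
]


class Genotype(str, Enum):
    REF = "ref"
    HET = "het"
    HOM = "hom"


class Phase(str, Enum):
    TRANS = "trans"
    CIS = "cis"
    UNKNOWN = "unknown"


@dataclass
class PedigreeMember:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "0"
    affected: bool | None = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def genotype(self, allele: str) -> Genotype | None:
        return self.genotypes.get(allele)

    def carries(self, allele: str) -> bool | None:
        g = self.genotype(allele)
        if g is None:
            return None
        return g is not Genotype.REF


Pedigree = Mapping[str, PedigreeMember]


@dataclass
class SegregationResult:
    consistent: bool
    violations: list[tuple[str, str]]
    model: str
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _validate(pedigree: Pedigree, alleles: Iterable[str]) -> None:
    for m in pedigree.values():
        for pid in (m.father_id, m.mother_id):
            if pid is not None and pid not in pedigree:
                raise ValueError(f"member {m.id}: parent {pid} not in pedigree")
    alleles = list(alleles)
    genotyped = {
        a for m in pedigree.values() for a in m.genotypes if m.genotypes[a] is not None
    }
    missing = [a for a in alleles if a not in genotyped]
    if missing:
        raise ValueError(f"allele(s) absent from all genotype maps: {missing}")
    if not any(
        m.affected and any(a in m.genotypes for a in alleles) for m in pedigree.values()
    ):
        raise ValueError("allele(s) not genotyped in any affected member")


def phase_compound_het(
    pedigree: Pedigree, member_id: str, allele_a: str, allele_b: str
) -> Phase:
    """Infer whether two het alleles in a member lie in trans or in cis.

    Trans when each parent carries exactly one of the two alleles (one each);
    cis when one parent carries both and the other neither; unknown
    otherwise (including ungenotyped or absent parents).
    """
    member = pedigree[member_id]
    if member.genotype(allele_a) is not Genotype.HET or member.genotype(allele_b) is not Genotype.HET:
        raise ValueError(f"{member_id} must be het for both alleles to phase them")
    father = pedigree.get(member.father_id) if member.father_id else None
    mother = pedigree.get(member.mother_id) if member.mother_id else None
    if father is None or mother is None:
        return Phase.UNKNOWN
    fa, fb = father.carries(allele_a), father.carries(allele_b)
    ma, mb = mother.carries(allele_a), mother.carries(allele_b)
    if None in (fa, fb, ma, mb):
        return Phase.UNKNOWN
    if (fa and not fb and mb and not ma) or (fb and not fa and ma and not mb):
        return Phase.TRANS
    if (fa and fb and not ma and not mb) or (ma and mb and not fa and not fb):
        return Phase.CIS
    return Phase.UNKNOWN


def _pathogenic_dose(
    pedigree: Pedigree, member: PedigreeMember, allele_a: str, allele_b: str | None
) -> tuple[int | None, bool]:
    """(certain pathogenic-chromosome count capped at 2, phase_ambiguous).

    None when the member's genotypes are entirely unknown for the alleles.
    """
    ga = member.genotype(allele_a)
    if allele_b is None or allele_b == allele_a:
        if ga is None:
            return None, False
        return {Genotype.REF: 0, Genotype.HET: 1, Genotype.HOM: 2}[ga], False
    gb = member.genotype(allele_b)
    if ga is None and gb is None:
        return None, False
    doses = {Genotype.REF: 0, Genotype.HET: 1, Genotype.HOM: 2}
    da = doses.get(ga, 0)
    db = doses.get(gb, 0)
    if ga is Genotype.HET and gb is Genotype.HET:
        phase = phase_compound_het(pedigree, member.id, allele_a, allele_b)
        if phase is Phase.TRANS:
            return 2, False
        if phase is Phase.CIS:
            return 1, False
        return 1, True  # could be two in trans; ambiguous
    return min(2, da + db), False


def check_recessive(
    pedigree: Pedigree, allele_a: str, allele_b: str | None = None
) -> SegregationResult:
    """Co-segregation under autosomal recessive inheritance.

    ``allele_b`` names the second allele of a compound-heterozygous pair;
    omit it (or repeat ``allele_a``) for a simple homozygous model.
    """
    _validate(pedigree, [allele_a] if allele_b in (None, allele_a) else [allele_a, allele_b])
    violations: list[tuple[str, str]] = []
    warnings: list[str] = []
    for m in pedigree.values():
        if m.affected is None:
            continue
        dose, ambiguous = _pathogenic_dose(pedigree, m, allele_a, allele_b)
        if dose is None:
            continue
        if m.affected:
            if ambiguous:
                warnings.append(
                    f"{m.id}: het for both alleles with unresolved phase; "
                    "counted consistent pending confirmation"
                )
            elif dose < 2:
                violations.append((m.id, "affected member lacks two pathogenic alleles"))
        else:
            if not ambiguous and dose >= 2:
                violations.append((m.id, "unaffected member carries two pathogenic alleles"))
            elif ambiguous:
                warnings.append(
                    f"{m.id}: unaffected het/het with unresolved phase; not counted as violation"
                )
    return SegregationResult(
        consistent=not violations,
        violations=violations,
        model="recessive",
        warnings=warnings,
    )


def check_dominant(pedigree: Pedigree, allele: str) -> SegregationResult:
    """Co-segregation under fully penetrant autosomal dominant inheritance."""
    _validate(pedigree, [allele])
    violations: list[tuple[str, str]] = []
    for m in pedigree.values():
        if m.affected is None:
            continue
        carrier = m.carries(allele)
        if carrier is None:
            continue
        if m.affected and not carrier:
            violations.append((m.id, "affected member does not carry the allele"))
        elif not m.affected and carrier:
            violations.append((m.id, "unaffected member carries the allele"))
    return SegregationResult(
        consistent=not violations, violations=violations, model="dominant"
    )


# -- PED + genotype sidecar I/O ----------------------------------------------


def read_ped(path: str | Path, family_id: str | None = None) -> dict[str, PedigreeMember]:
    """Read a standard 6-column PED file into a pedigree mapping."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fam", "id", "father", "mother", "sex", "phenotype"],
        dtype=str,
        comment="#",
    )
    if family_id is not None:
        df = df[df["fam"] == family_id]
    ped: dict[str, PedigreeMember] = {}
    for r in df.itertuples(index=False):
        affected = {"1": False, "2": True}.get(str(r.phenotype))
        ped[str(r.id)] = PedigreeMember(
            id=str(r.id),
            father_id=None if str(r.father) in ("0", "nan") else str(r.father),
            mother_id=None if str(r.mother) in ("0", "nan") else str(r.mother),
            sex=str(r.sex),
            affected=affected,
        )
    return ped


def read_genotypes(path: str | Path, pedigree: dict[str, PedigreeMember]) -> None:
    """Attach genotypes from a sidecar TSV (member_id, allele_id, genotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for r in df.itertuples(index=False):
        mid = str(r.member_id)
        if mid in pedigree:
            pedigree[mid].genotypes[str(r.allele_id)] = Genotype(str(r.genotype))


def write_ped(
    pedigree: Pedigree, path: str | Path, family_id: str = "FAM1"
) -> None:
    with open(path, "w") as fh:
        for m in pedigree.values():
            pheno = "0" if m.affected is None else ("2" if m.affected else "1")
            fh.write(
                f"{family_id}\t{m.id}\t{m.father_id or 0}\t{m.mother_id or 0}\t{m.sex}\t{pheno}\n"
            )


def write_genotypes(pedigree: Pedigree, path: str | Path) -> None:
    rows = [
        (m.id, allele, g.value)
        for m in pedigree.values()
        for allele, g in sorted(m.genotypes.items())
    ]
    pd.DataFrame(rows, columns=["member_id", "allele_id", "genotype"]).to_csv(
        path, sep="\t", index=False
    )
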