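"""Founder-allele population statistics from cohort genotype counts.

Given counts of homozygotes, compound heterozygotes (one focal copy plus one
copy of a distinct pathogenic allele of the same gene) and simple
heterozygotes among N individuals, the focal allele frequency is

    (2·n_hom + n_compound_het + n_het) / 2N

and the carrier frequency is the fraction of individuals with at least one
copy.  Case/control allele frequencies are compared with a two-sided Fisher
exact test on the 2x2 table of focal vs other chromosomes (chromosomes
treated as independent draws — Hardy–Weinberg, unrelated individuals).  The
fraction of a cohort explained by a gene's pathogenic genotypes is reported
with a one-sided exact (Clopper–Pearson) lower binomial bound.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

__all__ = [
    "CohortGenotypeCounts",
    "CaseControlResult",
    "AttributableFraction",
    "allele_frequency",
    "carrier_frequency",
    "case_control_test",
    "attributable_fraction",
    "read_cohort_counts",
    "write_cohort_counts",
    "format_frequency",
]


@dataclass(frozen=True)
class CohortGenotypeCounts:
    """Genotype counts for one focal allele in one cohort."""

    n_individuals: int
    n_hom: int = 0
    n_compound_het: int = 0
    n_het: int = 0
    label: str = "cases"

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("cohort must contain at least one individual")
        if min(self.n_hom, self.n_compound_het, self.n_het) < 0:
            raise ValueError("genotype counts must be >= 0")
        if self.n_hom + self.n_compound_het + self.n_het > self.n_individuals:
            raise ValueError("genotype counts exceed cohort size")

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals

    @property
    def focal_allele_count(self) -> int:
        # a compound het contributes one focal chromosome; its second allele
        # counts toward that allele's own tally
        return 2 * self.n_hom + self.n_compound_het + self.n_het

    @property
    def n_carriers(self) -> int:
        return self.n_hom + self.n_compound_het + self.n_het


@dataclass(frozen=True)
class CaseControlResult:
    case_freq: float
    control_freq: float
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass(frozen=True)
class AttributableFraction:
    point: float
    lower_bound: float
    confidence: float
    n_solved: int
    n_total: int


def allele_frequency(c: CohortGenotypeCounts) -> float:
    """Focal allele frequency over the cohort's chromosomes."""
    return c.focal_allele_count / c.n_chromosomes


def carrier_frequency(c: CohortGenotypeCounts) -> float:
    """Fraction of individuals carrying at least one focal copy."""
    return c.n_carriers / c.n_individuals


def case_control_test(
    cases: CohortGenotypeCounts,
    controls: CohortGenotypeCounts,
    method: str = "fisher",
) -> CaseControlResult:
    """Compare focal allele frequencies between cohorts.

    ``method`` is "fisher" (two-sided exact, default) or "chi2".  The odds
    ratio is the sample ratio, with a Haldane–Anscombe 0.5 correction on
    every cell when any cell is zero.
    """
    a, b = cases.focal_allele_count, cases.n_chromosomes - cases.focal_allele_count
    c, d = controls.focal_allele_count, controls.n_chromosomes - controls.focal_allele_count
    table = [[a, b], [c, d]]
    if method == "fisher":
        p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    elif method == "chi2":
        p = float(stats.chi2_contingency(table, correction=False).pvalue)
    else:
        raise ValueError(f"unknown method: {method}")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return CaseControlResult(
        case_freq=allele_frequency(cases),
        control_freq=allele_frequency(controls),
        odds_ratio=odds,
        p_value=p,
        table=((a, b), (c, d)),
    )


def attributable_fraction(
    n_solved: int, n_total: int, confidence: float = 0.95
) -> AttributableFraction:
    """Share of a cohort explained by the gene, with an exact lower bound.

    The lower bound is the one-sided Clopper–Pearson limit at the given
    confidence, i.e. the smallest proportion not rejected by an exact
    binomial test.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_solved <= n_total:
        raise ValueError("need 0 <= n_solved <= n_total")
    point = n_solved / n_total
    if n_solved == 0:
        lower = 0.0
    else:
        lower = float(stats.beta.ppf(1 - confidence, n_solved, n_total - n_solved + 1))
    return AttributableFraction(
        point=point,
        lower_bound=lower,
        confidence=confidence,
        n_solved=n_solved,
        n_total=n_total,
    )


# -- I/O ----------------------------------------------------------------------

_COLUMNS = ["label", "n_individuals", "n_hom", "n_compound_het", "n_het"]


def read_cohort_counts(path: str | Path) -> dict[str, CohortGenotypeCounts]:
    """Read a counts TSV (label, n_individuals, n_hom, n_compound_het, n_het)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples(index=False):
        out[str(r.label)] = CohortGenotypeCounts(
            n_individuals=int(r.n_individuals),
            n_hom=int(r.n_hom),
            n_compound_het=int(r.n_compound_het),
            n_het=int(r.n_het),
            label=str(r.label),
        )
    return out


def write_cohort_counts(
    cohorts: Iterable[CohortGenotypeCounts], path: str | Path
) -> None:
    pd.DataFrame(
        [(c.label, c.n_individuals, c.n_hom, c.n_compound_het, c.n_het) for c in cohorts],
        columns=_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def format_frequency(c: CohortGenotypeCounts) -> str:
    """Frequency in 'f (k/2N)' layout, e.g. '0.337 (35/104)'."""
    f = allele_frequency(c)
    return f"{f:.3f} ({c.focal_allele_count}/{c.n_chromosomes})"
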