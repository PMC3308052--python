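"""Founder-allele statistics from cohort genotype counts.

Among 52 deaf probands of one population: 10 homozygous for the founder
missense allele, 6 compound heterozygous with a nonsense partner allele,
9 simple heterozygous; among 282 hearing controls, 16 heterozygous.
"""

from panelseeker import (
    CohortGenotypeCounts,
    allele_frequency,
    attributable_fraction,
    carrier_frequency,
    case_control_test,
)
from panelseeker.cohort_stats import format_frequency

cases = CohortGenotypeCounts(52, n_hom=10, n_compound_het=6, n_het=9, label="cases")
controls = CohortGenotypeCounts(282, n_het=16, label="controls")

print(f"allele frequency in deaf:     {format_frequency(cases)}")
print(f"allele frequency in controls: {format_frequency(controls)}")
print(f"carrier frequency (controls): {carrier_frequency(controls):.1%}")

fisher = case_control_test(cases, controls)
chi = case_control_test(cases, controls, method="chi2")
print(f"Fisher exact p = {fisher.p_value:.2e}, odds ratio = {fisher.odds_ratio:.1f}")
print(f"chi-square    p = {chi.p_value:.2e}")

af = attributable_fraction(20, 52)
print(f"attributable fraction: {af.point:.1%} "
      f"(exact one-sided 95% lower bound {af.lower_bound:.1%})")
# 20 of the 52 probands are explained by this gene's pathogenic genotypes.
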