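"""Test co-segregation of candidate alleles in a pedigree.

A recessive compound-heterozygous family: two affected sibs carry both
candidate alleles in trans (one inherited from each carrier parent), an
unaffected sib carries one.  A benign candidate carried by an unaffected
member fails the dominant check.
"""

from panelseeker import (
    Genotype,
    PedigreeMember,
    check_dominant,
    check_recessive,
    phase_compound_het,
)

G = Genotype
ped = {
    "F": PedigreeMember("F", affected=False, genotypes={"c.1810C>T": G.HET, "c.1939T>C": G.REF}),
    "M": PedigreeMember("M", affected=False, genotypes={"c.1810C>T": G.REF, "c.1939T>C": G.HET}),
    "S1": PedigreeMember("S1", "F", "M", affected=True,
                         genotypes={"c.1810C>T": G.HET, "c.1939T>C": G.HET}),
    "S2": PedigreeMember("S2", "F", "M", affected=True,
                         genotypes={"c.1810C>T": G.HET, "c.1939T>C": G.HET}),
    "S3": PedigreeMember("S3", "F", "M", affected=False,
                         genotypes={"c.1810C>T": G.HET, "c.1939T>C": G.REF}),
}

res = check_recessive(ped, "c.1810C>T", "c.1939T>C")
print(f"recessive compound het consistent: {res.consistent}")
print(f"phase in proband: {phase_compound_het(ped, 'S1', 'c.1810C>T', 'c.1939T>C').value}")

dom = check_dominant(ped, "c.1810C>T")
print(f"same allele under a dominant model: consistent={dom.consistent}, "
      f"violations={dom.violations}")
# The dominant model fails because both parents are unaffected carriers.
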