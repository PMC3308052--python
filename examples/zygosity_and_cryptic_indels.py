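"""Call zygosity from read counts and resolve a cryptic indel.

Variant allele fractions near 50% indicate heterozygosity and near 100%
homozygosity.  Two adjacent substitutions each supported by ~25% of reads
are the classic signature of an unaligned small deletion: they are merged
into one candidate and resolved against the local truth.
"""

from panelseeker import VariantObservation, call_zygosity, detect_cryptic_indels, resolve_indel

observations = [
    VariantObservation("chr9", 75_435_804, "C", "T", 643, 666, "D28C"),
    VariantObservation("chr10", 73_565_593, "G", "T", 0, 425, "Z686A"),
]
for o in observations:
    call = call_zygosity(o)
    print(f"{o.chrom}:{o.pos} {o.ref_allele}>{o.alt_allele}  "
          f"VAF {call.vaf:.0%} -> {call.state.value}")

weak = [
    VariantObservation("chr17", 18_022_486, "C", "G", 300, 100, "Z421A"),
    VariantObservation("chr17", 18_022_488, "G", "C", 310, 98, "Z421A"),
]
(candidate,) = detect_cryptic_indels(weak)
print(f"cryptic indel candidate spanning {candidate.span}, "
      f"{len(candidate.member_sites)} weak sites")
resolved = resolve_indel(
    candidate,
    window_start=18_022_400,
    window_seq="N" * 200,
    truth=[("chr17", 18_022_487, "ACG", "A")],
)
print(f"resolved to: {resolved.resolved_allele}  (a 2-bp deletion)")
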