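"""Design capture baits for a small exon panel.

Expands exons by the 40 bp intronic flank, tiles each target with 120-mer
baits in 3x centered tiling, drops baits overlapping repeats by more than
20 bp, and prints the design summary.
"""

from panelseeker import GenomicInterval, expand_targets, summarize_design
from panelseeker.panel_design import tile_panel

exons = [
    GenomicInterval("chr9", 75_435_700, 75_435_900),
    GenomicInterval("chr9", 75_436_100, 75_436_220),
    GenomicInterval("chr17", 18_022_400, 18_022_560),
]
repeats = [GenomicInterval("chr17", 18_022_540, 18_022_900)]

targets = expand_targets(exons, flank=40)
baits = tile_panel(targets, repeats=repeats)
report = summarize_design(targets, baits)

print(f"{len(exons)} exons -> {len(targets)} targets")
print(f"accepted baits: {report.n_baits}")
print(f"capture size:   {report.capture_size_bp} bp")
print(f"failed bases:   {report.failed_fraction:.1%}")
# The failed fraction is the share of target bases no accepted bait covers —
# here the bases of the last exon buried deep inside the repeat.
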