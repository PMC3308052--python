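"""Run the rare-variant filter cascade on a simulated proband.

Simulates an 11-proband study with one planted causal missense variant,
then filters one proband's raw calls through dbSNP -> conservation ->
cohort recurrence -> 1000 Genomes and prints the per-proband summary row.
"""

from panelseeker import (
    PlantedCausal,
    SimulationConfig,
    compute_recurrence,
    run_cascade,
    simulate_panel,
    simulate_proband_variants,
)

cfg = SimulationConfig(seed=11, n_genes=12, exons_per_gene=(4, 10), exon_length=(80, 250))
panel = simulate_panel(cfg)
study = simulate_proband_variants(panel, cfg, planted=PlantedCausal("P01"))
recurrence = compute_recurrence(study.tables)

annotated, summary = run_cascade(
    study.tables["P01"], study.stubs, panel.genes, recurrence, proband_id="P01"
)
print(f"raw calls: {len(annotated)}")
print(f"rare SNVs / private indels / total: "
      f"{summary.n_rare_snv} / {summary.n_private_indel} / {summary.n_rare_total}")
print(f"potentially functional: {summary.n_functional_total} "
      f"(missense {summary.n_missense}, nonsense {summary.n_nonsense}, "
      f"splice {summary.n_splice}, frameshift {summary.n_frameshift})")
planted = set(study.truth.causal)
survived = [a for a in annotated if a.passed and a.observation.key in planted]
print(f"planted causal variant survived the cascade: {bool(survived)}")
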