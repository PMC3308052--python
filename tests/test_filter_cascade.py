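"""The rare-variant filter cascade: individual filters, ordering, tabulation."""

import itertools

import numpy as np
import pytest

from panelseeker import (
    AnnotationStubs,
    Effect,
    PlantedCausal,
    VariantObservation,
    classify_effect,
    compute_recurrence,
    run_cascade,
    simulate_panel,
    simulate_proband_variants,
)
from panelseeker.filter_cascade import (
    filter_1000g,
    filter_conservation,
    filter_dbsnp,
    filter_recurrence,
)


def obs(chrom, pos, ref="C", alt="T", pid="D28C", ref_reads=100, var_reads=95):
    return VariantObservation(chrom, pos, ref, alt, ref_reads, var_reads, pid)


class TestIndividualFilters:
    def test_dbsnp_rules(self):
        key = ("chr9", 75435804, "C", "T")
        assert filter_dbsnp(key, {}) is True  # novel
        assert filter_dbsnp(key, {key: False}) is False  # known benign
        assert filter_dbsnp(key, {key: True}) is True  # clinically associated

    def test_conservation_boundary(self):
        v = obs("chr1", 100)
        assert filter_conservation(v, {("chr1", 100): 0.89}) is False
        assert filter_conservation(v, {("chr1", 100): 0.90}) is True  # strict "< 0.9" discarded

    def test_conservation_exempts_indels_and_missing(self):
        indel = obs("chr1", 100, ref="CT", alt="C")
        assert filter_conservation(indel, {("chr1", 100): 0.1}) is True
        assert filter_conservation(obs("chr1", 200), {}) is True  # missing -> pass, logged
        assert filter_conservation(obs("chr1", 200), {}, missing_passes=False) is False

    def test_recurrence_threshold(self):
        assert filter_recurrence(1) is True
        assert filter_recurrence(3) is True  # present in up to three probands
        assert filter_recurrence(4) is False  # four or more of the cohort

    def test_1000g_and_hearing_genomes(self):
        key = ("chr1", 100, "C", "T")
        assert filter_1000g(key, set()) is True
        assert filter_1000g(key, {key}) is False
        assert filter_1000g(key, set(), hearing_genomes={key}) is False

    def test_compute_recurrence_counts_probands_once(self):
        a = obs("chr1", 100, pid="P1")
        tables = {
            "P1": [a, obs("chr1", 100, pid="P1")],  # duplicate within a proband
            "P2": [obs("chr1", 100, pid="P2")],
            "P3": [obs("chr1", 200, pid="P3")],
        }
        rec = compute_recurrence(tables)
        assert rec[("chr1", 100, "C", "T")] == 2
        assert rec[("chr1", 200, "C", "T")] == 1


class TestFilterAlgebra:
    def _random_setting(self, rng):
        stubs = AnnotationStubs()
        variants = []
        for i in range(40):
            v = obs("chr1", 100 + 10 * i)
            variants.append(v)
            if rng.random() < 0.4:
                stubs.dbsnp[v.key] = bool(rng.random() < 0.3)
            if rng.random() < 0.8:
                stubs.phylop[(v.chrom, v.pos)] = float(rng.uniform(-2, 3))
            if rng.random() < 0.3:
                stubs.kgenomes.add(v.key)
        return variants, stubs

    def test_membership_filters_commute(self):
        """dbSNP, conservation and 1000G are independent predicates: any
        application order keeps the same survivor set."""
        rng = np.random.default_rng(3)
        variants, stubs = self._random_setting(rng)
        preds = {
            "dbsnp": lambda v: filter_dbsnp(v.key, stubs.dbsnp),
            "cons": lambda v: filter_conservation(v, stubs.phylop),
            "kg": lambda v: filter_1000g(v.key, stubs.kgenomes),
        }
        results = set()
        for order in itertools.permutations(preds):
            surv = list(variants)
            for name in order:
                surv = [v for v in surv if preds[name](v)]
            results.add(tuple(v.key for v in surv))
        assert len(results) == 1

    def test_filters_are_idempotent(self):
        rng = np.random.default_rng(4)
        variants, stubs = self._random_setting(rng)
        surv = [v for v in variants if filter_dbsnp(v.key, stubs.dbsnp)]
        assert [v for v in surv if filter_dbsnp(v.key, stubs.dbsnp)] == surv


class TestRunCascade:
    def test_survivor_trails_complete_and_output_subset(self, small_cfg):
        panel = simulate_panel(small_cfg)
        study = simulate_proband_variants(panel, small_cfg, planted=PlantedCausal("P01"))
        rec = compute_recurrence(study.tables)
        annotated, _ = run_cascade(
            study.tables["P01"], study.stubs, panel.genes, rec, proband_id="P01"
        )
        keys_in = {o.key for o in study.tables["P01"]}
        names = ["dbsnp", "conservation", "recurrence", "1000g"]
        for a in annotated:
            assert a.observation.key in keys_in
            applied = [n for n, _ in a.verdict_trail]
            assert applied == names[: len(applied)]
            if a.passed:
                assert applied == names
                assert all(ok for _, ok in a.verdict_trail)

    def test_planted_causal_survives_and_commons_fall(self, small_cfg):
        panel = simulate_panel(small_cfg)
        study = simulate_proband_variants(panel, small_cfg, planted=PlantedCausal("P01"))
        rec = compute_recurrence(study.tables)
        annotated, _ = run_cascade(
            study.tables["P01"], study.stubs, panel.genes, rec, proband_id="P01"
        )
        survivors = {a.observation.key for a in annotated if a.passed}
        for k in study.truth.causal:
            assert k in survivors
        for a in annotated:
            if a.passed:
                assert not (a.in_dbsnp and not a.clinically_associated)
                assert a.recurrence <= 3
                assert not a.in_1000g
        # the planted causal is annotated with its pathogenicity scores
        causal = [a for a in annotated if a.observation.key in set(study.truth.causal)]
        assert all(a.polyphen2_humvar is not None and a.polyphen2_humvar >= 0.85 for a in causal)

    def test_empty_table_gives_zero_counts(self):
        annotated, summary = run_cascade([], AnnotationStubs(), [], {}, proband_id="DQ3")
        assert annotated == []
        assert summary.n_rare_total == 0 and summary.n_functional_total == 0


class TestProbandSummaryFixture:
    def _pick(self, gene, effect, n, used):
        """Deterministically find n distinct SNVs of the wanted effect class."""
        out = []
        for p in gene.coding_positions():
            if (gene.chrom, p) in used:
                continue
            ref = gene.base(p)
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = VariantObservation(gene.chrom, p + 1, ref, alt, 100, 95, "D28C")
                if classify_effect(v, gene) is effect:
                    out.append(v)
                    used.add((gene.chrom, p))
                    break
            if len(out) == n:
                return out
        raise AssertionError(f"could not place {n} {effect} variants")

    def test_rare_variant_table_row_reconstruction(self, small_cfg):
        """A proband built to carry 24 rare SNVs (9 missense) and 14 private
        non-frameshift indels tabulates as 24/14/38 with 9 functional."""
        panel = simulate_panel(small_cfg)
        stubs = AnnotationStubs()
        used = set()
        variants = []
        genes = panel.genes

        missense = self._pick(genes[0], Effect.MISSENSE, 9, used)
        synonymous = self._pick(genes[1], Effect.SYNONYMOUS, 9, used)
        # 6 deep-intronic SNVs round out the 24 surviving rare SNVs
        intronic = []
        g = genes[2]
        (e1s, e1e), (e2s, _) = g.exons[0], g.exons[1]
        for i in range(6):
            p = e1e + 10 + i  # > 2 bp from any boundary
            intronic.append(VariantObservation(g.chrom, p + 1, g.base(p), "A" if g.base(p) != "A" else "C", 100, 95, "D28C"))
        # 14 private intronic indels: none touch CDS, so no frameshifts
        indels = []
        g2 = genes[3]
        anchor = g2.exons[0][1] + 15
        for i in range(14):
            p = anchor + 8 * i
            ref = g2.seq[p : p + 3]
            indels.append(VariantObservation(g2.chrom, p + 1, ref, ref[0], 100, 95, "D28C"))
        survivors = missense + synonymous + intronic + indels
        # conserved, novel, private
        for v in survivors:
            if v.is_snv:
                stubs.phylop[(v.chrom, v.pos)] = 1.5

        # chaff that every filter should remove
        chaff = []
        g3 = genes[4]
        benign = self._pick(g3, Effect.MISSENSE, 6, used)
        for i, v in enumerate(benign):
            chaff.append(v)
            stubs.phylop[(v.chrom, v.pos)] = 1.5
            if i < 2:
                stubs.dbsnp[v.key] = False  # known benign
            elif i < 4:
                stubs.phylop[(v.chrom, v.pos)] = 0.2  # non-conserved
            else:
                stubs.kgenomes.add(v.key)  # in 1000 Genomes

        recurrence = {v.key: 1 for v in survivors + chaff}
        recurrent = self._pick(genes[5], Effect.MISSENSE, 2, used)
        for v in recurrent:
            chaff.append(v)
            stubs.phylop[(v.chrom, v.pos)] = 1.5
            recurrence[v.key] = 5  # common in the cohort

        annotated, summary = run_cascade(
            survivors + chaff, stubs, genes, recurrence, proband_id="D28C"
        )
        assert summary.proband_id == "D28C"
        assert (summary.n_rare_snv, summary.n_private_indel, summary.n_rare_total) == (24, 14, 38)
        assert (
            summary.n_nonsense,
            summary.n_missense,
            summary.n_splice,
            summary.n_frameshift,
            summary.n_functional_total,
        ) == (0, 9, 0, 0, 9)
        assert sum(1 for a in annotated if a.passed) == 38
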