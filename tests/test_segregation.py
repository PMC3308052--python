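"""Co-segregation checks against exhaustive Mendelian-transmission oracles."""

import itertools

import numpy as np
import pytest

from panelseeker import (
    Genotype,
    PedigreeMember,
    Phase,
    check_dominant,
    check_recessive,
    phase_compound_het,
)
from panelseeker.segregation import read_genotypes, read_ped, write_genotypes, write_ped

G = Genotype
DOSE = {G.REF: 0, G.HET: 1, G.HOM: 2}


def member(mid, father=None, mother=None, affected=None, **genotypes):
    return PedigreeMember(
        id=mid,
        father_id=father,
        mother_id=mother,
        affected=affected,
        genotypes={k: v for k, v in genotypes.items()},
    )


# -- worked examples ----------------------------------------------------------


class TestRecessive:
    def test_compound_het_sibs_with_carrier_parents(self):
        """Two affected sibs het for both alleles, each parent het for one:
        classic recessive compound heterozygosity in trans."""
        ped = {
            "F": member("F", affected=False, a=G.HET, b=G.REF),
            "M": member("M", affected=False, a=G.REF, b=G.HET),
            "S1": member("S1", "F", "M", affected=True, a=G.HET, b=G.HET),
            "S2": member("S2", "F", "M", affected=True, a=G.HET, b=G.HET),
            "S3": member("S3", "F", "M", affected=False, a=G.HET, b=G.REF),
        }
        res = check_recessive(ped, "a", "b")
        assert res.consistent and res.violations == []

    def test_affected_hom_with_het_parent(self):
        ped = {
            "F": member("F", affected=False, a=G.HET),
            "M": member("M", affected=False, a=G.HET),
            "C": member("C", "F", "M", affected=True, a=G.HOM),
        }
        assert check_recessive(ped, "a").consistent

    def test_unaffected_hom_sib_violates(self):
        ped = {
            "F": member("F", affected=False, a=G.HET),
            "M": member("M", affected=False, a=G.HET),
            "C1": member("C1", "F", "M", affected=True, a=G.HOM),
            "C2": member("C2", "F", "M", affected=False, a=G.HOM),
        }
        res = check_recessive(ped, "a")
        assert not res.consistent
        assert res.violations == [("C2", "unaffected member carries two pathogenic alleles")]

    def test_unknown_genotypes_abstain(self):
        ped = {
            "C1": member("C1", affected=True, a=G.HOM),
            "C2": member("C2", affected=True),  # ungenotyped
        }
        assert check_recessive(ped, "a").consistent

    def test_lone_het_affected_violates(self):
        ped = {"C": member("C", affected=True, a=G.HET)}
        res = check_recessive(ped, "a")
        assert not res.consistent

    def test_unphased_double_het_warns_not_violates(self):
        ped = {"C": member("C", affected=True, a=G.HET, b=G.HET)}
        res = check_recessive(ped, "a", "b")
        assert res.consistent
        assert res.warnings

    def test_absent_allele_rejected(self):
        ped = {"C": member("C", affected=True, a=G.HOM)}
        with pytest.raises(ValueError):
            check_recessive(ped, "z")


class TestDominant:
    def test_two_generation_carriers(self):
        ped = {
            "GF": member("GF", affected=True, a=G.HET),
            "GM": member("GM", affected=False, a=G.REF),
            "P": member("P", "GF", "GM", affected=True, a=G.HET),
            "S": member("S", affected=False, a=G.REF),
            "C1": member("C1", "P", "S", affected=True, a=G.HET),
            "C2": member("C2", "P", "S", affected=False, a=G.REF),
        }
        assert check_dominant(ped, "a").consistent

    def test_unaffected_carrier_violates(self):
        ped = {
            "P": member("P", affected=True, a=G.HET),
            "C": member("C", affected=False, a=G.HET),
        }
        res = check_dominant(ped, "a")
        assert not res.consistent
        assert res.violations == [("C", "unaffected member carries the allele")]

    def test_affected_unknown_genotype_abstains(self):
        ped = {
            "P": member("P", affected=True, a=G.HET),
            "C": member("C", affected=True),
        }
        assert check_dominant(ped, "a").consistent


# -- trio phase: rule vs transmission enumeration -----------------------------


def _hap_pairs(da, db):
    """All phase configurations for given per-allele doses: unordered pairs of
    haplotypes (subsets of {a, b})."""
    subs = [frozenset(), frozenset("a"), frozenset("b"), frozenset("ab")]
    return [
        (h1, h2)
        for h1, h2 in itertools.product(subs, repeat=2)
        if (("a" in h1) + ("a" in h2), ("b" in h1) + ("b" in h2)) == (da, db)
    ]


def _phase_oracle(father_g, mother_g):
    """For a child het for both alleles: the set of feasible configurations
    (trans / cis) under all parental phase assignments and transmissions."""
    feasible = set()
    for f1, f2 in _hap_pairs(*father_g):
        for m1, m2 in _hap_pairs(*mother_g):
            for hf in (f1, f2):
                for hm in (m1, m2):
                    if ("a" in hf) + ("a" in hm) == 1 and ("b" in hf) + ("b" in hm) == 1:
                        both_on_one = ("a" in hf and "b" in hf) or ("a" in hm and "b" in hm)
                        feasible.add("cis" if both_on_one else "trans")
    return feasible


class TestPhase:
    def test_each_parent_one_allele_is_trans(self):
        ped = {
            "F": member("F", a=G.HET, b=G.REF),
            "M": member("M", a=G.REF, b=G.HET),
            "C": member("C", "F", "M", a=G.HET, b=G.HET),
        }
        assert phase_compound_het(ped, "C", "a", "b") is Phase.TRANS

    def test_one_parent_both_is_cis(self):
        ped = {
            "F": member("F", a=G.HET, b=G.HET),
            "M": member("M", a=G.REF, b=G.REF),
            "C": member("C", "F", "M", a=G.HET, b=G.HET),
        }
        assert phase_compound_het(ped, "C", "a", "b") is Phase.CIS

    def test_missing_parents_unknown(self):
        ped = {"C": member("C", a=G.HET, b=G.HET)}
        assert phase_compound_het(ped, "C", "a", "b") is Phase.UNKNOWN

    def test_rule_is_sound_against_enumeration_over_all_parent_genotypes(self):
        """Across all 81 parental genotype combinations, whenever the phase
        rule asserts trans or cis, transmission enumeration must force that
        same phase (the rule may abstain where enumeration could decide)."""
        gts = list(itertools.product(range(3), repeat=2))
        decided = 0
        for fg in gts:
            for mg in gts:
                ped = {
                    "F": member("F", a=list(G)[fg[0]], b=list(G)[fg[1]]),
                    "M": member("M", a=list(G)[mg[0]], b=list(G)[mg[1]]),
                    "C": member("C", "F", "M", a=G.HET, b=G.HET),
                }
                got = phase_compound_het(ped, "C", "a", "b")
                feasible = _phase_oracle(fg, mg)
                if got is Phase.TRANS:
                    assert feasible == {"trans"}, (fg, mg)
                    decided += 1
                elif got is Phase.CIS:
                    assert feasible == {"cis"}, (fg, mg)
                    decided += 1
        assert decided >= 4  # the canonical configurations are decided


# -- brute-force equivalence on random Mendelian pedigrees --------------------


def _random_pedigree(rng, n_extra_children=3, three_gen=False):
    """Members carry explicit haplotypes (subsets of {a,b}); genotypes follow."""

    def founder():
        return [
            frozenset(x for x, keep in (("a", rng.random() < 0.35), ("b", rng.random() < 0.35)) if keep)
            for _ in range(2)
        ]

    haps = {}
    parents = {}
    if three_gen:
        haps["GF"], haps["GM"] = founder(), founder()
        parents["P1"] = ("GF", "GM")
        haps["P1"] = [
            haps["GF"][int(rng.integers(2))],
            haps["GM"][int(rng.integers(2))],
        ]
        haps["P2"] = founder()
        core = ("P1", "P2")
    else:
        haps["P1"], haps["P2"] = founder(), founder()
        core = ("P1", "P2")
    for i in range(1 + n_extra_children):
        cid = f"C{i + 1}"
        parents[cid] = core
        haps[cid] = [
            haps[core[0]][int(rng.integers(2))],
            haps[core[1]][int(rng.integers(2))],
        ]

    ped = {}
    for mid, hp in haps.items():
        da = sum("a" in h for h in hp)
        db = sum("b" in h for h in hp)
        fa, mo = parents.get(mid, (None, None))
        ped[mid] = member(
            mid,
            father=fa,
            mother=mo,
            affected=bool(rng.random() < 0.5),
            a=list(G)[da],
            b=list(G)[db],
        )
    if not any(m.affected for m in ped.values()):
        ped["C1"].affected = True
    return ped, haps


def _oracle_single(ped, allele, model):
    viols = []
    for m in ped.values():
        if m.affected is None or m.genotype(allele) is None:
            continue
        d = DOSE[m.genotype(allele)]
        if model == "recessive":
            bad = (m.affected and d < 2) or (not m.affected and d == 2)
        else:
            bad = (m.affected and d == 0) or (not m.affected and d > 0)
        if bad:
            viols.append(m.id)
    return not viols


def _feasible_counts(ped, m):
    """Feasible pathogenic-chromosome counts for a member over all phase
    assignments consistent with (genotyped) parents."""
    da, db = DOSE[m.genotype("a")], DOSE[m.genotype("b")]
    child_pairs = _hap_pairs(da, db)
    father = ped.get(m.father_id) if m.father_id else None
    mother = ped.get(m.mother_id) if m.mother_id else None
    counts = set()
    if father and mother and None not in (
        father.genotype("a"),
        father.genotype("b"),
        mother.genotype("a"),
        mother.genotype("b"),
    ):
        fpairs = _hap_pairs(DOSE[father.genotype("a")], DOSE[father.genotype("b")])
        mpairs = _hap_pairs(DOSE[mother.genotype("a")], DOSE[mother.genotype("b")])
        for f1, f2 in fpairs:
            for m1, m2 in mpairs:
                for hf in (f1, f2):
                    for hm in (m1, m2):
                        if ("a" in hf) + ("a" in hm) == da and ("b" in hf) + ("b" in hm) == db:
                            counts.add((len(hf) > 0) + (len(hm) > 0))
    if not counts:
        counts = {(len(h1) > 0) + (len(h2) > 0) for h1, h2 in child_pairs}
    return counts


def _oracle_pair_recessive(ped):
    for m in ped.values():
        if m.affected is None:
            continue
        if m.genotype("a") is None and m.genotype("b") is None:
            continue
        counts = _feasible_counts(ped, m)
        if m.affected and 2 not in counts:
            return False
        if not m.affected and counts == {2}:
            return False
    return True


class TestBruteForceEquivalence:
    def test_single_allele_models_match_oracle(self):
        rng = np.random.default_rng(21)
        for trial in range(150):
            three_gen = bool(rng.random() < 0.5)
            ped, _ = _random_pedigree(
                rng,
                n_extra_children=int(rng.integers(1, 4 if three_gen else 6)),
                three_gen=three_gen,
            )
            assert len(ped) <= 8
            assert check_recessive(ped, "a").consistent == _oracle_single(ped, "a", "recessive")
            assert check_dominant(ped, "a").consistent == _oracle_single(ped, "a", "dominant")

    def test_compound_pair_sound_against_haplotype_enumeration(self):
        """The checker flags a violation only when haplotype enumeration also
        rules the pedigree out, and a clean (warning-free) pass implies the
        enumeration agrees; ambiguous-phase members may differ."""
        rng = np.random.default_rng(22)
        n_pass, n_fail = 0, 0
        for trial in range(200):
            three_gen = bool(rng.random() < 0.5)
            ped, _ = _random_pedigree(
                rng,
                n_extra_children=int(rng.integers(1, 4 if three_gen else 6)),
                three_gen=three_gen,
            )
            res = check_recessive(ped, "a", "b")
            want = _oracle_pair_recessive(ped)
            if not res.consistent:
                assert not want, ped
                n_fail += 1
            elif not res.warnings:
                assert want, ped
                n_pass += 1
        # both directions must actually be exercised
        assert n_pass >= 3 and n_fail >= 50

    def test_adding_ungenotyped_member_never_breaks_consistency(self):
        rng = np.random.default_rng(23)
        for trial in range(80):
            ped, _ = _random_pedigree(rng, n_extra_children=2)
            before = check_recessive(ped, "a").consistent
            ped["X"] = member("X", father="P1", mother="P2", affected=bool(rng.random() < 0.5))
            after = check_recessive(ped, "a").consistent
            if before:
                assert after


class TestPedIO:
    def test_round_trip(self, tmp_path):
        ped = {
            "F": member("F", affected=False, a=G.HET),
            "M": member("M", affected=False, a=G.HET),
            "C": member("C", "F", "M", affected=True, a=G.HOM),
        }
        ped["C"].sex = "2"
        write_ped(ped, tmp_path / "fam.ped")
        write_genotypes(ped, tmp_path / "geno.tsv")
        back = read_ped(tmp_path / "fam.ped")
        read_genotypes(tmp_path / "geno.tsv", back)
        assert back["C"].father_id == "F" and back["C"].affected is True
        assert back["C"].genotypes == {"a": G.HOM}
        assert check_recessive(back, "a").consistent
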