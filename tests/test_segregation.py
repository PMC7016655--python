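"""Recessive co-segregation (PP1, BS4)."""

import dataclasses

import pytest

from varclass.segregation import (
    EscalationRule,
    check_ar_cosegregation,
    evaluate_bs4,
    evaluate_pp1,
)
from varclass.types import (
    Affection,
    Genotype,
    Individual,
    Pedigree,
    Strength,
    ValidationError,
)


def _family(members_spec, family_id="F"):
    """members_spec: list of (iid, genotype, affection, is_child)."""
    members = []
    for iid, gt, aff, is_child in members_spec:
        members.append(Individual(
            iid, family_id,
            "dad" if is_child else None, "mum" if is_child else None,
            Sex_unknown, aff, gt))
    return Pedigree(family_id, tuple(members))


from varclass.types import Sex  # noqa: E402

Sex_unknown = Sex.unknown

PARENTS = [("dad", Genotype.het, Affection.unaffected, False),
           ("mum", Genotype.het, Affection.unaffected, False)]


class TestVerdicts:
    def test_two_affected_sibs_consistent(self):
        ped = _family(PARENTS + [
            ("c1", Genotype.hom_alt, Affection.affected, True),
            ("c2", Genotype.hom_alt, Affection.affected, True)])
        v = check_ar_cosegregation(ped)
        assert v.consistent
        assert v.n_affected_homalt == 2
        assert v.n_informative_unaffected == 2  # the carrier parents

    def test_unaffected_homozygote_breaks_consistency(self):
        ped = _family(PARENTS + [
            ("c1", Genotype.hom_alt, Affection.affected, True),
            ("c2", Genotype.hom_alt, Affection.unaffected, True)])
        v = check_ar_cosegregation(ped)
        assert not v.consistent and v.contradicted

    def test_affected_non_homozygote_breaks_consistency(self):
        ped = _family(PARENTS + [
            ("c1", Genotype.het, Affection.affected, True)])
        v = check_ar_cosegregation(ped)
        assert not v.consistent
        assert v.n_affected_other_genotype == 1

    def test_singleton_weakly_informative(self):
        ped = _family([("p", Genotype.hom_alt, Affection.affected, False)])
        v = check_ar_cosegregation(ped)
        assert v.consistent and v.n_informative_unaffected == 0

    def test_ungenotyped_family_uninformative(self):
        ped = _family([("p", Genotype.missing, Affection.affected, False)])
        v = check_ar_cosegregation(ped)
        assert not v.informative and not v.consistent

    def test_unknown_affection_excluded_from_counts(self):
        ped = _family(PARENTS + [
            ("c1", Genotype.hom_alt, Affection.affected, True),
            ("c2", Genotype.hom_alt, Affection.unknown, True)])
        v = check_ar_cosegregation(ped)
        assert v.consistent  # the unknown homozygote carries no weight

    def test_count_sum_bounded_by_genotyped(self):
        ped = _family(PARENTS + [
            ("c1", Genotype.hom_alt, Affection.affected, True),
            ("c2", Genotype.missing, Affection.affected, True),
            ("c3", Genotype.het, Affection.unknown, True)])
        v = check_ar_cosegregation(ped)
        total = (v.n_affected_homalt + v.n_affected_other_genotype
                 + v.n_unaffected_homalt + v.n_informative_unaffected)
        genotyped_known = sum(
            1 for m in ped if m.genotype is not Genotype.missing
            and m.affection is not Affection.unknown)
        assert total <= genotyped_known

    def test_adding_unaffected_het_never_flips(self):
        base = _family(PARENTS + [
            ("c1", Genotype.hom_alt, Affection.affected, True)])
        assert check_ar_cosegregation(base).consistent
        extended = _family(PARENTS + [
            ("c1", Genotype.hom_alt, Affection.affected, True),
            ("c2", Genotype.het, Affection.unaffected, True)])
        assert check_ar_cosegregation(extended).consistent


class TestPP1:
    def test_replica_families_all_consistent(self, replica):
        verdicts = []
        for study in replica.values():
            verdicts.extend(check_ar_cosegregation(p)
                            for p in study.pedigrees)
        assert len(verdicts) == 7  # families A-G
        assert all(v.consistent for v in verdicts)
        item = evaluate_pp1(verdicts)
        assert item.met and item.strength is Strength.supporting
        assert not evaluate_bs4(verdicts).met

    def test_mutating_any_unaffected_to_homozygote_suppresses_pp1(
            self, replica):
        """Flipping any one unaffected member to hom-alt makes that family
        inconsistent and withdraws the co-segregation criterion."""
        for study in replica.values():
            pedigrees = list(study.pedigrees)
            for i, ped in enumerate(pedigrees):
                for j, member in enumerate(ped.members):
                    if member.affection is not Affection.unaffected:
                        continue
                    mutated_member = dataclasses.replace(
                        member, genotype=Genotype.hom_alt)
                    members = list(ped.members)
                    members[j] = mutated_member
                    mutated = Pedigree(ped.family_id, tuple(members))
                    verdicts = [check_ar_cosegregation(p) for p in
                                pedigrees[:i] + [mutated] + pedigrees[i+1:]]
                    assert not verdicts[i].consistent
                    assert not evaluate_pp1(verdicts).met
                    assert evaluate_bs4(verdicts).met

    def test_empty_verdict_list_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_pp1([])

    def test_all_uninformative_not_met(self):
        ped = _family([("p", Genotype.missing, Affection.affected, False)])
        item = evaluate_pp1([check_ar_cosegregation(ped)])
        assert not item.met and "no informative families" in item.rationale

    def test_escalation_promotes_strength(self):
        peds = [
            _family(PARENTS + [
                ("c1", Genotype.hom_alt, Affection.affected, True)],
                family_id=f"F{i}")
            for i in range(5)
        ]
        verdicts = [check_ar_cosegregation(p) for p in peds]
        default = evaluate_pp1(verdicts)
        assert default.strength is Strength.supporting
        rule = EscalationRule(enabled=True)
        escalated = evaluate_pp1(verdicts, escalation=rule)
        assert escalated.strength is Strength.strong
        moderate = evaluate_pp1(verdicts[:3], escalation=rule)
        assert moderate.strength is Strength.moderate


class TestBS4:
    def test_affected_hom_ref_triggers(self):
        ped = _family(PARENTS + [
            ("c1", Genotype.hom_ref, Affection.affected, True)])
        assert evaluate_bs4([check_ar_cosegregation(ped)]).met

    def test_uninformative_only_not_met(self):
        ped = _family([("p", Genotype.missing, Affection.affected, False)])
        assert not evaluate_bs4([check_ar_cosegregation(ped)]).met
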