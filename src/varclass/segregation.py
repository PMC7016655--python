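"""Autosomal-recessive co-segregation: PP1 and its benign counterpart BS4.

Under a fully penetrant recessive model, every affected family member must be
homozygous for the candidate allele and no unaffected member may be. Each
pedigree yields a verdict with the counts behind it; verdicts aggregate into
PP1 (co-segregation supports pathogenicity) or BS4 (segregation contradicts
it). Members with unknown affection status or missing genotype are excluded
from all counts. Reduced penetrance is deliberately not modeled: a single
unaffected homozygote breaks consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .types import (
    Affection,
    EvidenceItem,
    Genotype,
    Pedigree,
    Strength,
    ValidationError,
)


@dataclass(frozen=True)
class EscalationRule:
    """When to promote PP1 beyond supporting strength.

    Escalation is disabled by default: within a single cohort of one ancestry
    the guideline-style promotion to moderate/strong (more families, more
    informative meioses) is not justified, but the thresholds are exposed so
    multi-cohort users can enable it.
    """

    enabled: bool = False
    moderate_min_families: int = 3
    moderate_min_informative: int = 6
    strong_min_families: int = 5


@dataclass(frozen=True)
class FamilySegregationVerdict:
    family_id: str
    consistent: bool
    n_affected_homalt: int
    n_affected_other_genotype: int
    n_unaffected_homalt: int
    n_informative_unaffected: int
    informative: bool = True

    @property
    def contradicted(self) -> bool:
        """True when the pedigree actively argues against pathogenicity."""
        return (self.n_affected_other_genotype > 0
                or self.n_unaffected_homalt > 0)


def check_ar_cosegregation(pedigree: Pedigree) -> FamilySegregationVerdict:
    """Score one pedigree against the recessive co-segregation model.

    Consistent iff at least one affected homozygote is present, no affected
    member carries any other genotype, and no unaffected member is homozygous.
    A pedigree with no genotyped member of known affection is uninformative.
    """
    n_aff_hom = n_aff_other = n_unaff_hom = n_inf_unaff = 0
    any_counted = False
    for m in pedigree:
        if m.genotype is Genotype.missing or m.affection is Affection.unknown:
            continue
        any_counted = True
        if m.affection is Affection.affected:
            if m.genotype is Genotype.hom_alt:
                n_aff_hom += 1
            else:
                n_aff_other += 1
        else:
            if m.genotype is Genotype.hom_alt:
                n_unaff_hom += 1
            else:
                n_inf_unaff += 1
    if not any_counted:
        return FamilySegregationVerdict(
            family_id=pedigree.family_id, consistent=False,
            n_affected_homalt=0, n_affected_other_genotype=0,
            n_unaffected_homalt=0, n_informative_unaffected=0,
            informative=False)
    consistent = n_aff_other == 0 and n_unaff_hom == 0 and n_aff_hom >= 1
    return FamilySegregationVerdict(
        family_id=pedigree.family_id, consistent=consistent,
        n_affected_homalt=n_aff_hom, n_affected_other_genotype=n_aff_other,
        n_unaffected_homalt=n_unaff_hom, n_informative_unaffected=n_inf_unaff)


def evaluate_pp1(verdicts: Sequence[FamilySegregationVerdict],
                 escalation: EscalationRule = EscalationRule()
                 ) -> EvidenceItem:
    """PP1: the variant co-segregates with disease across families.

    Met iff at least one family is consistent and no family contradicts the
    recessive model. Strength defaults to supporting; with escalation enabled
    it rises to moderate or strong as consistent families and informative
    unaffected carriers accumulate.
    """
    if not verdicts:
        raise ValidationError("evaluate_pp1 requires at least one verdict")
    informative = [v for v in verdicts if v.informative]
    if not informative:
        return EvidenceItem("PP1", met=False,
                            rationale="no informative families")
    contradicting = [v.family_id for v in informative if v.contradicted]
    consistent = [v for v in informative if v.consistent]
    met = bool(consistent) and not contradicting
    n_inf_unaff = sum(v.n_informative_unaffected for v in consistent)
    strength = Strength.supporting
    if met and escalation.enabled:
        if len(consistent) >= escalation.strong_min_families:
            strength = Strength.strong
        elif (len(consistent) >= escalation.moderate_min_families
              and n_inf_unaff >= escalation.moderate_min_informative):
            strength = Strength.moderate
    if contradicting:
        rationale = (f"segregation contradicted in family(ies) "
                     f"{sorted(contradicting)}")
    else:
        rationale = (f"{len(consistent)}/{len(informative)} informative "
                     f"families consistent with recessive segregation; "
                     f"{n_inf_unaff} informative unaffected carriers")
    return EvidenceItem("PP1", met=met, rationale=rationale,
                        strength=strength)


def evaluate_bs4(verdicts: Sequence[FamilySegregationVerdict]) -> EvidenceItem:
    """BS4: lack of segregation — an affected non-homozygote or an
    unaffected homozygote was observed in some family."""
    bad = [v.family_id for v in verdicts if v.contradicted]
    if bad:
        rationale = f"non-segregating family(ies): {sorted(bad)}"
    else:
        rationale = "no family contradicts recessive segregation"
    return EvidenceItem("BS4", met=bool(bad), rationale=rationale)
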