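"""Synthetic cohorts, pedigrees and predictor profiles.

Emulates the structure of a recessive-retinopathy case-control study: a
proband cohort split into an LCA/EORD stratum and an other-IRD stratum, with
an exact number of homozygous carriers of the candidate variant planted in
each stratum, plus nuclear-family pedigrees for the carrier families (carrier
parents, homozygous affected children, Mendelian sibling genotypes). Planted
exposure counts are exact, not sampled, so 2x2 tables are recoverable from the
spec; everything else (sibship sizes, sibling genotypes, carrier het
genotypes) is drawn from a seeded generator and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np

from .insilico import (
    CANONICAL_TOOLS,
    CategoricalRule,
    Call,
    CutoffDirection,
    DEFAULT_THRESHOLDS,
    NumericRule,
    PredictionProfile,
)
from .types import (
    Affection,
    CohortProband,
    DiagnosisGroup,
    Genotype,
    Individual,
    Pedigree,
    Sex,
    ValidationError,
)

#: Distribution over the number of children in a carrier nuclear family.
DEFAULT_FAMILY_STRUCTURE: dict[int, float] = {2: 0.5, 3: 0.3, 4: 0.2}


@dataclass(frozen=True)
class CohortSpec:
    """Study design for one synthetic cohort.

    ``n_exposed_cases`` / ``n_exposed_controls`` homozygotes are planted
    exactly; remaining probands are het with probability
    ``carrier_frequency``, else hom-ref. ``penetrance`` is the probability
    that a homozygous child is affected (1.0 reproduces the fully penetrant
    presentation; lower values create unaffected homozygotes that break
    co-segregation, on purpose).
    """

    n_case_families: int
    n_control_families: int
    n_exposed_cases: int
    n_exposed_controls: int = 0
    family_structure: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_STRUCTURE))
    carrier_frequency: float = 0.0
    penetrance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exposed_cases > self.n_case_families:
            raise ValidationError(
                "n_exposed_cases exceeds n_case_families")
        if self.n_exposed_controls > self.n_control_families:
            raise ValidationError(
                "n_exposed_controls exceeds n_control_families")
        if not 0 <= self.carrier_frequency <= 1:
            raise ValidationError("carrier_frequency must be in [0,1]")
        if not 0 <= self.penetrance <= 1:
            raise ValidationError("penetrance must be in [0,1]")
        total = sum(self.family_structure.values())
        if abs(total - 1.0) > 1e-9 or min(self.family_structure) < 1:
            raise ValidationError(
                "family_structure must be a distribution over sizes >= 1")


def _nuclear_family(family_id: str, n_children: int, rng: np.random.Generator,
                    penetrance: float) -> Pedigree:
    """Carrier-parent nuclear family with a homozygous affected proband.

    The first child is the proband (hom-alt, affected). Remaining children
    draw genotypes from the het x het Mendelian distribution (1/4, 1/2, 1/4);
    homozygous children are affected with probability ``penetrance``.
    """
    father = Individual(f"{family_id}-I:1", family_id, None, None,
                        Sex.male, Affection.unaffected, Genotype.het)
    mother = Individual(f"{family_id}-I:2", family_id, None, None,
                        Sex.female, Affection.unaffected, Genotype.het)
    members = [father, mother]
    for k in range(1, n_children + 1):
        iid = f"{family_id}-II:{k}"
        sex = Sex.male if rng.random() < 0.5 else Sex.female
        if k == 1:
            genotype, affection = Genotype.hom_alt, Affection.affected
        else:
            u = rng.random()
            genotype = (Genotype.hom_alt if u < 0.25
                        else Genotype.het if u < 0.75 else Genotype.hom_ref)
            if genotype is Genotype.hom_alt:
                affection = (Affection.affected
                             if rng.random() < penetrance
                             else Affection.unaffected)
            else:
                affection = Affection.unaffected
        members.append(Individual(iid, family_id, father.individual_id,
                                  mother.individual_id, sex, affection,
                                  genotype))
    return Pedigree(family_id=family_id, members=tuple(members))


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[CohortProband], list[Pedigree]]:
    """Generate a proband cohort and pedigrees for the exposed families.

    Exposure counts match the spec exactly; the exposed families are the
    first ones in each stratum so the output is deterministic under a fixed
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = np.array(sorted(spec.family_structure))
    probs = np.array([spec.family_structure[s] for s in sizes])
    cohort: list[CohortProband] = []
    pedigrees: list[Pedigree] = []
    strata = [
        (DiagnosisGroup.lca_eord, spec.n_case_families, spec.n_exposed_cases,
         "CASE"),
        (DiagnosisGroup.other_ird, spec.n_control_families,
         spec.n_exposed_controls, "CTRL"),
    ]
    for group, n_families, n_exposed, prefix in strata:
        for i in range(n_families):
            fam = f"{prefix}{i + 1:04d}"
            if i < n_exposed:
                n_children = int(rng.choice(sizes, p=probs))
                ped = _nuclear_family(fam, n_children, rng, spec.penetrance)
                pedigrees.append(ped)
                genotype = Genotype.hom_alt
                proband_id = f"{fam}-II:1"
            else:
                genotype = (Genotype.het
                            if rng.random() < spec.carrier_frequency
                            else Genotype.hom_ref)
                proband_id = f"{fam}-P"
            cohort.append(CohortProband(proband_id, fam, group, genotype))
    return cohort, pedigrees


def generate_null_cohorts(n_reps: int, n_families: int, case_fraction: float,
                          exposure_prob: float, seed: int = 0
                          ) -> Iterator[list[CohortProband]]:
    """Cohorts with exposure independent of diagnosis group (the null).

    Group margins are fixed (``round(n_families * case_fraction)`` cases);
    each proband is homozygous with probability ``exposure_prob`` regardless
    of group. Per-replicate generators derive from the master seed, so any
    replicate is reproducible independently of how many were consumed.
    """
    if not 0 <= exposure_prob <= 1 or not 0 <= case_fraction <= 1:
        raise ValidationError("probabilities must be in [0,1]")
    n_cases = round(n_families * case_fraction)
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    for rep, child_seed in enumerate(seeds):
        rng = np.random.default_rng(child_seed)
        exposed = rng.random(n_families) < exposure_prob
        cohort = []
        for i in range(n_families):
            group = (DiagnosisGroup.lca_eord if i < n_cases
                     else DiagnosisGroup.other_ird)
            genotype = Genotype.hom_alt if exposed[i] else Genotype.hom_ref
            fam = f"R{rep}F{i + 1:04d}"
            cohort.append(CohortProband(f"{fam}-P", fam, group, genotype))
        yield cohort


_DAMAGING_LABEL = "Damaging"
_BENIGN_LABEL = "Benign"
# Per-tool label/score ranges used when emitting synthetic predictor output.
_CATEGORICAL_SIDES = {
    "PolyPhen2": ("Probably damaging", "Benign"),
    "MutationAssessor": ("Medium impact", "Neutral"),
    "MutationTaster": ("Disease-causing", "Polymorphism"),
    "LRT": ("Deleterious", "Neutral"),
    "SIFT": (_DAMAGING_LABEL, "Tolerated"),
}
_NUMERIC_RANGES = {
    "DANN": ((0.9, 1.0), (0.0, 0.9)),
    "CADD": ((20.0, 45.0), (0.0, 20.0)),
    "PhyloP20way": ((0.5, 1.199), (-3.0, 0.5)),
    "PhyloP100way": ((2.0, 10.003), (-5.0, 2.0)),
    "GERP_RS": ((4.0, 6.17), (-5.0, 4.0)),
}


def generate_predictor_profile(ground_truth: str, noise: float = 0.0,
                               seed: int = 0) -> PredictionProfile:
    """A 16-tool profile whose calls follow the ground truth up to noise.

    Each tool lands on the ground-truth side with probability ``1 - noise``
    (noise <= 0.5). A noise of ~0.06 reproduces a 15-of-16 consensus in
    expectation.
    """
    if ground_truth not in ("deleterious_like", "benign_like"):
        raise ValidationError(
            "ground_truth must be 'deleterious_like' or 'benign_like'")
    if not 0 <= noise <= 0.5:
        raise ValidationError("noise must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    truth_deleterious = ground_truth == "deleterious_like"
    values: dict[str, object] = {}
    for tool in CANONICAL_TOOLS:
        deleterious = truth_deleterious ^ (rng.random() < noise)
        rule = DEFAULT_THRESHOLDS[tool]
        if isinstance(rule, NumericRule):
            (dlo, dhi), (blo, bhi) = _NUMERIC_RANGES[tool]
            lo, hi = (dlo, dhi) if deleterious else (blo, bhi)
            score = float(rng.uniform(lo, hi))
            # keep draws strictly on the intended side of the cutoff
            if deleterious and score <= rule.cutoff:
                score = np.nextafter(rule.cutoff, hi)
            values[tool] = score
        else:
            dam, ben = _CATEGORICAL_SIDES.get(
                tool, (_DAMAGING_LABEL, _BENIGN_LABEL))
            values[tool] = dam if deleterious else ben
    return PredictionProfile(values)
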