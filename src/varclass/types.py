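"""Shared domain types for ACMG/AMP variant classification.

The vocabulary here follows clinical variant-curation practice: a candidate
variant is described in HGVS notation against a declared transcript, evidence
for or against pathogenicity is expressed as coded criteria (PVS1, PS1-PS4,
PM1-PM6, PP1-PP5 on the pathogenic side; BA1, BS1-BS4, BP1-BP7 on the benign
side), and the final verdict is one of five tiers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ParseError(ValueError):
    """Malformed file content; message names the offending line."""


class ConfigurationError(ValueError):
    """A threshold table or run configuration is inconsistent."""


class Consequence(str, enum.Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    splice = "splice"
    synonymous = "synonymous"
    other = "other"


class InheritanceMode(str, enum.Enum):
    autosomal_recessive = "autosomal_recessive"
    autosomal_dominant = "autosomal_dominant"
    x_linked = "x_linked"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Affection(str, enum.Enum):
    affected = "affected"
    unaffected = "unaffected"
    unknown = "unknown"


class Genotype(str, enum.Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"


class DiagnosisGroup(str, enum.Enum):
    lca_eord = "lca_eord"
    other_ird = "other_ird"


class Direction(str, enum.Enum):
    pathogenic = "pathogenic"
    benign = "benign"


class Strength(str, enum.Enum):
    stand_alone = "stand_alone"
    very_strong = "very_strong"
    strong = "strong"
    moderate = "moderate"
    supporting = "supporting"


class Tier(str, enum.Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    uncertain_significance = "uncertain_significance"
    likely_benign = "likely_benign"
    benign = "benign"


#: All ACMG/AMP criterion codes with their default evidence strength.
DEFAULT_STRENGTH: dict[str, Strength] = {
    "PVS1": Strength.very_strong,
    **{f"PS{i}": Strength.strong for i in range(1, 5)},
    **{f"PM{i}": Strength.moderate for i in range(1, 7)},
    **{f"PP{i}": Strength.supporting for i in range(1, 6)},
    "BA1": Strength.stand_alone,
    **{f"BS{i}": Strength.strong for i in range(1, 5)},
    **{f"BP{i}": Strength.supporting for i in range(1, 8)},
}


def criterion_direction(code: str) -> Direction:
    """Direction is determined by the code prefix: P* pathogenic, B* benign."""
    if code not in DEFAULT_STRENGTH:
        raise ValidationError(f"unknown ACMG/AMP criterion code: {code!r}")
    return Direction.pathogenic if code.startswith("P") else Direction.benign


@dataclass(frozen=True)
class EvidenceItem:
    """One ACMG/AMP criterion evaluation.

    ``strength`` defaults to the code's guideline strength but may be
    overridden (strength modulation, e.g. co-segregation promoted from
    supporting to moderate when many families are informative).
    """

    code: str
    met: bool
    rationale: str = ""
    strength: Optional[Strength] = None

    def __post_init__(self) -> None:
        criterion_direction(self.code)  # validates the code
        if self.strength is None:
            object.__setattr__(self, "strength", DEFAULT_STRENGTH[self.code])

    @property
    def direction(self) -> Direction:
        return criterion_direction(self.code)


@dataclass(frozen=True)
class VariantRecord:
    """A candidate variant in HGVS notation against a declared transcript."""

    gene: str
    transcript: str
    cdna_change: str
    protein_change: str
    consequence: Consequence = Consequence.missense
    inheritance_mode: InheritanceMode = InheritanceMode.autosomal_recessive

    def __post_init__(self) -> None:
        if not self.cdna_change.startswith("c."):
            raise ValidationError(
                f"cdna_change must start with 'c.': {self.cdna_change!r}")
        if not self.protein_change.startswith("p."):
            raise ValidationError(
                f"protein_change must start with 'p.': {self.protein_change!r}")

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.cdna_change} ({self.protein_change})"


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Sex
    affection: Affection
    genotype: Genotype


@dataclass(frozen=True)
class Pedigree:
    """A family: members share a family id and have acyclic parent links."""

    family_id: str
    members: tuple[Individual, ...]

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"duplicate individual id(s) in family {self.family_id}: {dup}")
        for m in self.members:
            if m.family_id != self.family_id:
                raise ValidationError(
                    f"member {m.individual_id} carries family id "
                    f"{m.family_id!r}, expected {self.family_id!r}")
        by_id = {m.individual_id: m for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in by_id:
                    raise ValidationError(
                        f"parent {pid!r} of {m.individual_id} not found in "
                        f"family {self.family_id}")
        self._check_acyclic(by_id)

    def _check_acyclic(self, by_id: dict[str, Individual]) -> None:
        for start in by_id:
            seen = {start}
            frontier = [start]
            while frontier:
                cur = by_id[frontier.pop()]
                for pid in (cur.father_id, cur.mother_id):
                    if pid is None:
                        continue
                    if pid in seen and pid == start:
                        raise ValidationError(
                            f"parental cycle involving {start} in family "
                            f"{self.family_id}")
                    if pid not in seen:
                        seen.add(pid)
                        frontier.append(pid)

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CohortProband:
    """The index patient of one family; analysis unit of the 2x2 table."""

    proband_id: str
    family_id: str
    diagnosis_group: DiagnosisGroup
    genotype: Genotype


@dataclass(frozen=True)
class Classification:
    """Five-tier verdict plus the combining rule that produced it."""

    tier: Tier
    rule_fired: str
    evidence_trace: tuple[EvidenceItem, ...] = ()
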