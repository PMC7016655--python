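"""ACMG/AMP evidence combiner: met criteria in, five-tier verdict out.

The combining rules are the standard guideline rule set. Evidence is tallied
by (direction, strength); rules are evaluated in a fixed order (pathogenic,
likely pathogenic, benign, likely benign) and the first satisfied rule on each
side is reported. The tier itself is order-independent; only the ``rule_fired``
label depends on the ordering. A tally satisfying both a pathogenic-side and a
benign-side rule is conflicting and resolves to uncertain significance.

Strength-modulated items (e.g. co-segregation promoted from supporting to
moderate) count in the bucket of their assigned strength, not their default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .types import (
    Classification,
    Direction,
    EvidenceItem,
    Strength,
    Tier,
    ValidationError,
)


@dataclass(frozen=True)
class EvidenceTally:
    """Counts of met evidence by direction and strength.

    Pathogenic side: very strong / strong / moderate / supporting. Benign
    side: stand-alone (BA1), strong (BS), supporting (BP). ``codes`` records
    which criteria contributed, to reject duplicates and support what-if
    queries.
    """

    n_very_strong: int = 0
    n_strong: int = 0
    n_moderate: int = 0
    n_supporting: int = 0
    n_ba: int = 0
    n_bs: int = 0
    n_bp: int = 0
    codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        counts = (self.n_very_strong, self.n_strong, self.n_moderate,
                  self.n_supporting, self.n_ba, self.n_bs, self.n_bp)
        if min(counts) < 0:
            raise ValidationError("tally counts must be >= 0")

    def add(self, code: str, direction: Direction,
            strength: Strength) -> "EvidenceTally":
        if code in self.codes:
            raise ValidationError(f"criterion {code} already tallied")
        kw = dict(
            n_very_strong=self.n_very_strong, n_strong=self.n_strong,
            n_moderate=self.n_moderate, n_supporting=self.n_supporting,
            n_ba=self.n_ba, n_bs=self.n_bs, n_bp=self.n_bp,
            codes=self.codes | {code})
        if direction is Direction.pathogenic:
            key = {
                Strength.very_strong: "n_very_strong",
                Strength.strong: "n_strong",
                Strength.moderate: "n_moderate",
                Strength.supporting: "n_supporting",
            }.get(strength)
            if key is None:
                raise ValidationError(
                    f"{code}: strength {strength.value} is not valid on the "
                    f"pathogenic side")
        else:
            key = {
                Strength.stand_alone: "n_ba",
                Strength.very_strong: "n_bs",
                Strength.strong: "n_bs",
                Strength.moderate: "n_bp",
                Strength.supporting: "n_bp",
            }[strength]
        kw[key] += 1
        return EvidenceTally(**kw)


def tally(evidence: Sequence[EvidenceItem]) -> EvidenceTally:
    """Count met evidence items; each criterion code at most once."""
    out = EvidenceTally()
    for item in evidence:
        if not item.met:
            continue
        out = out.add(item.code, item.direction, item.strength)
    return out


# (tier, rule id, predicate) in fixed evaluation order. vs/s/m/p are the
# pathogenic-side counts; ba/bs/bp the benign-side counts.
_PATHOGENIC_RULES = [
    ("P1", lambda t: t.n_very_strong >= 1 and t.n_strong >= 1),
    ("P2", lambda t: t.n_very_strong >= 1 and t.n_moderate >= 2),
    ("P3", lambda t: t.n_very_strong >= 1 and t.n_moderate >= 1
        and t.n_supporting >= 1),
    ("P4", lambda t: t.n_very_strong >= 1 and t.n_supporting >= 2),
    ("P5", lambda t: t.n_strong >= 2),
    ("P6", lambda t: t.n_strong >= 1 and t.n_moderate >= 3),
    ("P7", lambda t: t.n_strong >= 1 and t.n_moderate >= 2
        and t.n_supporting >= 2),
    ("P8", lambda t: t.n_strong >= 1 and t.n_moderate >= 1
        and t.n_supporting >= 4),
]

_LIKELY_PATHOGENIC_RULES = [
    ("LP1", lambda t: t.n_very_strong >= 1 and t.n_moderate >= 1),
    ("LP2", lambda t: t.n_strong >= 1 and t.n_moderate >= 1),
    ("LP3", lambda t: t.n_strong >= 1 and t.n_supporting >= 2),
    ("LP4", lambda t: t.n_moderate >= 3),
    ("LP5", lambda t: t.n_moderate >= 2 and t.n_supporting >= 2),
    ("LP6", lambda t: t.n_moderate >= 1 and t.n_supporting >= 4),
]

_BENIGN_RULES = [
    ("B1", lambda t: t.n_ba >= 1),
    ("B2", lambda t: t.n_bs >= 2),
]

_LIKELY_BENIGN_RULES = [
    ("LB1", lambda t: t.n_bs >= 1 and t.n_bp >= 1),
    ("LB2", lambda t: t.n_bp >= 2),
]


def _first_fired(rules, t: EvidenceTally) -> Optional[str]:
    for rule_id, pred in rules:
        if pred(t):
            return rule_id
    return None


def combine(t: EvidenceTally,
            evidence_trace: Sequence[EvidenceItem] = ()) -> Classification:
    """Apply the combining rules to a tally and return the five-tier verdict.

    The verdict is a deterministic function of the multiset of met
    (direction, strength) pairs. If both sides fire, the result is uncertain
    significance with ``rule_fired = "conflicting"``; if neither fires,
    ``"default_vus"``.
    """
    path_rule = _first_fired(_PATHOGENIC_RULES, t)
    path_tier = Tier.pathogenic
    if path_rule is None:
        path_rule = _first_fired(_LIKELY_PATHOGENIC_RULES, t)
        path_tier = Tier.likely_pathogenic
    benign_rule = _first_fired(_BENIGN_RULES, t)
    benign_tier = Tier.benign
    if benign_rule is None:
        benign_rule = _first_fired(_LIKELY_BENIGN_RULES, t)
        benign_tier = Tier.likely_benign

    trace = tuple(e for e in evidence_trace if e.met)
    if path_rule and benign_rule:
        return Classification(Tier.uncertain_significance, "conflicting",
                              trace)
    if path_rule:
        return Classification(path_tier, path_rule, trace)
    if benign_rule:
        return Classification(benign_tier, benign_rule, trace)
    return Classification(Tier.uncertain_significance, "default_vus", trace)


def what_if(t: EvidenceTally, additional: tuple[str, Strength]
            ) -> Classification:
    """Classification after adding one not-yet-met criterion to the tally.

    Used to report escalation paths, e.g. "with PM3 the verdict would become
    pathogenic". Adding a code already in the tally is an error.
    """
    from .types import criterion_direction

    code, strength = additional
    augmented = t.add(code, criterion_direction(code), strength)
    return combine(augmented)


def reweight(evidence: Sequence[EvidenceItem], code: str,
             strength: Strength) -> Classification:
    """Classification after promoting/demoting one met criterion's strength."""
    adjusted = []
    found = False
    for item in evidence:
        if item.code == code and item.met:
            adjusted.append(EvidenceItem(code, met=True,
                                         rationale=item.rationale,
                                         strength=strength))
            found = True
        else:
            adjusted.append(item)
    if not found:
        raise ValidationError(f"criterion {code} is not met; cannot reweight")
    return combine(tally(adjusted), adjusted)
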