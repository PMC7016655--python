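"""In-silico predictor consensus: PP3 (deleterious) and BP4 (benign).

Sixteen predictors are consulted: protein-impact classifiers (PolyPhen2, SIFT,
PROVEAN, LRT, MutationTaster, MutationAssessor, FATHMM, FATHMM-MKL, M-CAP,
MetaSVM, MetaLR), genome-wide scores (DANN, CADD) and conservation metrics
(PhyloP 20-way, PhyloP 100-way, GERP RS). Each tool's raw output — a label or
a score — is mapped to a deleterious / benign / ambiguous call through a
per-tool threshold table, and PP3 fires when the deleterious fraction of the
mapped calls reaches a consensus threshold tau. Conservation-only tools count
in the same pool as impact predictors: conservation of the residue and
predicted functional damage are treated as interchangeable lines of
computational support.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Union

from .types import ConfigurationError, EvidenceItem, ParseError, ValidationError

RawValue = Union[float, int, str]


class Call(str, enum.Enum):
    deleterious = "deleterious"
    benign = "benign"
    ambiguous = "ambiguous"


class CutoffDirection(str, enum.Enum):
    higher_is_damaging = "higher_is_damaging"
    lower_is_damaging = "lower_is_damaging"


@dataclass(frozen=True)
class CategoricalRule:
    """Label -> call mapping; matching is case-insensitive on stripped text."""

    mapping: Mapping[str, Call]

    def __call__(self, value: RawValue) -> Call:
        label = str(value).strip().lower()
        return self.mapping.get(label, Call.ambiguous)


@dataclass(frozen=True)
class NumericRule:
    """Score cutoff with a direction; scores past the cutoff are damaging."""

    cutoff: float
    direction: CutoffDirection = CutoffDirection.higher_is_damaging

    def __call__(self, value: RawValue) -> Call:
        try:
            score = float(value)
        except (TypeError, ValueError):
            raise ParseError(
                f"expected a numeric score, got {value!r}") from None
        if not math.isfinite(score):
            raise ValidationError(f"score must be finite, got {score}")
        if self.direction is CutoffDirection.higher_is_damaging:
            return Call.deleterious if score > self.cutoff else Call.benign
        return Call.deleterious if score < self.cutoff else Call.benign


ThresholdTable = Mapping[str, Union[CategoricalRule, NumericRule]]

_DAMAGING_LABELS = {
    "damaging": Call.deleterious,
    "deleterious": Call.deleterious,
    "disease-causing": Call.deleterious,
    "disease causing": Call.deleterious,
    "d": Call.deleterious,
}
_BENIGN_LABELS = {
    "tolerated": Call.benign,
    "benign": Call.benign,
    "neutral": Call.benign,
    "polymorphism": Call.benign,
    "t": Call.benign,
    "n": Call.benign,
}


def _categorical(extra: Mapping[str, Call] = ()) -> CategoricalRule:
    mapping = dict(_DAMAGING_LABELS)
    mapping.update(_BENIGN_LABELS)
    mapping.update(extra or {})
    return CategoricalRule(mapping)


#: Conventional per-tool thresholds (config-overridable). CADD uses the usual
#: Phred-scale cutoff of 20; DANN scores approach 1 for damaging variants;
#: PhyloP and GERP RS cutoffs mark clearly conserved positions.
DEFAULT_THRESHOLDS: dict[str, Union[CategoricalRule, NumericRule]] = {
    "PolyPhen2": _categorical({
        "probably damaging": Call.deleterious,
        "possibly damaging": Call.deleterious,
    }),
    "SIFT": _categorical(),
    "PROVEAN": _categorical(),
    "LRT": _categorical(),
    "MutationTaster": _categorical(),
    "MutationAssessor": _categorical({
        "high": Call.deleterious,
        "high impact": Call.deleterious,
        "medium": Call.deleterious,
        "medium impact": Call.deleterious,
        "low": Call.benign,
        "low impact": Call.benign,
    }),
    "FATHMM": _categorical(),
    "FATHMM-MKL": _categorical(),
    "M-CAP": _categorical(),
    "MetaSVM": _categorical(),
    "MetaLR": _categorical(),
    "DANN": NumericRule(0.9),
    "CADD": NumericRule(20.0),
    "PhyloP20way": NumericRule(0.5),
    "PhyloP100way": NumericRule(2.0),
    "GERP_RS": NumericRule(4.0),
}

CANONICAL_TOOLS: tuple[str, ...] = tuple(DEFAULT_THRESHOLDS)


@dataclass(frozen=True)
class PredictionProfile:
    """The raw outputs of the predictor panel for one variant."""

    values: Mapping[str, RawValue]

    def __post_init__(self) -> None:
        for tool, value in self.values.items():
            if isinstance(value, (int, float)) and not math.isfinite(value):
                raise ValidationError(
                    f"{tool}: numeric predictor value must be finite")

    def items(self):
        return self.values.items()

    def __len__(self) -> int:
        return len(self.values)


def classify_tool_call(tool: str, value: RawValue,
                       thresholds: ThresholdTable = DEFAULT_THRESHOLDS) -> Call:
    """Map one tool's raw output to a deleterious/benign/ambiguous call."""
    rule = thresholds.get(tool)
    if rule is None:
        raise ConfigurationError(
            f"no threshold registered for predictor {tool!r}")
    return rule(value)


def profile_calls(profile: PredictionProfile,
                  thresholds: ThresholdTable = DEFAULT_THRESHOLDS
                  ) -> dict[str, Call]:
    return {tool: classify_tool_call(tool, value, thresholds)
            for tool, value in profile.items()}


def _consensus(profile: PredictionProfile, thresholds: ThresholdTable):
    calls = profile_calls(profile, thresholds)
    n_del = sum(1 for c in calls.values() if c is Call.deleterious)
    n_ben = sum(1 for c in calls.values() if c is Call.benign)
    return calls, n_del, n_ben, len(calls)


def _describe(calls: dict[str, Call], n_del: int, n_ben: int, n: int) -> str:
    per_tool = ", ".join(f"{t}={c.value}" for t, c in sorted(calls.items()))
    return (f"{n_del}/{n} tools deleterious, {n_ben}/{n} benign "
            f"({per_tool})")


def evaluate_pp3(profile: PredictionProfile,
                 thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
                 tau: float = 0.75) -> EvidenceItem:
    """PP3: computational consensus that the variant is damaging.

    Met iff deleterious calls / mapped calls >= ``tau``. An empty profile is
    uninformative and never meets the criterion.
    """
    if len(profile) == 0:
        return EvidenceItem("PP3", met=False, rationale="no predictions")
    calls, n_del, n_ben, n = _consensus(profile, thresholds)
    met = n > 0 and n_del / n >= tau
    return EvidenceItem("PP3", met=met,
                        rationale=_describe(calls, n_del, n_ben, n))


def evaluate_bp4(profile: PredictionProfile,
                 thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
                 tau_benign: float = 0.75,
                 tau: float = 0.75) -> EvidenceItem:
    """BP4: computational consensus that the variant is benign.

    Met iff the benign fraction reaches ``tau_benign`` and PP3 (at ``tau``)
    does not fire, so the two criteria are mutually exclusive.
    """
    if len(profile) == 0:
        return EvidenceItem("BP4", met=False, rationale="no predictions")
    calls, n_del, n_ben, n = _consensus(profile, thresholds)
    pp3_met = n > 0 and n_del / n >= tau
    met = n > 0 and n_ben / n >= tau_benign and not pp3_met
    return EvidenceItem("BP4", met=met,
                        rationale=_describe(calls, n_del, n_ben, n))
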