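"""The classification model: evidence inputs in, five-tier verdict out.

`VariantPathogenicityModel` gathers whatever evidence sources are available
for one candidate variant — population-frequency records, a predictor
profile, gene-level variant counts, family pedigrees, a case-control cohort,
and manually asserted criteria — and `fit()` evaluates each ACMG/AMP
criterion, tallies the met evidence, and applies the combining rules. The
returned `VariantClassificationResults` carries the evidence trace, the
association statistics, the verdict, what-if escalation queries, and a
`summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import combiner, enrichment, frequency, gene_context, insilico, segregation
from .config import Thresholds
from .insilico import PredictionProfile, ThresholdTable, DEFAULT_THRESHOLDS
from .types import (
    Classification,
    CohortProband,
    EvidenceItem,
    Pedigree,
    Strength,
    Tier,
    ValidationError,
    VariantRecord,
)


class VariantPathogenicityModel:
    """ACMG/AMP classification model for a single candidate variant.

    Parameters
    ----------
    variant
        The candidate variant (HGVS notation, recessive inheritance).
    frequency_records, prediction_profile, gene_summaries, pedigrees, cohort
        Evidence sources; each may be ``None``, in which case the criteria it
        feeds are simply not evaluated. An *empty* frequency record list is
        meaningful (absent from every database) and does evaluate PM2.
    extra_evidence
        Manually asserted criteria (e.g. PP4, PM1, PM3) that are narrative
        rather than computable; passed through to the tally as given.
    thresholds
        All numeric cutoffs; defaults suit a severe recessive childhood
        disease.
    predictor_thresholds
        Per-tool score/label mapping for the in-silico panel.
    """

    def __init__(self, variant: VariantRecord, *,
                 frequency_records=None,
                 prediction_profile: Optional[PredictionProfile] = None,
                 gene_summaries=None,
                 pedigrees: Optional[Sequence[Pedigree]] = None,
                 cohort: Optional[Sequence[CohortProband]] = None,
                 extra_evidence: Sequence[EvidenceItem] = (),
                 thresholds: Optional[Thresholds] = None,
                 predictor_thresholds: ThresholdTable = DEFAULT_THRESHOLDS):
        self.variant = variant
        self.frequency_records = frequency_records
        self.prediction_profile = prediction_profile
        self.gene_summaries = gene_summaries
        self.pedigrees = list(pedigrees) if pedigrees is not None else None
        self.cohort = list(cohort) if cohort is not None else None
        self.extra_evidence = list(extra_evidence)
        self.thresholds = thresholds or Thresholds()
        self.predictor_thresholds = predictor_thresholds

    def fit(self) -> "VariantClassificationResults":
        th = self.thresholds
        evidence: list[EvidenceItem] = []
        verdicts = None
        association = None

        if self.frequency_records is not None:
            records = list(self.frequency_records)
            evidence.append(frequency.evaluate_pm2(
                records, af_max=th.af_max, hom_max=th.hom_max))
            evidence.extend(frequency.evaluate_ba1_bs1(
                records, ba1_af=th.ba1_af, bs1_af=th.bs1_af))

        if self.prediction_profile is not None:
            evidence.append(insilico.evaluate_pp3(
                self.prediction_profile, self.predictor_thresholds,
                tau=th.tau))
            evidence.append(insilico.evaluate_bp4(
                self.prediction_profile, self.predictor_thresholds,
                tau_benign=th.tau_benign, tau=th.tau))

        if self.gene_summaries is not None:
            summaries = list(self.gene_summaries)
            evidence.append(gene_context.evaluate_pp2(
                summaries, missense_fraction_min=th.missense_fraction_min,
                benign_fraction_max=th.benign_fraction_max))
            evidence.append(gene_context.evaluate_bp1(
                summaries,
                missense_fraction_max=th.bp1_missense_fraction_max))

        if self.pedigrees is not None and self.pedigrees:
            verdicts = [segregation.check_ar_cosegregation(p)
                        for p in self.pedigrees]
            evidence.append(segregation.evaluate_pp1(
                verdicts, escalation=th.escalation_rule()))
            evidence.append(segregation.evaluate_bs4(verdicts))

        if self.cohort is not None:
            association = enrichment.CaseControlEnrichment.from_cohort(
                self.cohort, base_confidence=th.base_confidence,
                n_tests=th.n_tests).fit()
            evidence.append(enrichment.evaluate_ps4(
                association, or_min=th.or_min,
                exclude_value=th.or_exclude))

        evidence.extend(self.extra_evidence)
        t = combiner.tally(evidence)
        classification = combiner.combine(t, evidence)
        return VariantClassificationResults(
            model=self, evidence=tuple(evidence), tally=t,
            classification=classification, association=association,
            segregation_verdicts=tuple(verdicts) if verdicts else None)


@dataclass(frozen=True)
class VariantClassificationResults:
    """Fitted classification for one variant, with its full evidence trace."""

    model: VariantPathogenicityModel
    evidence: tuple[EvidenceItem, ...]
    tally: combiner.EvidenceTally
    classification: Classification
    association: Optional[enrichment.AssociationResult]
    segregation_verdicts: Optional[tuple] = None

    @property
    def tier(self) -> Tier:
        return self.classification.tier

    @property
    def met_codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.evidence if e.met)

    def what_if(self, code: str, strength: Optional[Strength] = None
                ) -> Classification:
        """Verdict after adding one not-yet-met criterion."""
        from .types import DEFAULT_STRENGTH

        return combiner.what_if(
            self.tally, (code, strength or DEFAULT_STRENGTH[code]))

    def reweight(self, code: str, strength: Strength) -> Classification:
        """Verdict after promoting/demoting one met criterion's strength."""
        return combiner.reweight(self.evidence, code, strength)

    def escalation_paths(self) -> dict[str, str]:
        """Standard what-if table: verdicts under the escalations a curator
        would consider next (a second pathogenic allele in trans -> PM3;
        co-segregation confirmed in further families -> PP1 moderate/strong).
        """
        out = {}
        if "PM3" not in self.tally.codes:
            out["add PM3 (moderate)"] = self.what_if("PM3").tier.value
        if "PP1" in self.met_codes:
            out["PP1 -> moderate"] = self.reweight(
                "PP1", Strength.moderate).tier.value
            out["PP1 -> strong"] = self.reweight(
                "PP1", Strength.strong).tier.value
        return out

    def summary(self) -> str:
        """Human-readable report: evidence table, association, verdict."""
        lines = [
            f"ACMG/AMP classification: {self.model.variant.label}",
            "=" * 64,
            f"{'criterion':<10}{'strength':<12}{'met':<5}rationale",
            "-" * 64,
        ]
        for e in self.evidence:
            rationale = e.rationale if len(e.rationale) <= 60 else \
                e.rationale[:57] + "..."
            lines.append(f"{e.code:<10}{e.strength.value:<12}"
                         f"{'yes' if e.met else 'no':<5}{rationale}")
        if self.association is not None:
            lines.append("-" * 64)
            lines.append(self.association.summary())
        lines.append("-" * 64)
        lines.append(f"tier: {self.tier.value}   "
                     f"(rule fired: {self.classification.rule_fired})")
        esc = self.escalation_paths()
        if esc:
            lines.append("what-if escalations:")
            for label, tier in esc.items():
                lines.append(f"  {label:<22}-> {tier}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variant": {
                "gene": self.model.variant.gene,
                "transcript": self.model.variant.transcript,
                "cdna_change": self.model.variant.cdna_change,
                "protein_change": self.model.variant.protein_change,
            },
            "evidence": [
                {"code": e.code, "direction": e.direction.value,
                 "strength": e.strength.value, "met": e.met,
                 "rationale": e.rationale}
                for e in self.evidence
            ],
            "association": (self.association.to_dict()
                            if self.association else None),
            "tier": self.tier.value,
            "rule_fired": self.classification.rule_fired,
            "what_if": self.escalation_paths(),
        }
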