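"""Gene-level context evidence: PP2 and its benign counterpart BP1.

PP2 applies to a missense variant in a gene where missense changes are a
common disease mechanism and benign missense variation is rare; BP1 applies
in genes where essentially all pathogenic variation is truncating. Both are
evaluated from database count summaries (ClinVar/UniProt, HGMD, Varsome, ...)
supplied by the caller, so the thresholds make the qualitative argument
("many pathogenic missenses", "few benign variants") explicit and testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .types import EvidenceItem, ValidationError


@dataclass(frozen=True)
class GeneVariantSummary:
    """Variant-class counts for one gene from one database.

    ``benign_count`` / ``total_classified`` are optional: some sources report
    only pathogenic breakdowns, others only an overall benign fraction.
    """

    source: str
    pathogenic_total: int
    pathogenic_missense: int
    benign_count: Optional[int] = None
    total_classified: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.pathogenic_total, self.pathogenic_missense) < 0:
            raise ValidationError("counts must be >= 0")
        if self.pathogenic_missense > self.pathogenic_total:
            raise ValidationError(
                f"{self.source}: pathogenic_missense "
                f"{self.pathogenic_missense} exceeds pathogenic_total "
                f"{self.pathogenic_total}")
        if (self.benign_count is not None and self.total_classified is not None
                and self.benign_count > self.total_classified):
            raise ValidationError(
                f"{self.source}: benign_count exceeds total_classified")

    @property
    def missense_fraction(self) -> Optional[float]:
        if self.pathogenic_total == 0:
            return None
        return self.pathogenic_missense / self.pathogenic_total

    @property
    def benign_fraction(self) -> Optional[float]:
        if self.benign_count is None or not self.total_classified:
            return None
        return self.benign_count / self.total_classified


def _best_missense_fraction(summaries: Sequence[GeneVariantSummary]):
    best = None
    for s in summaries:
        f = s.missense_fraction
        if f is not None and (best is None or f > best[1]):
            best = (s.source, f)
    return best


def evaluate_pp2(summaries: Sequence[GeneVariantSummary],
                 missense_fraction_min: float = 0.5,
                 benign_fraction_max: float = 0.10) -> EvidenceItem:
    """PP2: missense is a common disease mechanism and benign variation rare.

    Met iff the largest pathogenic-missense fraction across sources reaches
    ``missense_fraction_min`` and, where any source reports benign counts,
    the smallest benign fraction is at most ``benign_fraction_max``. When
    multiple sources conflict, the most favorable source may satisfy each
    condition. No source with pathogenic counts -> uninformative, not met.
    """
    best = _best_missense_fraction(summaries)
    if best is None:
        return EvidenceItem(
            "PP2", met=False,
            rationale="no source reports pathogenic variant counts")
    source, frac = best
    benign_fracs = [(s.source, s.benign_fraction) for s in summaries
                    if s.benign_fraction is not None]
    mech_ok = frac >= missense_fraction_min
    parts = [f"pathogenic missense fraction {frac:.3f} ({source})"]
    if benign_fracs:
        bsource, bfrac = min(benign_fracs, key=lambda t: t[1])
        benign_ok = bfrac <= benign_fraction_max
        parts.append(f"benign fraction {bfrac:.3f} ({bsource})")
    else:
        benign_ok = True
        parts.append("no benign counts reported")
    return EvidenceItem("PP2", met=mech_ok and benign_ok,
                        rationale="; ".join(parts))


def evaluate_bp1(summaries: Sequence[GeneVariantSummary],
                 missense_fraction_max: float = 0.1) -> EvidenceItem:
    """BP1: missense variant in a gene where truncating variants cause disease.

    Met iff the largest pathogenic-missense fraction is at most
    ``missense_fraction_max``.
    """
    best = _best_missense_fraction(summaries)
    if best is None:
        return EvidenceItem(
            "BP1", met=False,
            rationale="no source reports pathogenic variant counts")
    source, frac = best
    return EvidenceItem(
        "BP1", met=frac <= missense_fraction_max,
        rationale=f"pathogenic missense fraction {frac:.3f} ({source})")
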