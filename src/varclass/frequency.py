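"""Population-frequency evidence: PM2 and its benign counterparts BA1/BS1.

For a severe recessive childhood disease a pathogenic allele is expected to be
absent or extremely rare in outbred population databases (gnomAD, ExAC, ESP,
1000 Genomes, ABraOM, ...), with essentially no homozygotes. PM2 encodes that
expectation; BA1 (stand-alone benign) and BS1 (strong benign) fire when the
allele is instead common.

Boundary conventions: PM2 compares frequency with strict ``<`` against
``af_max``; BA1/BS1 use ``>=`` against their thresholds. "No data" in a
database is treated as absence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .types import EvidenceItem, ValidationError


@dataclass(frozen=True)
class PopulationFrequencyRecord:
    """Allele counts for one variant in one population database.

    ``allele_count`` of ``None`` means the database reports no data for the
    variant (absence). When ``allele_count`` is present, ``allele_number``
    must be a positive denominator.
    """

    database: str
    allele_count: Optional[int] = None
    allele_number: Optional[int] = None
    homozygote_count: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("allele_count", "allele_number", "homozygote_count"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if self.allele_count is not None:
            if self.allele_number is None or self.allele_number <= 0:
                raise ValidationError(
                    f"{self.database}: allele_number must be > 0 when "
                    f"allele_count is present")
            if self.allele_count > self.allele_number:
                raise ValidationError(
                    f"{self.database}: allele_count {self.allele_count} "
                    f"exceeds allele_number {self.allele_number}")
            if (self.homozygote_count is not None
                    and 2 * self.homozygote_count > self.allele_count):
                raise ValidationError(
                    f"{self.database}: {self.homozygote_count} homozygotes "
                    f"imply more than {self.allele_count} alleles")

    @property
    def absent(self) -> bool:
        return self.allele_count is None

    @property
    def frequency(self) -> Optional[float]:
        if self.absent:
            return None
        return allele_frequency(self.allele_count, self.allele_number)


def allele_frequency(allele_count: int, allele_number: int) -> float:
    """Plain allele frequency ``allele_count / allele_number``."""
    if allele_number <= 0:
        raise ValidationError(
            f"allele frequency undefined for allele_number={allele_number}")
    if allele_count < 0 or allele_count > allele_number:
        raise ValidationError(
            f"allele_count must be in [0, allele_number], got "
            f"{allele_count}/{allele_number}")
    return allele_count / allele_number


def evaluate_pm2(records: Sequence[PopulationFrequencyRecord],
                 af_max: float = 1e-4,
                 hom_max: int = 0) -> EvidenceItem:
    """PM2: absent from, or extremely rare in, all population databases.

    Met iff every record is either absent or has frequency strictly below
    ``af_max`` with at most ``hom_max`` homozygotes (when a homozygote count
    is reported). An empty record list means the variant was found in no
    database and PM2 is met.
    """
    if af_max <= 0:
        raise ValidationError(f"af_max must be > 0, got {af_max}")
    if not records:
        return EvidenceItem("PM2", met=True,
                            rationale="absent from all queried databases")
    details = []
    met = True
    for rec in records:
        if rec.absent:
            details.append(f"{rec.database}: no data")
            continue
        freq = rec.frequency
        ok = freq < af_max
        if rec.homozygote_count is not None and rec.homozygote_count > hom_max:
            ok = False
        met = met and ok
        hom = ("" if rec.homozygote_count is None
               else f", {rec.homozygote_count} hom")
        details.append(
            f"{rec.database}: {rec.allele_count}/{rec.allele_number} "
            f"(AF={freq:.3g}{hom})")
    if met and all(r.absent for r in records):
        rationale = "absent from all queried databases"
    else:
        rationale = "; ".join(details)
    return EvidenceItem("PM2", met=met, rationale=rationale)


def evaluate_ba1_bs1(records: Sequence[PopulationFrequencyRecord],
                     ba1_af: float = 0.05,
                     bs1_af: float = 0.01) -> list[EvidenceItem]:
    """BA1 (stand-alone) and BS1 (strong) benign frequency criteria.

    BA1 is met when any database frequency reaches ``ba1_af``; BS1 when any
    reaches ``bs1_af`` and BA1 did not fire. Both comparisons are ``>=``.
    """
    if not ba1_af > bs1_af:
        raise ValidationError(
            f"ba1_af ({ba1_af}) must exceed bs1_af ({bs1_af})")
    freqs = {r.database: r.frequency for r in records if not r.absent}
    max_db, max_af = None, 0.0
    for db, af in freqs.items():
        if af >= max_af:
            max_db, max_af = db, af
    ba1 = max_db is not None and max_af >= ba1_af
    bs1 = (not ba1) and max_db is not None and max_af >= bs1_af
    if max_db is None:
        why = "no database reports the allele"
    else:
        why = f"maximum frequency {max_af:.3g} in {max_db}"
    return [
        EvidenceItem("BA1", met=ba1, rationale=why),
        EvidenceItem("BS1", met=bs1, rationale=why),
    ]
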