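"""Case-control enrichment: Haldane-Anscombe odds ratio and Wald CI; PS4.

The cohort is split into a case stratum (LCA/EORD probands) and a control
stratum (probands with other inherited retinal dystrophies); exposure is
homozygosity for the candidate variant, one proband per family. Because the
control cell is typically zero for an ultra-rare allele, the odds ratio uses
the Haldane-Anscombe correction: when any cell of the 2x2 table is zero, 0.5
is added to all four cells before forming the cross-product ratio and the
log-scale standard error. The confidence interval is a Wald interval on
log OR, with the confidence level Bonferroni-adjusted for the number of
variants tested (two variants: 95% -> 97.5%).

PS4 (pathogenic strong: prevalence in affected individuals significantly
exceeds controls) is operationalized as OR >= 3 with a confidence interval
excluding 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from scipy.stats import norm

from .types import (
    CohortProband,
    DiagnosisGroup,
    EvidenceItem,
    Genotype,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Proband counts: (case, control) x (exposed, unexposed).

    a: cases exposed, b: cases unexposed, c: controls exposed, d: controls
    unexposed.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("table cells must be >= 0")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def needs_correction(self) -> bool:
        return 0 in self.cells

    def corrected_cells(self) -> tuple[float, float, float, float]:
        """Cells used for estimation: +0.5 everywhere iff any cell is zero."""
        if self.needs_correction:
            return tuple(x + 0.5 for x in self.cells)  # type: ignore[return-value]
        return tuple(float(x) for x in self.cells)  # type: ignore[return-value]

    def transpose_groups(self) -> "ContingencyTable2x2":
        """Swap case and control rows (OR maps to its reciprocal)."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class AssociationResult:
    """Odds-ratio estimate with its Wald interval and the settings used."""

    table: ContingencyTable2x2
    or_point: float
    ci_lower: float
    ci_upper: float
    confidence_level: float
    z_quantile: float
    correction_applied: bool
    se_log_or: float

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.or_point <= self.ci_upper):
            raise ValidationError("CI must bracket the point estimate")
        if self.ci_lower <= 0:
            raise ValidationError("ci_lower must be > 0")

    def summary(self) -> str:
        t = self.table
        corr = "Haldane-Anscombe +0.5" if self.correction_applied else "none"
        pct = 100 * self.confidence_level
        return "\n".join([
            "Case-control enrichment (odds ratio, Wald log-scale CI)",
            "=" * 56,
            f"table (a,b,c,d)      {t.cells}",
            f"zero-cell correction {corr}",
            f"odds ratio           {self.or_point:.3f}",
            f"{pct:.1f}% CI            ({self.ci_lower:.3f}, "
            f"{self.ci_upper:.3f})",
            f"SE(log OR)           {self.se_log_or:.4f}",
            f"z quantile           {self.z_quantile:.6f}",
        ])

    def to_dict(self) -> dict:
        return {
            "table": list(self.table.cells),
            "or": self.or_point,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "confidence_level": self.confidence_level,
            "correction_applied": self.correction_applied,
        }


def build_table(cohort: Sequence[CohortProband],
                exposure: Optional[Callable[[CohortProband], bool]] = None
                ) -> ContingencyTable2x2:
    """Cross-tabulate a proband cohort into the 2x2 enrichment table.

    Exposure defaults to homozygosity for the candidate variant. Probands with
    missing genotype are counted as unexposed (a warning is logged), matching
    the conservative convention that an ungenotyped proband cannot support
    enrichment.
    """
    if not cohort:
        raise ValidationError("cannot build a 2x2 table from an empty cohort")
    if exposure is None:
        exposure = lambda p: p.genotype is Genotype.hom_alt  # noqa: E731
    n_missing = sum(1 for p in cohort if p.genotype is Genotype.missing)
    if n_missing:
        logger.warning(
            "%d proband(s) with missing genotype counted as unexposed",
            n_missing)
    a = b = c = d = 0
    for p in cohort:
        exposed = p.genotype is not Genotype.missing and exposure(p)
        if p.diagnosis_group is DiagnosisGroup.lca_eord:
            a, b = (a + 1, b) if exposed else (a, b + 1)
        else:
            c, d = (c + 1, d) if exposed else (c, d + 1)
    return ContingencyTable2x2(a, b, c, d)


def haldane_anscombe_or(table: ContingencyTable2x2) -> float:
    """Cross-product odds ratio with the zero-cell +0.5 correction.

    The correction is applied to all four cells, and only when at least one
    raw cell is zero; otherwise the plain ratio (a*d)/(b*c) is returned.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValidationError("both margins must contain probands")
    a, b, c, d = table.corrected_cells()
    return (a * d) / (b * c)


def bonferroni_confidence(base_level: float, n_tests: int) -> float:
    """Adjusted confidence level 1 - (1 - base) / n for n comparisons."""
    if not 0 < base_level < 1:
        raise ValidationError(f"base_level must be in (0,1), got {base_level}")
    if n_tests < 1:
        raise ValidationError(f"n_tests must be >= 1, got {n_tests}")
    return 1 - (1 - base_level) / n_tests


def wald_log_ci(table: ContingencyTable2x2,
                confidence_level: float) -> tuple[float, float]:
    """Wald interval for the odds ratio on the log scale.

    The standard error uses the same (possibly corrected) cells as the point
    estimate: SE = sqrt(1/a' + 1/b' + 1/c' + 1/d').
    """
    if not 0 < confidence_level < 1:
        raise ValidationError(
            f"confidence_level must be in (0,1), got {confidence_level}")
    or_point = haldane_anscombe_or(table)
    a, b, c, d = table.corrected_cells()
    if min(a, b, c, d) == 0:
        raise ValidationError(
            "Wald CI undefined: zero cell without correction")
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf(1 - (1 - confidence_level) / 2))
    log_or = math.log(or_point)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


class CaseControlEnrichment:
    """Enrichment model for one variant: 2x2 table in, odds ratio out.

    Parameters
    ----------
    table
        The proband contingency table, or use :meth:`from_cohort`.
    base_confidence, n_tests
        The per-comparison confidence level and the number of variants tested
        in the study; the working level is Bonferroni-adjusted to
        ``1 - (1 - base_confidence)/n_tests``.
    """

    def __init__(self, table: ContingencyTable2x2,
                 base_confidence: float = 0.95, n_tests: int = 1):
        self.table = table
        self.base_confidence = base_confidence
        self.n_tests = n_tests
        self.confidence_level = bonferroni_confidence(base_confidence, n_tests)

    @classmethod
    def from_cohort(cls, cohort: Sequence[CohortProband],
                    base_confidence: float = 0.95,
                    n_tests: int = 1) -> "CaseControlEnrichment":
        return cls(build_table(cohort), base_confidence, n_tests)

    def fit(self) -> AssociationResult:
        or_point = haldane_anscombe_or(self.table)
        lo, hi = wald_log_ci(self.table, self.confidence_level)
        a, b, c, d = self.table.corrected_cells()
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = float(norm.ppf(1 - (1 - self.confidence_level) / 2))
        return AssociationResult(
            table=self.table, or_point=or_point, ci_lower=lo, ci_upper=hi,
            confidence_level=self.confidence_level, z_quantile=z,
            correction_applied=self.table.needs_correction, se_log_or=se)


def evaluate_ps4(assoc: AssociationResult, or_min: float = 3.0,
                 exclude_value: float = 1.0) -> EvidenceItem:
    """PS4: prevalence in cases significantly exceeds controls.

    Met iff the odds ratio reaches ``or_min`` and the confidence interval
    excludes ``exclude_value`` (no association).
    """
    excludes = (assoc.ci_lower > exclude_value
                or assoc.ci_upper < exclude_value)
    met = assoc.or_point >= or_min and excludes
    pct = 100 * assoc.confidence_level
    rationale = (f"OR={assoc.or_point:.3f}, {pct:.1f}% CI "
                 f"({assoc.ci_lower:.3f}, {assoc.ci_upper:.3f}); "
                 f"threshold OR>={or_min:g}, CI must exclude "
                 f"{exclude_value:g}")
    return EvidenceItem("PS4", met=met, rationale=rationale)
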