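"""Case-control enrichment statistics and PS4."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from varclass.enrichment import (
    AssociationResult,
    CaseControlEnrichment,
    ContingencyTable2x2,
    bonferroni_confidence,
    build_table,
    evaluate_ps4,
    haldane_anscombe_or,
    wald_log_ci,
)
from varclass.types import (
    CohortProband,
    DiagnosisGroup,
    Genotype,
    ValidationError,
)


def oracle_or_ci(a, b, c, d, level):
    """Independent re-coding of the corrected OR and Wald CI formulas."""
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - (1 - level) / 2)
    return or_, math.exp(math.log(or_) - z * se), math.exp(
        math.log(or_) + z * se)


class TestBuildTable:
    def test_replica_tables(self, replica):
        cells = {key: build_table(list(study.cohort)).cells
                 for key, study in replica.items()}
        assert cells["p.Phe83Leu"] == (4, 89, 0, 420)
        assert cells["p.Gly187Glu"] == (3, 90, 0, 420)

    def test_no_exposed_probands(self):
        cohort = (
            [CohortProband(f"c{i}", f"c{i}", DiagnosisGroup.lca_eord,
                           Genotype.hom_ref) for i in range(5)]
            + [CohortProband(f"k{i}", f"k{i}", DiagnosisGroup.other_ird,
                             Genotype.het) for i in range(7)])
        assert build_table(cohort).cells == (0, 5, 0, 7)

    def test_missing_genotype_counts_unexposed(self, caplog):
        cohort = [
            CohortProband("p", "f", DiagnosisGroup.lca_eord,
                          Genotype.missing),
            CohortProband("q", "g", DiagnosisGroup.other_ird,
                          Genotype.hom_alt)]
        with caplog.at_level("WARNING"):
            table = build_table(cohort)
        assert table.cells == (0, 1, 1, 0)
        assert "missing genotype" in caplog.text

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            build_table([])


class TestOddsRatio:
    def test_first_variant_or(self):
        assert round(haldane_anscombe_or(
            ContingencyTable2x2(4, 89, 0, 420)), 3) == 42.285

    def test_second_variant_or(self):
        assert round(haldane_anscombe_or(
            ContingencyTable2x2(3, 90, 0, 420)), 3) == 32.525

    def test_balanced_table_uncorrected(self):
        table = ContingencyTable2x2(10, 10, 10, 10)
        assert haldane_anscombe_or(table) == 1.0
        assert not table.needs_correction

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            haldane_anscombe_or(ContingencyTable2x2(0, 0, 1, 1))


class TestWaldCI:
    @pytest.mark.parametrize("cells,expected", [
        ((4, 89, 0, 420), (1.482, 1206.268)),
        ((3, 90, 0, 420), (1.088, 972.642)),
    ])
    def test_reported_intervals_within_1pct(self, cells, expected):
        lo, hi = wald_log_ci(ContingencyTable2x2(*cells), 0.975)
        assert lo == pytest.approx(expected[0], rel=0.01)
        assert hi == pytest.approx(expected[1], rel=0.01)

    def test_log_symmetry_for_balanced_table(self):
        lo, hi = wald_log_ci(ContingencyTable2x2(10, 10, 10, 10), 0.95)
        assert lo * hi == pytest.approx(1.0)

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValidationError):
            wald_log_ci(ContingencyTable2x2(1, 1, 1, 1), 1.2)

    def test_oracle_equivalence_small_tables(self):
        """Corrected OR and CI agree with the direct-formula oracle to
        1e-12 relative over all tables with entries in 0..6."""
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b == 0 or c + d == 0:
                continue
            table = ContingencyTable2x2(a, b, c, d)
            exp_or, exp_lo, exp_hi = oracle_or_ci(a, b, c, d, 0.975)
            assert haldane_anscombe_or(table) == pytest.approx(
                exp_or, rel=1e-12)
            lo, hi = wald_log_ci(table, 0.975)
            assert lo == pytest.approx(exp_lo, rel=1e-12)
            assert hi == pytest.approx(exp_hi, rel=1e-12)

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_transpose_symmetry(self, cells):
        """Swapping case and control rows inverts the OR and mirrors the CI."""
        a, b, c, d = cells
        if a + b == 0 or c + d == 0:
            return
        table = ContingencyTable2x2(a, b, c, d)
        flipped = table.transpose_groups()
        assert haldane_anscombe_or(flipped) == pytest.approx(
            1 / haldane_anscombe_or(table), rel=1e-12)
        lo, hi = wald_log_ci(table, 0.975)
        flo, fhi = wald_log_ci(flipped, 0.975)
        assert flo == pytest.approx(1 / hi, rel=1e-12)
        assert fhi == pytest.approx(1 / lo, rel=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize("base,n,expected", [
        (0.95, 2, 0.975),
        (0.95, 1, 0.95),
        (0.99, 4, 0.9975),
    ])
    def test_adjusted_levels(self, base, n, expected):
        assert bonferroni_confidence(base, n) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_confidence(1.5, 2)
        with pytest.raises(ValidationError):
            bonferroni_confidence(0.95, 0)


class TestModel:
    def test_fit_carries_settings(self, replica):
        result = CaseControlEnrichment.from_cohort(
            list(replica["p.Phe83Leu"].cohort), base_confidence=0.95,
            n_tests=2).fit()
        assert result.confidence_level == pytest.approx(0.975)
        assert result.correction_applied
        assert result.z_quantile == pytest.approx(norm.ppf(0.9875))
        assert result.ci_lower <= result.or_point <= result.ci_upper

    def test_summary_mentions_correction(self, replica):
        result = CaseControlEnrichment.from_cohort(
            list(replica["p.Phe83Leu"].cohort), n_tests=2).fit()
        text = result.summary()
        assert "Haldane-Anscombe" in text
        assert "42.285" in text


class TestPS4:
    def _assoc(self, or_point, lo, hi):
        return AssociationResult(
            table=ContingencyTable2x2(1, 1, 1, 1), or_point=or_point,
            ci_lower=lo, ci_upper=hi, confidence_level=0.975,
            z_quantile=2.2414, correction_applied=False, se_log_or=1.0)

    def test_strong_association_met(self):
        assert evaluate_ps4(self._assoc(42.285, 1.482, 1206.268)).met

    def test_below_or_threshold_not_met(self):
        assert not evaluate_ps4(self._assoc(2.5, 1.2, 5.0)).met

    def test_ci_including_one_not_met(self):
        assert not evaluate_ps4(self._assoc(5.0, 0.8, 30.0)).met
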