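"""ACMG/AMP evidence combiner: tallies, rules, what-if queries."""

import itertools

import pytest

from varclass.combiner import (
    EvidenceTally,
    combine,
    reweight,
    tally,
    what_if,
)
from varclass.types import EvidenceItem, Strength, Tier, ValidationError


def _items(codes, strengths=None):
    strengths = strengths or {}
    return [EvidenceItem(c, met=True, rationale="x",
                         strength=strengths.get(c)) for c in codes]


def oracle_tier(vs, s, m, p, ba, bs, bp):
    """Independent restatement of the guideline combining rules, written as
    score checks rather than an ordered rule list."""
    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2)
                        or (m >= 1 and p >= 4))))
    likely = pathogenic or (
        (vs >= 1 and m >= 1) or (s >= 1 and m >= 1) or (s >= 1 and p >= 2)
        or m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4))
    benign = ba >= 1 or bs >= 2
    likely_benign = benign or (bs >= 1 and bp >= 1) or bp >= 2
    if likely and likely_benign:
        return Tier.uncertain_significance
    if pathogenic:
        return Tier.pathogenic
    if likely:
        return Tier.likely_pathogenic
    if benign:
        return Tier.benign
    if likely_benign:
        return Tier.likely_benign
    return Tier.uncertain_significance


def all_tallies(max_count=3):
    for counts in itertools.product(range(max_count + 1), repeat=7):
        yield counts


class TestTally:
    def test_reclassified_variant_tally(self):
        t = tally(_items(["PS4", "PM2", "PP1", "PP2", "PP3"]))
        assert (t.n_strong, t.n_moderate, t.n_supporting) == (1, 1, 3)

    def test_initial_vus_tally(self):
        t = tally(_items(["PM2", "PP2", "PP3"]))
        assert (t.n_strong, t.n_moderate, t.n_supporting) == (0, 1, 2)

    def test_empty_evidence(self):
        t = tally([])
        assert t == EvidenceTally()

    def test_unmet_items_ignored(self):
        items = [EvidenceItem("PM2", met=False)]
        assert tally(items) == EvidenceTally()

    def test_duplicate_met_codes_rejected(self):
        with pytest.raises(ValidationError, match="already tallied"):
            tally(_items(["PM2", "PM2"]))

    def test_modulated_strength_counts_in_assigned_bucket(self):
        t = tally(_items(["PP1"], strengths={"PP1": Strength.moderate}))
        assert t.n_moderate == 1 and t.n_supporting == 0

    def test_benign_strengths_bucketed(self):
        t = tally(_items(["BA1", "BS1", "BP4"]))
        assert (t.n_ba, t.n_bs, t.n_bp) == (1, 1, 1)


class TestCombine:
    def test_one_strong_one_moderate_three_supporting_is_lp(self):
        c = combine(tally(_items(["PS4", "PM2", "PP1", "PP2", "PP3"])))
        assert c.tier is Tier.likely_pathogenic

    def test_one_moderate_two_supporting_is_vus(self):
        c = combine(tally(_items(["PM2", "PP2", "PP3"])))
        assert c.tier is Tier.uncertain_significance
        assert c.rule_fired == "default_vus"

    def test_very_strong_plus_moderate_is_lp(self):
        c = combine(tally(_items(["PVS1", "PM2"])))
        assert c.tier is Tier.likely_pathogenic

    def test_conflicting_evidence_is_vus(self):
        c = combine(tally(_items(["PVS1", "PM2", "BA1"])))
        assert c.tier is Tier.uncertain_significance
        assert c.rule_fired == "conflicting"

    def test_two_benign_strong_is_benign(self):
        c = combine(tally(_items(["BS1", "BS4"])))
        assert c.tier is Tier.benign

    def test_two_benign_supporting_is_likely_benign(self):
        c = combine(tally(_items(["BP1", "BP4"])))
        assert c.tier is Tier.likely_benign

    def test_oracle_equivalence_all_small_tallies(self):
        """Exhaustive agreement with an independently coded rule oracle
        over every tally with all counts <= 3."""
        for counts in all_tallies():
            t = EvidenceTally(*counts)
            assert combine(t).tier is oracle_tier(*counts), counts

    def test_monotone_in_evidence(self):
        """More pathogenic-side evidence never moves the verdict toward
        benign; more benign-side evidence never moves it toward pathogenic."""
        order = {Tier.benign: 0, Tier.likely_benign: 1,
                 Tier.uncertain_significance: 2, Tier.likely_pathogenic: 3,
                 Tier.pathogenic: 4}
        for counts in all_tallies(2):
            base = order[combine(EvidenceTally(*counts)).tier]
            for i in range(4):  # pathogenic-side buckets
                bumped = list(counts)
                bumped[i] += 1
                after = order[combine(EvidenceTally(*bumped)).tier]
                assert after >= base
            for i in range(4, 7):  # benign-side buckets
                bumped = list(counts)
                bumped[i] += 1
                after = order[combine(EvidenceTally(*bumped)).tier]
                assert after <= base

    def test_conflict_always_vus(self):
        for counts in all_tallies(2):
            vs, s, m, p, ba, bs, bp = counts
            path_fires = combine(
                EvidenceTally(vs, s, m, p)).tier in (
                    Tier.pathogenic, Tier.likely_pathogenic)
            benign_fires = combine(
                EvidenceTally(0, 0, 0, 0, ba, bs, bp)).tier in (
                    Tier.benign, Tier.likely_benign)
            if path_fires and benign_fires:
                c = combine(EvidenceTally(*counts))
                assert c.tier is Tier.uncertain_significance
                assert c.rule_fired == "conflicting"


class TestWhatIf:
    def test_adding_pm3_reaches_pathogenic(self):
        t = tally(_items(["PS4", "PM2", "PP1", "PP2", "PP3"]))
        c = what_if(t, ("PM3", Strength.moderate))
        assert c.tier is Tier.pathogenic

    def test_escalating_pp1_to_strong_reaches_pathogenic(self):
        items = _items(["PS4", "PM2", "PP1", "PP2", "PP3"])
        c = reweight(items, "PP1", Strength.strong)
        assert c.tier is Tier.pathogenic

    def test_escalating_pp1_to_moderate_reaches_pathogenic(self):
        items = _items(["PS4", "PM2", "PP1", "PP2", "PP3"])
        c = reweight(items, "PP1", Strength.moderate)
        assert c.tier is Tier.pathogenic

    def test_single_supporting_stays_vus(self):
        c = what_if(EvidenceTally(), ("PP3", Strength.supporting))
        assert c.tier is Tier.uncertain_significance

    def test_duplicate_addition_rejected(self):
        t = tally(_items(["PM2"]))
        with pytest.raises(ValidationError):
            what_if(t, ("PM2", Strength.moderate))

    def test_reweight_requires_met_criterion(self):
        with pytest.raises(ValidationError):
            reweight(_items(["PM2"]), "PP1", Strength.strong)
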