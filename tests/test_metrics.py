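"""Metrics: exact fractions, display formatting, verdict logic, aggregates."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from variantdq import (
    ConcordancePolicy,
    DisorderSpec,
    SchemaProfile,
    SignificanceAssertion,
    StatisticalAssociationRecord,
    Verdict,
    cdl,
    classify_gwas,
    classify_interpretation,
    concordance_summary,
    csl,
    format_percent,
    generate_concordance_fixture,
    gwas_relevant,
    integrate,
)
from variantdq.integrate import UnknownSourceError
from variantdq.metrics import (
    EmptyDatasetError,
    aggregate_cdl,
    aggregate_concordance,
)
from variantdq.model import CSHGEntity

from conftest import ASSEMBLY, make_record

DISORDER = DisorderSpec(name="Synthetic disorder")
POLICY = ConcordancePolicy()


def assertion(term_class, source="S", assertion_id="a0"):
    return SignificanceAssertion(term_raw=term_class, term_class=term_class,
                                 disorder=DISORDER, source_name=source,
                                 assertion_id=assertion_id)


def association(p, lo, hi, scale="ratio", source="GWAS Catalog", study="s"):
    return StatisticalAssociationRecord(p_value=p, ci_lower=lo, ci_upper=hi,
                                        effect_scale=scale, disorder=DISORDER,
                                        study_id=study, source_name=source)


class TestPercentFormatting:
    @pytest.mark.parametrize("num, den, style, display", [
        (8, 11, "truncate", "72.72%"),
        (8, 11, "half_up", "72.73%"),
        (7, 11, "truncate", "63.63%"),
        (144, 201, "half_up", "71.64%"),
        (1, 2, "half_up", "50.00%"),
        (0, 7, "half_up", "0.00%"),
        (7, 7, "truncate", "100.00%"),
    ])
    def test_both_styles(self, num, den, style, display):
        assert format_percent(Fraction(num, den), style) == display

    def test_none_renders_dash(self):
        assert format_percent(None) == "-"


class TestCSL:
    def test_eight_entity_profile(self):
        entities = frozenset(e for e in CSHGEntity
                             if e not in {CSHGEntity.GROUP_OF_INDIVIDUALS,
                                          CSHGEntity.STATISTICAL_ASSOCIATION,
                                          CSHGEntity.STUDY})
        result = csl(SchemaProfile("ClinVar", entities))
        assert result.fraction == Fraction(8, 11)
        assert result.percent_display == "72.72%"

    def test_empty_and_full_profiles(self):
        assert csl(SchemaProfile("X", frozenset())).percent_display == "0.00%"
        full = csl(SchemaProfile("X", frozenset(CSHGEntity)))
        assert full.fraction == 1
        assert full.percent_display == "100.00%"


class TestCDL:
    def _dataset(self, counts):
        """Disjoint per-source record sets plus an explicit shared region."""
        per_source = {}
        position = 1
        for source, n in counts.items():
            per_source[source] = [make_record(source, start=position + i)
                                  for i in range(n)]
            position += n
        return integrate(per_source, DISORDER, ASSEMBLY)

    def test_printed_style_fraction(self):
        dataset = self._dataset({"GWAS Catalog": 144, "Rest": 57})
        result = cdl(dataset, "GWAS Catalog")
        assert (result.n_in_source, result.n_unique_total) == (144, 201)
        assert result.fraction == Fraction(144, 201)
        assert result.percent_display == "71.64%"

    def test_full_and_zero_coverage(self):
        full = self._dataset({"Only": 10})
        assert cdl(full, "Only").percent_display == "100.00%"
        dataset = integrate({"A": [make_record("A")], "GWAS Catalog": []},
                            DISORDER, ASSEMBLY)
        result = cdl(dataset, "GWAS Catalog")
        assert result.n_in_source == 0
        assert result.percent_display == "0.00%"

    def test_errors(self):
        dataset = self._dataset({"A": 3})
        with pytest.raises(UnknownSourceError):
            cdl(dataset, "B")
        empty = integrate({"A": []}, DISORDER, ASSEMBLY)
        with pytest.raises(EmptyDatasetError):
            cdl(empty, "A")


class TestClassifyInterpretation:
    def test_three_source_conflict_is_discordant(self):
        verdict = classify_interpretation(
            [assertion("pathogenic", "ClinVar"),
             assertion("pathogenic", "LOVD"),
             assertion("uncertain_significance", "CardioDB")], POLICY)
        assert verdict is Verdict.DISCORDANT

    def test_pathogenic_vs_likely_pathogenic_depends_on_mode(self):
        assertions = [assertion("pathogenic", "ClinVar", "a0"),
                      assertion("likely_pathogenic", "ClinVar", "a1")]
        assert classify_interpretation(assertions, POLICY) is Verdict.CONCORDANT
        strict = ConcordancePolicy(strict_mode=True)
        assert classify_interpretation(assertions, strict) is Verdict.DISCORDANT

    def test_single_assertion_concordant_and_empty_not_applicable(self):
        assert classify_interpretation([assertion("risk_factor")],
                                       POLICY) is Verdict.CONCORDANT
        assert classify_interpretation([], POLICY) is Verdict.NOT_APPLICABLE

    def test_within_source_conflict_counts_like_between_source(self):
        within = [assertion("pathogenic", "ClinVar", "a0"),
                  assertion("likely_benign", "ClinVar", "a1")]
        between = [assertion("pathogenic", "ClinVar"),
                   assertion("likely_benign", "LOVD")]
        assert classify_interpretation(within, POLICY) is Verdict.DISCORDANT
        assert classify_interpretation(between, POLICY) is Verdict.DISCORDANT

    def test_risk_factor_conflicts_with_everything_else(self):
        verdict = classify_interpretation(
            [assertion("pathogenic"), assertion("risk_factor")], POLICY)
        assert verdict is Verdict.DISCORDANT


class TestGwasRelevance:
    @pytest.mark.parametrize("p, lo, hi, scale, expected", [
        (1e-9, 1.2, 1.5, "ratio", True),
        (1e-9, 0.9, 1.5, "ratio", False),   # CI crosses 1
        (5e-8, 1.2, 1.5, "ratio", False),   # boundary p, strict inequality
        (1e-9, 1.0, 1.5, "ratio", False),   # CI touching the null crosses
        (1e-9, 0.5, 0.9, "ratio", True),    # protective, CI below 1
        (1e-9, 0.1, 0.4, "difference", True),
        (1e-9, -0.1, 0.4, "difference", False),
    ])
    def test_relevance_rule(self, p, lo, hi, scale, expected):
        assert gwas_relevant(association(p, lo, hi, scale), POLICY) is expected

    def test_classify_gwas_agreement(self):
        relevant = association(1e-9, 1.2, 1.5)
        irrelevant = association(0.5, 0.9, 1.5)
        assert classify_gwas([relevant, relevant], POLICY) is Verdict.CONCORDANT
        assert classify_gwas([relevant, irrelevant],
                             POLICY) is Verdict.DISCORDANT
        # agreement on irrelevance is still agreement
        assert classify_gwas([irrelevant, irrelevant],
                             POLICY) is Verdict.CONCORDANT
        assert classify_gwas([relevant], POLICY) is Verdict.CONCORDANT
        assert classify_gwas([], POLICY) is Verdict.NOT_APPLICABLE


class TestConcordanceSummary:
    def test_printed_style_gwas_percentage(self):
        fixture = generate_concordance_fixture(0, 0, 143, 1)
        dataset = integrate(fixture, DISORDER, ASSEMBLY)
        result = concordance_summary(dataset)
        assert (result.gwas_concordant, result.gwas_discordant) == (143, 1)
        assert result.gwas_percent == "99.31%"
        assert result.interp_percent == "-"  # no interpretation evidence

    def test_all_concordant_is_100(self):
        fixture = generate_concordance_fixture(5, 0, 3, 0)
        dataset = integrate(fixture, DISORDER, ASSEMBLY)
        result = concordance_summary(dataset)
        assert result.interp_percent == "100.00%"
        assert result.gwas_percent == "100.00%"

    def test_membership_only_variations_are_not_applicable(self):
        per_source = {"A": [make_record("A")]}  # no evidence at all
        dataset = integrate(per_source, DISORDER, ASSEMBLY)
        result = concordance_summary(dataset)
        (verdicts,) = result.verdicts.values()
        assert verdicts == (Verdict.NOT_APPLICABLE, Verdict.NOT_APPLICABLE)
        assert result.interp_percent == "-"
        # ... but they still count toward the CDL denominator
        assert cdl(dataset, "A").n_unique_total == 1

    def test_literal_denominator_flag(self):
        fixture = generate_concordance_fixture(3, 1, 0, 0)
        dataset = integrate(fixture, DISORDER, ASSEMBLY)
        literal = concordance_summary(
            dataset, ConcordancePolicy(denominator="all_unique"))
        assert literal.interp_fraction == Fraction(3, 4)
        evidence = concordance_summary(dataset)
        assert evidence.interp_fraction == Fraction(3, 4)
        # they diverge once evidence-free variations exist
        fixture["SourceA"].append(make_record("SourceA", start=999_999))
        dataset = integrate(fixture, DISORDER, ASSEMBLY)
        assert concordance_summary(dataset).interp_fraction == Fraction(3, 4)
        assert concordance_summary(
            dataset, ConcordancePolicy(denominator="all_unique")
        ).interp_fraction == Fraction(3, 5)

    def test_counts_match_naive_double_loop_oracle(self):
        fixture = generate_concordance_fixture(40, 7, 12, 3, seed=5)
        dataset = integrate(fixture, DISORDER, ASSEMBLY)
        result = concordance_summary(dataset)
        ic = idc = gc = gd = 0
        for variation in dataset.variations.values():
            if variation.assertions:
                classes = {POLICY.class_of(a.term_class)
                           for a in variation.assertions}
                if len(classes) == 1:
                    ic += 1
                else:
                    idc += 1
            if variation.statistics:
                flags = {gwas_relevant(s, POLICY)
                         for s in variation.statistics}
                if len(flags) == 1:
                    gc += 1
                else:
                    gd += 1
        assert (result.interp_concordant, result.interp_discordant) == (ic, idc)
        assert (result.gwas_concordant, result.gwas_discordant) == (gc, gd)

    def test_displayed_percent_rederivable_from_counts(self):
        fixture = generate_concordance_fixture(11, 3, 6, 2)
        dataset = integrate(fixture, DISORDER, ASSEMBLY)
        result = concordance_summary(dataset)
        assert result.interp_percent == format_percent(
            Fraction(result.interp_concordant,
                     result.interp_concordant + result.interp_discordant))
        assert result.gwas_percent == format_percent(
            Fraction(result.gwas_concordant,
                     result.gwas_concordant + result.gwas_discordant))


@settings(derandomize=True, max_examples=60)
@given(st.integers(0, 11), st.integers(1, 5))
def test_conflict_injection_never_increases_concordance(n_concordant, flips):
    """Flipping an assertion of a concordant variation to another equivalence
    class can only keep or reduce the concordant count."""
    fixture = generate_concordance_fixture(n_concordant, 0)
    dataset = integrate(fixture, DISORDER, ASSEMBLY)
    before = concordance_summary(dataset).interp_concordant
    keys = dataset.sorted_keys()
    for i in range(min(flips, len(keys))):
        variation = dataset.variations[keys[i]]
        old = variation.assertions[-1]
        variation.assertions[-1] = SignificanceAssertion(
            term_raw="Benign", term_class="benign", disorder=old.disorder,
            source_name=old.source_name, assertion_id=old.assertion_id)
    after = concordance_summary(dataset).interp_concordant
    assert after <= before


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.sampled_from(["pathogenic", "likely_pathogenic", "benign",
                                 "likely_benign", "uncertain_significance",
                                 "risk_factor"]), min_size=1, max_size=6))
def test_strict_concordant_implies_default_concordant(classes):
    """Strict mode can only split equivalence classes, never merge them."""
    assertions = [assertion(c, "S", f"a{i}") for i, c in enumerate(classes)]
    strict = classify_interpretation(assertions,
                                     ConcordancePolicy(strict_mode=True))
    default = classify_interpretation(assertions, POLICY)
    if strict is Verdict.CONCORDANT:
        assert default is Verdict.CONCORDANT


class TestAggregates:
    def test_group_cdl_sums_per_disorder_counts(self):
        datasets = []
        for offset, (n_a, n_b) in enumerate([(3, 4), (5, 1)]):
            per_source = {
                "A": [make_record("A", start=1000 * offset + i)
                      for i in range(n_a)],
                "B": [make_record("B", start=1000 * offset + 500 + i)
                      for i in range(n_b)],
            }
            datasets.append(integrate(per_source, DISORDER, ASSEMBLY))
        result = aggregate_cdl(datasets, "A", "group")
        assert (result.n_in_source, result.n_unique_total) == (8, 13)
        assert result.fraction == Fraction(8, 13)

    def test_group_concordance_recomputes_percent_from_summed_counts(self):
        parts = []
        for n_c, n_d in [(10, 1), (7, 0)]:
            fixture = generate_concordance_fixture(n_c, n_d)
            parts.append(concordance_summary(
                integrate(fixture, DISORDER, ASSEMBLY)))
        total = aggregate_concordance(parts, "group")
        assert (total.interp_concordant, total.interp_discordant) == (17, 1)
        assert total.interp_fraction == Fraction(17, 18)
        assert total.gwas_percent == "-"
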