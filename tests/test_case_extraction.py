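"""SMQ extraction, indication/outcome classification and descriptive tables."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from jaderpv.case_extraction import (
    SMQDefinition,
    assign_indications,
    case_outcome_class,
    classify_indication,
    classify_outcome,
    demographic_table,
    extract_smq_cases,
    indication_counts,
    outcome_mosaic_table,
    reporting_ratio,
)
from jaderpv.errors import ConfigurationError, DomainError
from jaderpv.records import (
    AgeBand,
    IndicationCategory as IC,
    Involvement,
    Outcome,
    OutcomeClass,
    Sex,
)

from conftest import BEVA, make_case


class TestExtractSMQCases:
    def test_listed_pt_code_included(self, smq):
        case = make_case("A", reactions=[("10018001", Outcome.RECOVERED, "")])
        assert extract_smq_cases([case], smq)

    def test_unlisted_code_excluded(self, smq):
        case = make_case("A", reactions=[("10019211", Outcome.RECOVERED, "")])
        assert extract_smq_cases([case], smq) == []

    def test_two_matching_reactions_dedup_to_one_case(self, smq):
        case = make_case(
            "A",
            reactions=[
                ("10018001", Outcome.RECOVERED, ""),
                ("10022694", Outcome.DEATH, ""),
            ],
        )
        out = extract_smq_cases([case], smq)
        assert len(out) == 1 and len(out[0].smq_reactions) == 2

    def test_subset_and_idempotent(self, smq):
        cases = [
            make_case("A", reactions=[("10018001", Outcome.RECOVERED, "")]),
            make_case("B", reactions=[("10019211", Outcome.RECOVERED, "")]),
        ]
        once = extract_smq_cases(cases, smq)
        assert {c.case_id for c in once} <= {c.case_id for c in cases}
        assert extract_smq_cases(once, smq) == once

    def test_empty_smq_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SMQDefinition(smq_code=1, pt_codes=frozenset(), pt_names={})


class TestClassifyIndication:
    @pytest.mark.parametrize(
        "reason,expected",
        [
            ("Lung adenocarcinoma", IC.NSCLC),
            ("Non-small cell lung cancer with distant metastasis", IC.NSCLC),
            ("Malignant neoplasms of the lung", IC.NSCLC),
            ("Colon cancer with distant metastasis", IC.COLORECTAL),
            ("Rectal cancer (rectal cancer)", IC.COLORECTAL),
            ("Breast cancer (right breast cancer)", IC.BREAST),
            ("Glioblastoma (recurrent glioblastoma)", IC.MALIGNANT_GLIOMA),
            ("Ovarian cancer (advanced ovarian cancer)", IC.OVARIAN),
            ("Cervical cancer (locally advanced cervical cancer)", IC.CERVICAL),
            ("Hepatocellular carcinoma (HCC treated)", IC.HEPATOCELLULAR),
            ("Gastric cancer", IC.OTHER),
            ("Malignant neoplasms of unknown primary site", IC.OTHER),
            ("", IC.NO_ENTRY),
            ("   ", IC.NO_ENTRY),
        ],
    )
    def test_reason_string_mapping(self, keyword_rules, reason, expected):
        assert classify_indication(reason, keyword_rules) is expected

    def test_multi_indication_union_drops_no_entry(self, keyword_rules):
        case = make_case(
            "A",
            drugs=[
                (BEVA, Involvement.SUSPECT, "", "Colon cancer"),
                (BEVA, Involvement.SUSPECT, "", "Ovarian cancer"),
                (BEVA, Involvement.SUSPECT, "", ""),
            ],
        )
        (out,) = assign_indications([case], BEVA, keyword_rules)
        assert out.indications == frozenset({IC.COLORECTAL, IC.OVARIAN})

    def test_blank_only_reasons_give_no_entry(self, keyword_rules):
        case = make_case("A", drugs=[(BEVA, Involvement.SUSPECT, "", "")])
        (out,) = assign_indications([case], BEVA, keyword_rules)
        assert out.indications == frozenset({IC.NO_ENTRY})


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "outcome,expected",
        [
            (Outcome.DEATH, OutcomeClass.NO_IMPROVEMENT),
            (Outcome.WITH_SEQUELAE, OutcomeClass.NO_IMPROVEMENT),
            (Outcome.NOT_RECOVERED, OutcomeClass.NO_IMPROVEMENT),
            (Outcome.IMPROVED, OutcomeClass.IMPROVEMENT),
            (Outcome.RECOVERED, OutcomeClass.IMPROVEMENT),
            (Outcome.UNKNOWN, OutcomeClass.EXCLUDED),
            (Outcome.MISSING, OutcomeClass.EXCLUDED),
        ],
    )
    def test_dichotomization(self, outcome, expected):
        assert classify_outcome(outcome) is expected

    def test_case_level_takes_worst_classified(self):
        case = make_case(
            "A",
            reactions=[
                ("10018001", Outcome.RECOVERED, ""),
                ("10022694", Outcome.DEATH, ""),
                ("10034674", Outcome.UNKNOWN, ""),
            ],
        )
        assert case_outcome_class(case) is OutcomeClass.NO_IMPROVEMENT

    def test_unknown_only_case_is_excluded(self):
        case = make_case("A", reactions=[("10018001", Outcome.UNKNOWN, "")])
        assert case_outcome_class(case) is OutcomeClass.EXCLUDED


class TestReportingRatio:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(1413, 11161, 12.7), (0, 100, 0.0), (46, 598, 7.7), (182, 767, 23.7)],
    )
    def test_half_up_percentages(self, count, total, expected):
        assert reporting_ratio(count, total) == expected

    def test_half_up_tie_rounds_up(self):
        assert reporting_ratio(9, 400) == 2.3  # 2.25 rounds up, not to even

    def test_zero_total_is_domain_error(self):
        with pytest.raises(DomainError):
            reporting_ratio(1, 0)

    def test_count_above_total_rejected(self):
        with pytest.raises(DomainError):
            reporting_ratio(5, 4)


class TestDemographicTable:
    def test_counts_and_percent_with_missing_excluded(self):
        cases = (
            [make_case(f"M{i}", sex=Sex.MALE) for i in range(3)]
            + [make_case(f"F{i}", sex=Sex.FEMALE) for i in range(5)]
            + [make_case("U0")]
        )
        frame = demographic_table(cases)
        sex = frame[frame.variable == "sex"].set_index("level")
        assert frame.attrs["sex_total"] == 8
        assert sex.loc["male", "count"] == 3 and sex.loc["male", "percent"] == 37.5
        assert sex.loc["female", "percent"] == 62.5

    def test_all_missing_sex_reports_zero_denominator(self):
        frame = demographic_table([make_case("A"), make_case("B")])
        assert frame.attrs["sex_total"] == 0
        assert frame[frame.variable == "sex"].empty

    def test_age_band_rows(self):
        cases = [make_case("A", age_band=AgeBand.IN_60S), make_case("B", age_band=AgeBand.IN_60S)]
        frame = demographic_table(cases)
        age = frame[frame.variable == "age"].set_index("level")
        assert age.loc["60-69", "count"] == 2 and age.loc["60-69", "percent"] == 100.0


class TestOutcomeMosaic:
    def _case(self, cid, outcome, cat=IC.COLORECTAL):
        c = make_case(cid, reactions=[("10018001", outcome, "")])
        return c.annotated(indications=frozenset({cat}))

    def test_even_split(self):
        cases = [self._case("A", Outcome.DEATH), self._case("B", Outcome.RECOVERED)]
        frame = outcome_mosaic_table(cases).set_index("indication")
        row = frame.loc["colorectal"]
        assert row.prop_improvement == 0.5 and row.prop_no_improvement == 0.5

    def test_proportions_sum_to_one_per_category(self):
        rng = np.random.default_rng(5)
        outcomes = [Outcome.DEATH, Outcome.RECOVERED, Outcome.IMPROVED, Outcome.NOT_RECOVERED]
        cases = [
            self._case(f"C{i}", outcomes[rng.integers(4)], cat)
            for i in range(60)
            for cat in [list(IC)[rng.integers(8)]]
        ]
        frame = outcome_mosaic_table(cases)
        assert np.allclose(frame.prop_improvement + frame.prop_no_improvement, 1.0)

    def test_excluded_only_category_omitted_and_flagged(self):
        cases = [self._case("A", Outcome.UNKNOWN, IC.BREAST)]
        frame = outcome_mosaic_table(cases)
        assert "breast" in frame.attrs["omitted"]
        assert "breast" not in set(frame.indication)

    def test_observed_proportion_within_binomial_band(self):
        """A synthetic cohort planted with P(no improvement) = 0.35 lands in
        the exact binomial 95% band at n = 2000."""
        rng = np.random.default_rng(42)
        p, n = 0.35, 2000
        cases = [
            self._case(f"C{i}", Outcome.DEATH if rng.random() < p else Outcome.RECOVERED)
            for i in range(n)
        ]
        frame = outcome_mosaic_table(cases).set_index("indication")
        observed = frame.loc["all", "n_no_improvement"]
        lo, hi = stats.binom.ppf([0.025, 0.975], n, p)
        assert lo <= observed <= hi

    def test_multi_indication_counts_in_each_stratum(self):
        c = make_case("A", reactions=[("10018001", Outcome.RECOVERED, "")]).annotated(
            indications=frozenset({IC.COLORECTAL, IC.OVARIAN})
        )
        counts = indication_counts([c]).set_index("indication")
        assert counts.loc["colorectal", "cases"] == 1
        assert counts.loc["ovarian", "cases"] == 1
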