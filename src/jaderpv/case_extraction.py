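"""Cohort definition: SMQ extraction, indication and outcome classification.

The analysis cohort is defined by a standardized MedDRA query (SMQ): a case
belongs to the cohort when at least one of its reported reactions carries a
preferred-term (PT) code in the SMQ.  The gastrointestinal-perforation SMQ
(code 20000107, 96 PTs) ships with the package.

Free-text "reason for use" entries are mapped to a closed set of indication
categories with an ordered, first-match-wins substring rule set; reaction
outcomes are dichotomized into improvement vs no-improvement, with unknown or
blank outcomes excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError
from .records import (
    CaseReport,
    IndicationCategory,
    Involvement,
    Outcome,
    OutcomeClass,
    Sex,
    AgeBand,
    normalize_name,
)

__all__ = [
    "SMQDefinition",
    "KeywordRuleSet",
    "load_gi_perforation_smq",
    "load_default_keyword_rules",
    "extract_smq_cases",
    "classify_indication",
    "assign_indications",
    "classify_outcome",
    "case_outcome_class",
    "annotate_outcomes",
    "reporting_ratio",
    "half_up_percent",
    "demographic_table",
    "indication_counts",
    "outcome_mosaic_table",
]

GI_PERFORATION_SMQ_CODE = 20000107


@dataclass(frozen=True)
class SMQDefinition:
    """A standardized MedDRA query: a set of PT codes naming one concept."""

    smq_code: int
    pt_codes: frozenset[str]
    pt_names: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.pt_codes:
            raise ConfigurationError("SMQ definition has no PT codes")

    def __contains__(self, pt_code: str) -> bool:
        return pt_code in self.pt_codes


def load_gi_perforation_smq(path: Optional[Union[str, Path]] = None) -> SMQDefinition:
    """Load the bundled gastrointestinal-perforation SMQ (96 PTs)."""
    if path is None:
        src = resources.files("jaderpv.data").joinpath("smq_gi_perforation.csv")
        with resources.as_file(src) as p:
            frame = pd.read_csv(p, dtype=str)
    else:
        frame = pd.read_csv(path, dtype=str)
    names = dict(zip(frame["pt_code"], frame["pt_name"]))
    return SMQDefinition(
        smq_code=GI_PERFORATION_SMQ_CODE,
        pt_codes=frozenset(frame["pt_code"]),
        pt_names=names,
    )


class KeywordRuleSet:
    """Ordered (substring pattern, category) rules; first match wins."""

    def __init__(self, rules: Sequence[tuple[str, IndicationCategory]]):
        if not rules:
            raise ConfigurationError("keyword rule set is empty")
        self.rules = [(p.casefold(), c) for p, c in rules]
        reachable = {c for _, c in self.rules}
        self.categories = reachable | {IndicationCategory.OTHER, IndicationCategory.NO_ENTRY}

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "KeywordRuleSet":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls([(r["pattern"], IndicationCategory(r["category"])) for r in doc["rules"]])


def load_default_keyword_rules() -> KeywordRuleSet:
    src = resources.files("jaderpv.data").joinpath("indication_keywords.yaml")
    with resources.as_file(src) as p:
        return KeywordRuleSet.from_yaml(p)


def extract_smq_cases(cases: Iterable[CaseReport], smq: SMQDefinition) -> list[CaseReport]:
    """Return cases with at least one reaction whose PT code is in the SMQ.

    Each retained case is annotated with its matching reactions
    (``smq_reactions``); a case with several matching reactions is returned
    once.  Re-application is idempotent and the output is a subset of the
    input.
    """
    out = []
    for c in cases:
        matches = [r for r in c.reactions if r.pt_code in smq.pt_codes]
        if matches:
            out.append(c.annotated(smq_reactions=matches))
    return out


def classify_indication(reason_for_use: str, rules: KeywordRuleSet) -> IndicationCategory:
    """Map a free-text reason-for-use string to an indication category.

    Blank input -> ``no_entry``; non-matching non-blank input -> ``other``.
    Deterministic: the first matching rule (in rule order) decides.
    """
    text = normalize_name(reason_for_use) if reason_for_use else ""
    if not text:
        return IndicationCategory.NO_ENTRY
    for pattern, category in rules.rules:
        if pattern in text:
            return category
    return IndicationCategory.OTHER


def assign_indications(
    cases: Iterable[CaseReport], drug_name: str, rules: KeywordRuleSet
) -> list[CaseReport]:
    """Annotate each case with the indication categories of the target drug.

    The reasons for use of every *suspect* record of ``drug_name`` are
    classified; a case carries the union of the resulting categories
    (multi-indication cases belong to each matching stratum).  ``no_entry``
    survives only when no record carries a classifiable reason.
    """
    target = normalize_name(drug_name)
    out = []
    for c in cases:
        reasons = [
            d.reason_for_use
            for d in c.drugs
            if d.involvement is Involvement.SUSPECT and normalize_name(d.generic_name) == target
        ]
        cats = {classify_indication(r, rules) for r in reasons}
        informative = cats - {IndicationCategory.NO_ENTRY}
        out.append(c.annotated(indications=frozenset(informative or {IndicationCategory.NO_ENTRY})))
    return out


_OUTCOME_CLASS = {
    Outcome.DEATH: OutcomeClass.NO_IMPROVEMENT,
    Outcome.WITH_SEQUELAE: OutcomeClass.NO_IMPROVEMENT,
    Outcome.NOT_RECOVERED: OutcomeClass.NO_IMPROVEMENT,
    Outcome.IMPROVED: OutcomeClass.IMPROVEMENT,
    Outcome.RECOVERED: OutcomeClass.IMPROVEMENT,
    Outcome.UNKNOWN: OutcomeClass.EXCLUDED,
    Outcome.MISSING: OutcomeClass.EXCLUDED,
}

# Worst-first severity order used to resolve conflicting per-reaction outcomes.
_SEVERITY = [
    Outcome.DEATH,
    Outcome.WITH_SEQUELAE,
    Outcome.NOT_RECOVERED,
    Outcome.IMPROVED,
    Outcome.RECOVERED,
]


def classify_outcome(outcome: Outcome) -> OutcomeClass:
    """Dichotomize a reaction outcome; unknown/blank outcomes are excluded."""
    return _OUTCOME_CLASS[outcome]


def case_outcome_class(case: CaseReport) -> OutcomeClass:
    """Case-level outcome: the worst classified outcome across its reactions.

    Only the SMQ-matching reactions are consulted when the case has been
    annotated by :func:`extract_smq_cases`.  Unknown/missing outcomes are
    ignored unless they are all the case reports.
    """
    reactions = case.smq_reactions or case.reactions
    outcomes = {r.outcome for r in reactions}
    for level in _SEVERITY:
        if level in outcomes:
            return classify_outcome(level)
    return OutcomeClass.EXCLUDED


def annotate_outcomes(cases: Iterable[CaseReport]) -> list[CaseReport]:
    return [c.annotated(outcome_class=case_outcome_class(c)) for c in cases]


def half_up_percent(count: int, denominator: int) -> float:
    """100*count/denominator with half-up rounding to one decimal."""
    if denominator <= 0:
        raise DomainError("denominator must be positive")
    pct = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def reporting_ratio(case_count: int, total_count: int) -> float:
    """Percentage of cohort cases among all reports, half-up to one decimal."""
    if total_count <= 0:
        raise DomainError("total_count must be positive")
    if case_count < 0 or case_count > total_count:
        raise DomainError("case_count must satisfy 0 <= case_count <= total_count")
    return half_up_percent(case_count, total_count)


def demographic_table(cases: Iterable[CaseReport]) -> pd.DataFrame:
    """Counts and percentages by sex and age band.

    Denominators are restricted to cases with a non-missing entry for the
    respective variable; the denominators are recorded in ``frame.attrs``
    (``sex_total``, ``age_total``) so that an all-missing variable is reported
    as denominator 0 with no level rows.
    """
    cases = list(cases)
    rows = []
    sex_known = [c for c in cases if c.sex is not Sex.MISSING]
    for level in (Sex.MALE, Sex.FEMALE):
        n = sum(1 for c in sex_known if c.sex is level)
        if sex_known:
            rows.append(("sex", level.value, n, half_up_percent(n, len(sex_known))))
    age_known = [c for c in cases if c.age_band is not AgeBand.MISSING]
    for band in AgeBand:
        if band is AgeBand.MISSING:
            continue
        n = sum(1 for c in age_known if c.age_band is band)
        if age_known:
            rows.append(("age", band.value, n, half_up_percent(n, len(age_known))))
    frame = pd.DataFrame(rows, columns=["variable", "level", "count", "percent"])
    frame.attrs["sex_total"] = len(sex_known)
    frame.attrs["age_total"] = len(age_known)
    return frame


def indication_counts(
    cases: Iterable[CaseReport],
    totals: Optional[Mapping[IndicationCategory, int]] = None,
) -> pd.DataFrame:
    """Per-indication case counts (multi-indication cases count in each
    matching stratum) and, when per-indication report totals are supplied,
    the reporting ratio of cohort cases to all reports for that indication."""
    counts = {cat: 0 for cat in IndicationCategory}
    for c in cases:
        for cat in c.indications:
            counts[cat] += 1
    rows = []
    for cat in IndicationCategory:
        row = {"indication": cat.value, "cases": counts[cat]}
        if totals is not None and cat in totals:
            row["total_reports"] = totals[cat]
            row["reporting_ratio"] = reporting_ratio(counts[cat], totals[cat])
        rows.append(row)
    return pd.DataFrame(rows)


def outcome_mosaic_table(cases: Iterable[CaseReport]) -> pd.DataFrame:
    """Cross-tabulate indication by dichotomized outcome.

    Excluded outcomes are dropped.  Categories whose cases are all excluded
    are omitted from the table and listed in ``frame.attrs['omitted']``.  An
    ``all`` row gives the overall split.  Within every emitted row,
    ``prop_improvement + prop_no_improvement == 1``.
    """
    cases = list(cases)
    by_cat: dict[str, list[OutcomeClass]] = {}
    for c in cases:
        oc = c.outcome_class if c.outcome_class is not None else case_outcome_class(c)
        for cat in c.indications or {IndicationCategory.NO_ENTRY}:
            by_cat.setdefault(cat.value, []).append(oc)
    by_cat["all"] = [
        c.outcome_class if c.outcome_class is not None else case_outcome_class(c) for c in cases
    ]
    rows, omitted = [], []
    order = [c.value for c in IndicationCategory] + ["all"]
    for cat in order:
        if cat not in by_cat:
            continue
        outcomes = [o for o in by_cat[cat] if o is not OutcomeClass.EXCLUDED]
        if not outcomes:
            omitted.append(cat)
            continue
        n_imp = sum(1 for o in outcomes if o is OutcomeClass.IMPROVEMENT)
        n_no = len(outcomes) - n_imp
        rows.append(
            {
                "indication": cat,
                "n_improvement": n_imp,
                "n_no_improvement": n_no,
                "n_classified": len(outcomes),
                "prop_improvement": n_imp / len(outcomes),
                "prop_no_improvement": n_no / len(outcomes),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "indication",
            "n_improvement",
            "n_no_improvement",
            "n_classified",
            "prop_improvement",
            "prop_no_improvement",
        ],
    )
    frame.attrs["omitted"] = omitted
    return frame
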