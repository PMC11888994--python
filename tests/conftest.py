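from __future__ import annotations

import pytest

from jaderpv.case_extraction import load_default_keyword_rules, load_gi_perforation_smq
from jaderpv.records import (
    CaseReport,
    DrugRecord,
    Involvement,
    Outcome,
    PartialDate,
    ReacRecord,
    Sex,
    AgeBand,
)

BEVA = "bevacizumab (genetical recombination)"


@pytest.fixture(scope="session")
def smq():
    return load_gi_perforation_smq()


@pytest.fixture(scope="session")
def keyword_rules():
    return load_default_keyword_rules()


def make_case(
    case_id="C1",
    sex=Sex.MISSING,
    age_band=AgeBand.MISSING,
    drugs=(),
    reactions=(),
):
    """Terse case builder.

    drugs: (name, involvement, start_date_str, reason) tuples.
    reactions: (pt_code, outcome, event_date_str) tuples.
    """
    drecs = [
        DrugRecord(
            case_id=case_id,
            generic_name=name,
            involvement=inv,
            start_date=PartialDate.parse(start),
            reason_for_use=reason,
        )
        for name, inv, start, reason in drugs
    ]
    rrecs = [
        ReacRecord(
            case_id=case_id,
            pt_code=pt,
            outcome=outcome,
            event_date=PartialDate.parse(event),
        )
        for pt, outcome, event in reactions
    ]
    return CaseReport(
        case_id=case_id, sex=sex, age_band=age_band, drugs=drecs, reactions=rrecs
    )


@pytest.fixture
def beva_case():
    return make_case(
        "B1",
        sex=Sex.FEMALE,
        drugs=[
            (BEVA, Involvement.SUSPECT, "20200101", "Lung adenocarcinoma"),
            ("paclitaxel", Involvement.SUSPECT, "20200101", "Lung adenocarcinoma"),
        ],
        reactions=[("10018001", Outcome.RECOVERED, "20200215")],
    )
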