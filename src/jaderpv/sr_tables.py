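"""Reading, joining and filtering the four JADER-dialect tables.

JADER is distributed as four CSV tables keyed by an opaque case identifier:
DEMO (patient demographics), DRUG (one row per reported drug), HIST (primary
disease) and REAC (one row per adverse event).  PMDA files carry Japanese
headers that have changed across quarters, so the mapping from physical
column names to canonical fields is configuration (see
:data:`DEFAULT_COLUMN_MAPS`), not code.  Files default to Shift-JIS with a
UTF-8 fallback, matching the PMDA distribution encoding.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import IntegrityError, TableFormatError
from .records import (
    AgeBand,
    CaseReport,
    DemoRecord,
    DrugRecord,
    HistRecord,
    Involvement,
    Outcome,
    PartialDate,
    ReacRecord,
    Sex,
    normalize_name,
)

__all__ = [
    "DEFAULT_COLUMN_MAPS",
    "read_table",
    "records_from_frame",
    "join_cases",
    "filter_suspect",
    "cases_to_tables",
    "write_tables",
]

logger = logging.getLogger(__name__)

#: Canonical field -> accepted physical header names, per table kind.  The
#: first name is what :func:`cases_to_tables` writes.  Fields marked optional
#: below may be absent from the file.
DEFAULT_COLUMN_MAPS: dict[str, dict[str, list[str]]] = {
    "demo": {
        "case_id": ["case_id", "識別番号"],
        "sex": ["sex", "性別"],
        "age_band": ["age_band", "age", "年齢"],
        "reporting_year": ["reporting_year", "報告年度", "報告年"],
    },
    "drug": {
        "case_id": ["case_id", "識別番号"],
        "generic_name": ["generic_name", "医薬品（一般名）", "一般名"],
        "involvement": ["involvement", "医薬品の関与", "関与"],
        "start_date": ["start_date", "投与開始日"],
        "reason_for_use": ["reason_for_use", "使用理由"],
    },
    "hist": {
        "case_id": ["case_id", "識別番号"],
        "primary_disease": ["primary_disease", "原疾患等", "原疾患"],
    },
    "reac": {
        "case_id": ["case_id", "識別番号"],
        "pt_code": ["pt_code", "有害事象コード", "PTコード"],
        "pt_name": ["pt_name", "有害事象", "PT名"],
        "outcome": ["outcome", "転帰"],
        "event_date": ["event_date", "有害事象の発現日", "発現日"],
    },
}

_OPTIONAL_COLUMNS = {
    "demo": {"sex", "age_band", "reporting_year"},
    "drug": {"start_date", "reason_for_use"},
    "hist": set(),
    "reac": {"pt_name", "outcome", "event_date"},
}

_SEX_VALUES = {
    "male": Sex.MALE,
    "男性": Sex.MALE,
    "男": Sex.MALE,
    "female": Sex.FEMALE,
    "女性": Sex.FEMALE,
    "女": Sex.FEMALE,
    "missing": Sex.MISSING,
    "": Sex.MISSING,
}

_INVOLVEMENT_VALUES = {
    "suspect": Involvement.SUSPECT,
    "被疑薬": Involvement.SUSPECT,
    "concomitant": Involvement.CONCOMITANT,
    "併用薬": Involvement.CONCOMITANT,
    "interaction": Involvement.INTERACTION,
    "相互作用": Involvement.INTERACTION,
}

_OUTCOME_VALUES = {
    "death": Outcome.DEATH,
    "死亡": Outcome.DEATH,
    "with_sequelae": Outcome.WITH_SEQUELAE,
    "with sequelae": Outcome.WITH_SEQUELAE,
    "後遺症あり": Outcome.WITH_SEQUELAE,
    "not_recovered": Outcome.NOT_RECOVERED,
    "not recovered": Outcome.NOT_RECOVERED,
    "未回復": Outcome.NOT_RECOVERED,
    "improved": Outcome.IMPROVED,
    "軽快": Outcome.IMPROVED,
    "recovered": Outcome.RECOVERED,
    "回復": Outcome.RECOVERED,
    "unknown": Outcome.UNKNOWN,
    "不明": Outcome.UNKNOWN,
    "missing": Outcome.MISSING,
    "": Outcome.MISSING,
}

_AGE_BANDS = {
    AgeBand.IN_30S: 30,
    AgeBand.IN_40S: 40,
    AgeBand.IN_50S: 50,
    AgeBand.IN_60S: 60,
    AgeBand.IN_70S: 70,
}


def _parse_sex(raw: str) -> Sex:
    v = _SEX_VALUES.get(raw.strip().casefold())
    if v is None:
        logger.warning("unparseable sex value %r mapped to missing", raw)
        return Sex.MISSING
    return v


def _parse_age_band(raw: str) -> AgeBand:
    s = raw.strip()
    if not s or s.casefold() == "missing":
        return AgeBand.MISSING
    for band in AgeBand:
        if s == band.value:
            return band
    import re

    m = re.search(r"(\d+)", s)
    if m:
        decade = (int(m.group(1)) // 10) * 10
        if decade <= 20:
            return AgeBand.LE_29
        if decade >= 80:
            return AgeBand.GE_80
        for band, lo in _AGE_BANDS.items():
            if lo == decade:
                return band
    logger.warning("unparseable age value %r mapped to missing", raw)
    return AgeBand.MISSING


def _parse_enum(raw: str, table: Mapping[str, object], what: str):
    v = table.get(raw.strip().casefold(), None)
    if v is None:
        v = table.get(raw.strip(), None)  # Japanese values are not casefolded
    if v is None:
        logger.warning("unparseable %s value %r mapped to missing", what, raw)
        return None
    return v


def _resolve_columns(
    df: pd.DataFrame, table_kind: str, column_map: Optional[Mapping[str, Sequence[str]]]
) -> dict[str, Optional[str]]:
    cmap = column_map or DEFAULT_COLUMN_MAPS[table_kind]
    resolved: dict[str, Optional[str]] = {}
    for field, names in cmap.items():
        found = next((n for n in names if n in df.columns), None)
        if found is None and field not in _OPTIONAL_COLUMNS[table_kind]:
            raise TableFormatError(
                f"{table_kind.upper()} table is missing mandatory column "
                f"{field!r} (accepted headers: {list(names)})"
            )
        resolved[field] = found
    return resolved


def _read_csv(path, encoding: Optional[str], delimiter: str) -> pd.DataFrame:
    kwargs = dict(sep=delimiter, dtype=str, keep_default_na=False)
    try:
        if encoding is not None:
            return pd.read_csv(path, encoding=encoding, **kwargs)
        try:
            return pd.read_csv(path, encoding="cp932", **kwargs)
        except UnicodeDecodeError:
            return pd.read_csv(path, encoding="utf-8", **kwargs)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_table(
    path: Union[str, Path],
    table_kind: str,
    *,
    column_map: Optional[Mapping[str, Sequence[str]]] = None,
    encoding: Optional[str] = None,
    delimiter: str = ",",
) -> list:
    """Read one JADER-dialect CSV table into typed records.

    Parameters
    ----------
    path : path to the CSV file.
    table_kind : one of ``"demo"``, ``"drug"``, ``"hist"``, ``"reac"``.
    column_map : canonical field -> accepted header names; defaults to
        :data:`DEFAULT_COLUMN_MAPS` (English canonical + Japanese headers).
    encoding : force an encoding; default tries Shift-JIS (cp932) and falls
        back to UTF-8.

    Unparseable enum values are mapped to ``missing`` with a logged warning;
    partial dates are preserved, never coerced.
    """
    if table_kind not in DEFAULT_COLUMN_MAPS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_csv(path, encoding, delimiter)
    return records_from_frame(df, table_kind, column_map=column_map)


def records_from_frame(
    df: pd.DataFrame,
    table_kind: str,
    *,
    column_map: Optional[Mapping[str, Sequence[str]]] = None,
) -> list:
    """Parse an in-memory table (all-string cells) into typed records.

    Shares all parsing rules with :func:`read_table`; used directly by the
    synthetic-data path so in-memory and on-disk runs take one code path.
    """
    if table_kind not in DEFAULT_COLUMN_MAPS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    if df.empty and len(df.columns) == 0:
        return []
    cols = _resolve_columns(df, table_kind, column_map)

    def get(row, field, default=""):
        c = cols.get(field)
        return row[c] if c is not None else default

    out: list = []
    for _, row in df.iterrows():
        cid = str(get(row, "case_id")).strip()
        if table_kind == "demo":
            year_raw = str(get(row, "reporting_year")).strip()
            year = int(year_raw) if year_raw.isdigit() else None
            out.append(
                DemoRecord(
                    case_id=cid,
                    sex=_parse_sex(str(get(row, "sex"))),
                    age_band=_parse_age_band(str(get(row, "age_band"))),
                    reporting_year=year,
                )
            )
        elif table_kind == "drug":
            inv = _parse_enum(str(get(row, "involvement")), _INVOLVEMENT_VALUES, "involvement")
            if inv is None:
                continue  # a drug row without a readable involvement is unusable
            out.append(
                DrugRecord(
                    case_id=cid,
                    generic_name=str(get(row, "generic_name")).strip(),
                    involvement=inv,
                    start_date=PartialDate.parse(str(get(row, "start_date"))),
                    reason_for_use=str(get(row, "reason_for_use")).strip(),
                )
            )
        elif table_kind == "hist":
            out.append(HistRecord(case_id=cid, primary_disease=str(get(row, "primary_disease")).strip()))
        else:  # reac
            code = str(get(row, "pt_code")).strip()
            if code and not (len(code) == 8 and code.isdigit()):
                logger.warning("PT code %r is not 8 decimal digits", code)
            outcome = _parse_enum(str(get(row, "outcome")), _OUTCOME_VALUES, "outcome")
            out.append(
                ReacRecord(
                    case_id=cid,
                    pt_code=code,
                    pt_name=str(get(row, "pt_name")).strip(),
                    outcome=outcome if outcome is not None else Outcome.MISSING,
                    event_date=PartialDate.parse(str(get(row, "event_date"))),
                )
            )
    return out


def join_cases(
    demo: Iterable[DemoRecord],
    drug: Iterable[DrugRecord] = (),
    hist: Iterable[HistRecord] = (),
    reac: Iterable[ReacRecord] = (),
    *,
    with_stats: bool = False,
):
    """Integrate the four tables into one :class:`CaseReport` per DEMO row.

    The join is outer on DEMO: child lists may be empty, and child rows whose
    case id has no DEMO row (orphans) are excluded, counted and logged — never
    dropped silently.  A duplicate DEMO case id raises :class:`IntegrityError`.
    """
    cases: dict[str, CaseReport] = {}
    for d in demo:
        if d.case_id in cases:
            raise IntegrityError(f"duplicate DEMO case_id {d.case_id!r}")
        cases[d.case_id] = CaseReport(
            case_id=d.case_id, sex=d.sex, age_band=d.age_band, reporting_year=d.reporting_year
        )
    orphans = {"drug": 0, "hist": 0, "reac": 0}
    for r in drug:
        if r.case_id in cases:
            cases[r.case_id].drugs.append(r)
        else:
            orphans["drug"] += 1
    for r in hist:
        if r.case_id in cases:
            cases[r.case_id].primary_diseases.append(r.primary_disease)
        else:
            orphans["hist"] += 1
    for r in reac:
        if r.case_id in cases:
            cases[r.case_id].reactions.append(r)
        else:
            orphans["reac"] += 1
    total_orphans = sum(orphans.values())
    if total_orphans:
        logger.info("join excluded %d orphan child rows: %s", total_orphans, orphans)
    result = list(cases.values())
    if with_stats:
        return result, {"n_cases": len(result), "orphans": orphans}
    return result


def filter_suspect(cases: Iterable[CaseReport], drug_name: str) -> list[CaseReport]:
    """Keep cases where ``drug_name`` appears with *suspect* involvement.

    Matching is exact on the generic-name string after whitespace
    normalization and ASCII case-folding; concomitant-only mentions do not
    qualify.  All drug rows of a retained case are kept.
    """
    if not drug_name or not drug_name.strip():
        raise ValueError("drug_name must be non-empty")
    target = normalize_name(drug_name)
    return [
        c
        for c in cases
        if any(
            normalize_name(d.generic_name) == target and d.involvement is Involvement.SUSPECT
            for d in c.drugs
        )
    ]


def cases_to_tables(cases: Iterable[CaseReport]) -> dict[str, pd.DataFrame]:
    """Write :class:`CaseReport` objects back to the four-table form.

    Re-joining the returned tables reproduces the same cases field by field
    (annotations excluded) — the round-trip property the tests assert.
    """
    demo, drug, hist, reac = [], [], [], []
    for c in cases:
        demo.append(
            {
                "case_id": c.case_id,
                "sex": c.sex.value,
                "age_band": c.age_band.value,
                "reporting_year": "" if c.reporting_year is None else str(c.reporting_year),
            }
        )
        for d in c.drugs:
            drug.append(
                {
                    "case_id": d.case_id,
                    "generic_name": d.generic_name,
                    "involvement": d.involvement.value,
                    "start_date": d.start_date.isoformat() if d.start_date else "",
                    "reason_for_use": d.reason_for_use,
                }
            )
        for p in c.primary_diseases:
            hist.append({"case_id": c.case_id, "primary_disease": p})
        for r in c.reactions:
            reac.append(
                {
                    "case_id": r.case_id,
                    "pt_code": r.pt_code,
                    "pt_name": r.pt_name,
                    "outcome": r.outcome.value,
                    "event_date": r.event_date.isoformat() if r.event_date else "",
                }
            )
    cols = {k: [f for f in DEFAULT_COLUMN_MAPS[k]] for k in DEFAULT_COLUMN_MAPS}
    return {
        "demo": pd.DataFrame(demo, columns=cols["demo"]),
        "drug": pd.DataFrame(drug, columns=cols["drug"]),
        "hist": pd.DataFrame(hist, columns=cols["hist"]),
        "reac": pd.DataFrame(reac, columns=cols["reac"]),
    }


def write_tables(cases: Iterable[CaseReport], out_dir: Union[str, Path]) -> dict[str, Path]:
    """Serialize cases to ``demo.csv``/``drug.csv``/``hist.csv``/``reac.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, frame in cases_to_tables(cases).items():
        p = out_dir / f"{kind}.csv"
        frame.to_csv(p, index=False)
        paths[kind] = p
    return paths
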