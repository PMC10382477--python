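"""Shared fixtures: a 12-case hand-enumerated corpus exercising every
screening rule, plus a writer that dumps in-memory tables in the
quarterly '$'-delimited file dialect."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from faerspv.faers_io import Corpus, TABLE_NAMES


def write_plain_corpus(tables: dict[str, pd.DataFrame], directory: Path, token: str = "20Q1") -> None:
    """Write tables as one quarter of '$'-delimited files."""
    directory.mkdir(parents=True, exist_ok=True)
    for t in TABLE_NAMES:
        df = tables[t]
        lines = ["$".join(c.upper() for c in df.columns)]
        lines += ["$".join(map(str, row)) for row in df.itertuples(index=False, name=None)]
        (directory / f"{t.upper()}{token}.txt").write_text("\n".join(lines) + "\n")


def _demo_row(pid, caseid, fda, event="", age="", cod="", sex="", occp="", rep="", occr=""):
    return dict(primaryid=pid, caseid=str(caseid), caseversion="1", fda_dt=fda, event_dt=event,
                age=age, age_cod=cod, sex=sex, occp_cod=occp,
                reporter_country=rep, occr_country=occr)


def hand_tables() -> dict[str, pd.DataFrame]:
    """Twelve cases covering dedup, tie-breaks, multi-PS exclusion,
    brand-name matching, event set semantics, statin co-exposure, and
    every time-to-onset exclusion reason. Expectations live in
    HAND_EXPECTED below."""
    demo = pd.DataFrame([
        # case 1: two versions, latest FDA_DT (102) survives; sertraline + statin; evaluable? start missing
        _demo_row(101, 1, "20200101"),
        _demo_row(102, 1, "20210101", event="20210301", age="40", cod="YR", sex="F", occp="MD", occr="US"),
        # case 2: same FDA_DT twice -> highest PRIMARYID (202) survives; fluoxetine; TTO 9 d
        _demo_row(201, 2, "20210601"),
        _demo_row(202, 2, "20210601", event="20210110", age="17", cod="YR", sex="M", occp="CN", occr="US"),
        # case 3: multi-PS (sertraline + fluoxetine) -> excluded
        _demo_row(301, 3, "20210101", sex="F"),
        # case 4: non-target PS, event only
        _demo_row(401, 4, "20210101"),
        # case 5: paroxetine but no target event
        _demo_row(501, 5, "20210101"),
        # case 6: escitalopram (word-boundary: not citalopram); age 65 in 18-65 band; TTO 10 d
        _demo_row(601, 6, "20200101", event="20200111", age="65", cod="YR", sex="F", occp="", occr="FR"),
        # case 7: Myoglobinuria only -> not an event case
        _demo_row(701, 7, "20210101"),
        # case 8: missing-FDA_DT version sorts first, 802 survives; partial EVENT_DT -> TTO excluded
        _demo_row(801, 8, ""),
        _demo_row(802, 8, "20200301", event="202003", age="793", cod="MON", sex="F", occp="PH", occr="GB"),
        # case 9: fluvoxamine; EVENT_DT precedes START_DT -> negative duration excluded
        _demo_row(901, 9, "20200201", event="20200101", age="25", cod="YR", sex="M", occp="OT", occr="JP"),
        # case 10: sertraline, no THER row; outcomes DE + HO; age unknown
        _demo_row(1001, 10, "20200401", event="20200401", sex="", occp="LW", occr="US"),
        # case 11: sertraline, same-day onset (0 d included); outcome CA -> folds into OT
        _demo_row(1101, 11, "20200501", event="20200201", age="30", cod="YR", sex="M", occp="RN", occr="IT"),
        # case 12: citalopram (brand) + statin; TTO 425 d (> 1 year); country falls back to REPORTER_COUNTRY
        _demo_row(1201, 12, "20210401", event="20210301", age="8", cod="DEC", sex="M", occp="", rep="DE", occr=""),
    ])
    drug = pd.DataFrame(
        [
            (102, "1", "1", "PS", "SERTRALINE"),
            (102, "1", "2", "C", "SIMVASTATIN"),
            (202, "2", "1", "PS", "PROZAC 20MG"),
            (301, "3", "1", "PS", "SERTRALINE"),
            (301, "3", "2", "PS", "FLUOXETINE"),
            (401, "4", "1", "PS", "IBUPROFEN"),
            (501, "5", "1", "PS", "PAXIL"),
            (601, "6", "1", "PS", "ESCITALOPRAM OXALATE"),
            (701, "7", "1", "PS", "CITALOPRAM HYDROBROMIDE"),
            (802, "8", "1", "PS", "ZOLOFT"),
            (901, "9", "1", "PS", "LUVOX"),
            (1001, "10", "1", "PS", "SERTRALINE HCL 50MG"),
            (1101, "11", "1", "PS", "SERTRALINE"),
            (1201, "12", "1", "PS", "CELEXA"),
            (1201, "12", "2", "C", "LIPITOR"),
        ],
        columns=["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    )
    reac = pd.DataFrame(
        [
            (102, "1", "Rhabdomyolysis"),
            (202, "2", "RHABDOMYOLYSIS"),
            (202, "2", "Rhabdomyolysis"),  # duplicate PT rows count once
            (301, "3", "Rhabdomyolysis"),
            (401, "4", "rhabdomyolysis"),
            (501, "5", "Nausea"),
            (601, "6", "Rhabdomyolysis"),
            (701, "7", "Myoglobinuria"),
            (802, "8", "Rhabdomyolysis"),
            (901, "9", "Rhabdomyolysis"),
            (1001, "10", "Rhabdomyolysis"),
            (1101, "11", "Rhabdomyolysis"),
            (1201, "12", "Rhabdomyolysis"),
        ],
        columns=["primaryid", "caseid", "pt"],
    )
    ther = pd.DataFrame(
        [
            (102, "1", "1", "", ""),  # start missing -> unusable
            (202, "2", "1", "20210101", ""),
            (601, "6", "1", "20200101", ""),
            (802, "8", "1", "20200101", ""),
            (901, "9", "1", "20200110", ""),
            (1101, "11", "1", "20200201", ""),
            (1201, "12", "1", "20200101", ""),
        ],
        columns=["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    )
    outc = pd.DataFrame(
        [
            (1001, "10", "DE"),
            (1001, "10", "HO"),
            (1101, "11", "CA"),
        ],
        columns=["primaryid", "caseid", "outc_cod"],
    )
    return {"demo": demo, "drug": drug, "reac": reac, "ther": ther, "outc": outc}


HAND_EXPECTED = {
    "n_total": 12,
    "survivors": {102, 202, 301, 401, 501, 601, 701, 802, 901, 1001, 1101, 1201},
    "drug_case_ids": {
        "sertraline": {102, 802, 1001, 1101},
        "fluoxetine": {202},
        "paroxetine": {501},
        "escitalopram": {601},
        "citalopram": {701, 1201},  # case 7 is a drug case without the target event
        "fluvoxamine": {901},
    },
    "excluded_multi_ps": {301},
    "event_case_ids": {102, 202, 301, 401, 601, 802, 901, 1001, 1101, 1201},
    "pooled_drug_event": {102, 202, 601, 802, 901, 1001, 1101, 1201},
    "statin_in_pooled_drug": {102, 1201},
    # TTO: evaluable durations 9 (fluoxetine), 10 (escitalopram), 0 (sertraline), 425 (citalopram)
    "tto_durations": [0, 9, 10, 425],
    "tto_exclusions": {
        "no_therapy_row": 1,       # case 10
        "start_date_unusable": 1,  # case 1 (blank START_DT)
        "event_date_unusable": 1,  # case 8 (month-precision EVENT_DT)
        "negative_duration": 1,    # case 9
    },
    # demographics over the 8 drug-event cases
    "age_bands": {"<18": 1, "18-65": 4, ">65": 2, "unknown": 1},
    "sex": {"F": 3, "M": 4, "unknown": 1},
    "reporter": {"health-professional": 4, "consumer/lawyer": 2, "unknown": 2},
    "outcome_counts": {"DE": 1, "HO": 1, "OT": 1, "LT": 0, "DS": 0, "RI": 0},
}


@pytest.fixture(scope="session")
def hand_corpus() -> Corpus:
    t = hand_tables()
    return Corpus(**t, orphans_dropped={}, skipped_rows={})


@pytest.fixture()
def hand_corpus_dir(tmp_path: Path) -> Path:
    d = tmp_path / "corpus"
    write_plain_corpus(hand_tables(), d)
    return d
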