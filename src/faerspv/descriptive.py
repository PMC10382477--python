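"""Descriptive analyses over a screened cohort.

Three summaries mirror the usual pharmacovigilance case-series tables:

* demographics/administrative characteristics (age, sex, reporter
  class, reporting country), per target drug and pooled;
* time-to-onset: days from therapy start (THER.START_DT of the row
  linked to the case's primary-suspect target drug) to the adverse
  event date (DEMO.EVENT_DT), with input-error exclusions;
* serious-outcome counts and proportions (outcome codes are not
  mutually exclusive — one case can be both hospitalised and fatal).

Age handling follows the FAERS AGE/AGE_COD convention: values are
normalised to years (YR x1, DEC x10, MON /12, WK /52.18, DY /365.25,
HR /8766) and anything outside [0, 130] or with an unknown unit code is
treated as unknown. Age bands are <18, 18-65 (both ends inclusive) and
>65.

Only full calendar dates enter duration arithmetic: a year- or
month-precision START_DT/EVENT_DT is an "inaccurate date" and the case
is excluded from time-to-onset, as are negative durations and cases
with no linkable therapy row. Exclusion reasons partition the
non-evaluable cases (each case is counted under the first applicable
reason, in that order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dates import parse_faers_date
from .dictionary import DrugDictionary
from .faers_io import Corpus
from .screening import ScreenedCohort

logger = logging.getLogger(__name__)

__all__ = [
    "TTOStats",
    "TimeToOnsetSummary",
    "OutcomeSummary",
    "GroupDemographics",
    "time_to_onset",
    "outcome_summary",
    "demographics_table",
    "normalize_age_years",
    "POOLED",
]

POOLED = "all"

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "RI", "OT")

_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766}

_HEALTH_PROFESSIONAL = {"MD", "PH", "OT", "RN", "HP"}
_CONSUMER_LAWYER = {"CN", "LW"}


def normalize_age_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Age in years; NaN where the value or unit is unusable or outside [0, 130]."""
    value = pd.to_numeric(age, errors="coerce")
    factor = age_cod.fillna("").str.strip().str.upper().map(_AGE_FACTORS)
    years = value * factor
    return years.where((years >= 0) & (years <= 130))


@dataclass(frozen=True)
class TTOStats:
    n_evaluable: int
    median: float
    q1: float
    q3: float
    within_one_year_fraction: float


def _tto_stats(durations: np.ndarray) -> TTOStats:
    if durations.size == 0:
        return TTOStats(0, float("nan"), float("nan"), float("nan"), float("nan"))
    q1, med, q3 = np.percentile(durations, [25, 50, 75])  # linear interpolation
    return TTOStats(
        n_evaluable=int(durations.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        within_one_year_fraction=float(np.mean(durations <= 365)),
    )


@dataclass
class TimeToOnsetSummary:
    overall: TTOStats
    per_drug: dict[str, TTOStats]
    exclusions: dict[str, int]
    durations_by_drug: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"group": POOLED, **vars(self.overall)}]
        rows += [{"group": d, **vars(s)} for d, s in self.per_drug.items()]
        return pd.DataFrame(rows)


def _full_date_days(raw: pd.Series) -> pd.Series:
    """Days since epoch for full-precision dates, NaN otherwise."""
    uniques = {}
    for u in raw.unique():
        fd = parse_faers_date(u)
        uniques[u] = fd.to_date().toordinal() if fd.is_full else np.nan
    return raw.map(uniques)


def time_to_onset(
    cohort: ScreenedCohort, corpus: Corpus, target_dict: DrugDictionary
) -> TimeToOnsetSummary:
    """Therapy-start to event-date durations for the drug-event cases.

    The linked therapy row is the THER row whose ``dsg_drug_seq`` equals
    the ``drug_seq`` of a PS-role row canonicalising to the case's
    assigned drug; with several such rows, the earliest full START_DT is
    used.
    """
    assert cohort.dedup is not None, "cohort must carry its deduplicated DEMO table"
    demo = cohort.dedup.demo.set_index("primaryid")
    exclusions = {"no_therapy_row": 0, "start_date_unusable": 0, "event_date_unusable": 0,
                  "negative_duration": 0}
    durations_by_drug: dict[str, np.ndarray] = {}

    drug_rows = corpus.drug
    canon_all = target_dict.match_series(drug_rows["drugname"])
    ther = corpus.ther.copy()
    ther["_seq"] = pd.to_numeric(ther["dsg_drug_seq"], errors="coerce")
    ther["_start_days"] = _full_date_days(ther["start_dt"].fillna(""))

    for drug_name, ids in cohort.drug_event_case_ids.items():
        if not ids:
            durations_by_drug[drug_name] = np.array([])
            continue
        ps = drug_rows[
            drug_rows["primaryid"].isin(ids)
            & (drug_rows["role_cod"].str.strip().str.upper() == "PS")
            & (canon_all == drug_name)
        ][["primaryid", "drug_seq"]].copy()
        ps["_seq"] = pd.to_numeric(ps["drug_seq"], errors="coerce")
        linked = ps.merge(ther[["primaryid", "_seq", "_start_days"]], on=["primaryid", "_seq"])
        has_ther = set(linked["primaryid"].tolist())
        exclusions["no_therapy_row"] += len(ids - has_ther)
        start = linked.groupby("primaryid")["_start_days"].min()  # earliest full start; NaN-aware
        usable_start = start.dropna()
        exclusions["start_date_unusable"] += int(start.isna().sum())

        event_raw = demo.loc[demo.index.intersection(list(usable_start.index)), "event_dt"]
        event_days = _full_date_days(event_raw.fillna("")).reindex(usable_start.index)
        bad_event = event_days.isna()
        exclusions["event_date_unusable"] += int(bad_event.sum())
        dur = (event_days[~bad_event] - usable_start[~bad_event]).astype(float)
        neg = dur < 0
        exclusions["negative_duration"] += int(neg.sum())
        durations_by_drug[drug_name] = dur[~neg].to_numpy()

    all_durations = (
        np.concatenate([v for v in durations_by_drug.values()])
        if durations_by_drug
        else np.array([])
    )
    return TimeToOnsetSummary(
        overall=_tto_stats(all_durations),
        per_drug={d: _tto_stats(v) for d, v in durations_by_drug.items()},
        exclusions=exclusions,
        durations_by_drug=durations_by_drug,
    )


@dataclass
class OutcomeSummary:
    """Distinct-case counts and proportions per serious-outcome code.

    ``counts[group][code]``; groups are the pooled cohort plus each
    drug. Proportions are over the group's case count and can sum to
    more than 1 because codes are not mutually exclusive.
    """

    counts: dict[str, dict[str, int]]
    group_sizes: dict[str, int]

    @property
    def proportions(self) -> dict[str, dict[str, float]]:
        return {
            g: {
                code: (c / self.group_sizes[g] if self.group_sizes[g] else 0.0)
                for code, c in codes.items()
            }
            for g, codes in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions
        rows = [
            {"group": g, "outcome": code, "n": self.counts[g][code],
             "proportion": props[g][code], "group_size": self.group_sizes[g]}
            for g in self.counts
            for code in OUTCOME_CODES
        ]
        return pd.DataFrame(rows)


def outcome_summary(cohort: ScreenedCohort, outc: pd.DataFrame) -> OutcomeSummary:
    """Serious-outcome tallies over the drug-event cases.

    The legacy CA (congenital anomaly) code is folded into OT.
    """
    code = outc["outc_cod"].astype(str).str.strip().str.upper()
    if (code == "CA").any():
        logger.info("outcome_summary: folding %d CA row(s) into OT", int((code == "CA").sum()))
    code = code.replace({"CA": "OT"})
    rows = pd.DataFrame({"primaryid": outc["primaryid"], "code": code})
    rows = rows[rows["code"].isin(OUTCOME_CODES)]

    groups = {POOLED: cohort.pooled_drug_event_case_ids, **cohort.drug_event_case_ids}
    counts: dict[str, dict[str, int]] = {}
    for g, ids in groups.items():
        sub = rows[rows["primaryid"].isin(ids)]
        per_code = sub.groupby("code")["primaryid"].nunique()
        counts[g] = {c: int(per_code.get(c, 0)) for c in OUTCOME_CODES}
    return OutcomeSummary(counts=counts, group_sizes={g: len(ids) for g, ids in groups.items()})


@dataclass
class GroupDemographics:
    n: int
    age_median: float
    age_q1: float
    age_q3: float
    age_bands: dict[str, int]  # "<18", "18-65", ">65", "unknown"
    sex: dict[str, int]  # "F", "M", "unknown"
    reporter: dict[str, int]  # "health-professional", "consumer/lawyer", "unknown"
    countries: dict[str, int]  # top-k reporting countries


def _group_demographics(demo: pd.DataFrame, top_k: int) -> GroupDemographics:
    years = normalize_age_years(demo.get("age", pd.Series(dtype=object)),
                                demo.get("age_cod", pd.Series(dtype=object)))
    known = years.dropna()
    if known.size:
        q1, med, q3 = np.percentile(known, [25, 50, 75])
    else:
        q1 = med = q3 = float("nan")
    bands = {
        "<18": int((known < 18).sum()),
        "18-65": int(((known >= 18) & (known <= 65)).sum()),
        ">65": int((known > 65).sum()),
        "unknown": int(len(demo) - known.size),
    }
    sex_raw = demo.get("sex", pd.Series(dtype=object)).fillna("").str.strip().str.upper()
    sex = {
        "F": int((sex_raw == "F").sum()),
        "M": int((sex_raw == "M").sum()),
    }
    sex["unknown"] = len(demo) - sex["F"] - sex["M"]
    occp = demo.get("occp_cod", pd.Series(dtype=object)).fillna("").str.strip().str.upper()
    reporter = {
        "health-professional": int(occp.isin(_HEALTH_PROFESSIONAL).sum()),
        "consumer/lawyer": int(occp.isin(_CONSUMER_LAWYER).sum()),
    }
    reporter["unknown"] = len(demo) - sum(reporter.values())
    occr = demo.get("occr_country", pd.Series(dtype=object)).fillna("").str.strip().str.upper()
    rep = demo.get("reporter_country", pd.Series(dtype=object)).fillna("").str.strip().str.upper()
    country = occr.where(occr != "", rep).replace("", "unknown")
    top = country.value_counts().head(top_k)
    return GroupDemographics(
        n=len(demo),
        age_median=float(med),
        age_q1=float(q1),
        age_q3=float(q3),
        age_bands=bands,
        sex=sex,
        reporter=reporter,
        countries={str(k): int(v) for k, v in top.items()},
    )


def demographics_table(
    cohort: ScreenedCohort, demo: pd.DataFrame | None = None, top_k: int = 6
) -> dict[str, GroupDemographics]:
    """Per-drug and pooled demographic summaries of the drug-event cases."""
    if demo is None:
        assert cohort.dedup is not None
        demo = cohort.dedup.demo
    groups = {POOLED: cohort.pooled_drug_event_case_ids, **cohort.drug_event_case_ids}
    return {
        g: _group_demographics(demo[demo["primaryid"].isin(ids)], top_k)
        for g, ids in groups.items()
    }


def demographics_to_frame(summary: Mapping[str, GroupDemographics]) -> pd.DataFrame:
    """Long-format CSV layout: one row per (group, characteristic, level)."""
    rows = []
    for g, s in summary.items():
        denom = s.n or 1
        rows.append({"group": g, "characteristic": "cases", "level": "n", "value": s.n, "pct": 100.0})
        for label, v in (("median", s.age_median), ("q1", s.age_q1), ("q3", s.age_q3)):
            rows.append({"group": g, "characteristic": "age_years", "level": label, "value": v, "pct": float("nan")})
        for section, counts in (("age_band", s.age_bands), ("sex", s.sex),
                                ("reporter", s.reporter), ("country", s.countries)):
            for level, v in counts.items():
                rows.append({"group": g, "characteristic": section, "level": level,
                             "value": v, "pct": 100.0 * v / denom})
    return pd.DataFrame(rows)
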