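"""Case screening: deduplication, suspect-drug screening, event extraction.

Spontaneous-report databases carry several versions of the same case
(one ``caseid``, several ``primaryid`` report versions across quarters)
plus genuinely duplicated submissions. The screening procedure applied
here is the standard four-step funnel:

1. **Deduplicate**: keep one report per caseid — the one with the most
   recent FDA receipt date (``fda_dt``); ties broken by the highest
   ``primaryid``. Rows with a missing/partial receipt date sort before
   any dated row.
2. **Primary-suspect screening**: a case belongs to target drug *d* iff
   at least one PS-role drug row canonicalises to *d* and no PS-role row
   canonicalises to a *different* dictionary drug. Cases with two or
   more distinct dictionary drugs in the PS role are excluded entirely,
   so the per-drug case sets are pairwise disjoint.
3. **Event extraction**: a case has the target event iff any REAC row's
   preferred term equals the target term (case-insensitive, trimmed).
4. **Intersection** of the two, per drug.

After deduplication caseid and primaryid are in bijection, so all sets
are expressed in surviving ``primaryid`` terms.

A separate co-medication exclusion (used for the statin sensitivity
analysis) removes any case carrying a row of a second dictionary in
*any* role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .dates import parse_faers_date
from .dictionary import DrugDictionary
from .faers_io import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "DedupResult",
    "ScreenedCohort",
    "deduplicate",
    "screen_primary_suspect",
    "extract_event_cases",
    "exclude_comedicated",
    "build_cohort",
]


@dataclass
class DedupResult:
    demo: pd.DataFrame  # one row per caseid, the surviving report version
    n_input: int
    n_unique: int
    n_dropped_bad_caseid: int

    @property
    def primaryids(self) -> set[int]:
        return set(self.demo["primaryid"].tolist())


def _fda_sort_key(raw: pd.Series) -> pd.Series:
    """Vectorised FaersDate sort key: missing < partial < full."""
    uniques = {u: parse_faers_date(u).sort_key() for u in raw.unique()}
    return raw.map(uniques)


def deduplicate(demo: pd.DataFrame) -> DedupResult:
    """One surviving report version per case.

    Latest ``fda_dt`` wins; ties on ``fda_dt`` go to the highest
    ``primaryid``. Rows whose caseid cannot be parsed as an integer are
    dropped and counted. Idempotent and independent of input row order.
    """
    n_input = len(demo)
    caseid = pd.to_numeric(demo["caseid"], errors="coerce")
    bad = caseid.isna()
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("deduplicate: dropped %d row(s) with unparseable CASEID", n_bad)
    df = demo[~bad].copy()
    df["caseid"] = caseid[~bad].astype("int64")
    df["_fda_key"] = _fda_sort_key(df["fda_dt"].fillna(""))
    df = df.sort_values(["caseid", "_fda_key", "primaryid"], kind="mergesort")
    df = df.groupby("caseid", sort=True).tail(1).drop(columns="_fda_key")
    return DedupResult(
        demo=df.reset_index(drop=True),
        n_input=n_input,
        n_unique=len(df),
        n_dropped_bad_caseid=n_bad,
    )


def screen_primary_suspect(
    drug: pd.DataFrame, ddict: DrugDictionary, keep_ids: set[int]
) -> tuple[dict[str, set[int]], set[int]]:
    """Assign each surviving case to its sole primary-suspect target drug.

    Returns (per-canonical-drug primaryid sets, excluded multi-target
    cases). Only PS-role rows participate; SS/C/I rows are ignored here.
    """
    ps = drug[(drug["role_cod"].str.strip().str.upper() == "PS") & drug["primaryid"].isin(keep_ids)]
    if not len(ps):
        return {d: set() for d in ddict.canonical_names}, set()
    canon = ddict.match_series(ps["drugname"])
    hits = ps.assign(canonical=canon).dropna(subset=["canonical"])
    per_case = hits.groupby("primaryid")["canonical"].agg(["nunique", "first"])
    multi = set(per_case.index[per_case["nunique"] >= 2].tolist())
    sole = per_case[per_case["nunique"] == 1]
    assignments: dict[str, set[int]] = {d: set() for d in ddict.canonical_names}
    for pid, drug_name in sole["first"].items():
        assignments[drug_name].add(int(pid))
    if multi:
        logger.info("excluded %d case(s) with multiple target drugs in PS role", len(multi))
    return assignments, multi


def extract_event_cases(reac: pd.DataFrame, preferred_term: str, keep_ids: set[int]) -> set[int]:
    """Cases whose REAC rows include the target preferred term.

    Matching is case-insensitive after trimming; duplicate PT rows on a
    case count once (set semantics).
    """
    target = preferred_term.strip().casefold()
    pt = reac["pt"].astype(str).str.strip().str.casefold()
    hit = reac[(pt == target) & reac["primaryid"].isin(keep_ids)]
    return set(hit["primaryid"].tolist())


def exclude_comedicated(
    case_ids: set[int], drug: pd.DataFrame, comed_dict: DrugDictionary
) -> tuple[set[int], set[int]]:
    """Remove cases carrying any co-medication dictionary drug in any role.

    Returns (retained, removed); the two partition the input set.
    """
    rows = drug[drug["primaryid"].isin(case_ids)]
    canon = comed_dict.match_series(rows["drugname"])
    removed = set(rows.loc[canon.notna(), "primaryid"].tolist())
    return case_ids - removed, removed


@dataclass
class ScreenedCohort:
    """Outcome of the four-step screen for one event term."""

    target_event: str
    n_total: int  # deduplicated report count, the N of every 2x2 table
    drug_case_ids: dict[str, set[int]]
    event_case_ids: set[int]
    excluded_multi_ps: set[int] = field(default_factory=set)
    dedup: DedupResult | None = field(default=None, repr=False)

    @property
    def drug_event_case_ids(self) -> dict[str, set[int]]:
        return {d: ids & self.event_case_ids for d, ids in self.drug_case_ids.items()}

    @property
    def pooled_drug_case_ids(self) -> set[int]:
        out: set[int] = set()
        for ids in self.drug_case_ids.values():
            out |= ids
        return out

    @property
    def pooled_drug_event_case_ids(self) -> set[int]:
        return self.pooled_drug_case_ids & self.event_case_ids

    def funnel(self) -> dict[str, int]:
        """Case counts at each screening stage (flow-chart style)."""
        return {
            "demo_rows": self.dedup.n_input if self.dedup else -1,
            "unique_cases": self.n_total,
            "target_drug_ps_cases": len(self.pooled_drug_case_ids),
            "multi_target_ps_excluded": len(self.excluded_multi_ps),
            "event_cases": len(self.event_case_ids),
            "drug_event_cases": len(self.pooled_drug_event_case_ids),
        }


def build_cohort(corpus: Corpus, target_dict: DrugDictionary, event_term: str) -> ScreenedCohort:
    """Run the full four-step screen over a combined corpus."""
    dedup = deduplicate(corpus.demo)
    keep = dedup.primaryids
    drug_sets, multi = screen_primary_suspect(corpus.drug, target_dict, keep)
    event_ids = extract_event_cases(corpus.reac, event_term, keep)
    return ScreenedCohort(
        target_event=event_term,
        n_total=dedup.n_unique,
        drug_case_ids=drug_sets,
        event_case_ids=event_ids,
        excluded_multi_ps=multi,
        dedup=dedup,
    )
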