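"""Deduplication and four-step case screening, against hand enumeration
and generator ground truth."""

import pandas as pd
import pytest

from conftest import HAND_EXPECTED

from faerspv.dictionary import load_ssri_dictionary, load_statin_dictionary
from faerspv.screening import (
    build_cohort,
    deduplicate,
    exclude_comedicated,
    extract_event_cases,
    screen_primary_suspect,
)
from faerspv.synth import SynthConfig, corpus_from_tables, simulate


def demo_frame(rows):
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])


class TestDeduplicate:
    def test_latest_fda_dt_wins(self):
        d = deduplicate(demo_frame([(71, "7", "20200101"), (72, "7", "20210101")]))
        assert d.primaryids == {72}

    def test_fda_dt_tie_broken_by_highest_primaryid(self):
        d = deduplicate(demo_frame([(71, "7", "20210101"), (73, "7", "20210101")]))
        assert d.primaryids == {73}

    def test_missing_date_sorts_before_any_dated_row(self):
        d = deduplicate(demo_frame([(75, "7", ""), (71, "7", "20050101")]))
        assert d.primaryids == {71}

    def test_partial_date_sorts_before_full_date_same_month(self):
        d = deduplicate(demo_frame([(75, "7", "202001"), (71, "7", "20200101")]))
        assert d.primaryids == {71}

    def test_unparseable_caseid_dropped_and_counted(self):
        d = deduplicate(demo_frame([(71, "x", "20200101"), (81, "8", "20200101")]))
        assert d.primaryids == {81} and d.n_dropped_bad_caseid == 1

    def test_idempotent_and_order_independent(self):
        rows = [(71, "7", "20200101"), (72, "7", "20210101"), (73, "7", "20210101"),
                (81, "8", ""), (82, "8", "20190101"), (91, "9", "20200505")]
        base = deduplicate(demo_frame(rows))
        assert deduplicate(base.demo).primaryids == base.primaryids
        for perm in (rows[::-1], rows[3:] + rows[:3]):
            assert deduplicate(demo_frame(perm)).primaryids == base.primaryids


class TestScreeningRules:
    def test_concomitant_roles_do_not_affect_assignment(self):
        drug = pd.DataFrame(
            [(1, "1", "PS", "SERTRALINE"), (1, "2", "C", "ATORVASTATIN")],
            columns=["primaryid", "drug_seq", "role_cod", "drugname"],
        )
        sets, multi = screen_primary_suspect(drug, load_ssri_dictionary(), {1})
        assert sets["sertraline"] == {1} and not multi

    def test_multiple_target_ps_case_excluded_entirely(self):
        drug = pd.DataFrame(
            [(1, "1", "PS", "SERTRALINE"), (1, "2", "PS", "FLUOXETINE")],
            columns=["primaryid", "drug_seq", "role_cod", "drugname"],
        )
        sets, multi = screen_primary_suspect(drug, load_ssri_dictionary(), {1})
        assert multi == {1}
        assert all(not s for s in sets.values())

    def test_event_extraction_case_insensitive_set_semantics(self):
        reac = pd.DataFrame(
            [(1, "Rhabdomyolysis"), (1, "Nausea"), (2, "RHABDOMYOLYSIS"), (2, "Rhabdomyolysis"),
             (3, "Myoglobinuria")],
            columns=["primaryid", "pt"],
        )
        assert extract_event_cases(reac, "rhabdomyolysis", {1, 2, 3}) == {1, 2}

    def test_comedication_exclusion_partitions_input(self):
        drug = pd.DataFrame(
            [(1, "1", "PS", "SERTRALINE"), (1, "2", "C", "SIMVASTATIN"), (2, "1", "PS", "ZOLOFT")],
            columns=["primaryid", "drug_seq", "role_cod", "drugname"],
        )
        retained, removed = exclude_comedicated({1, 2}, drug, load_statin_dictionary())
        assert retained == {2} and removed == {1}
        assert retained | removed == {1, 2} and not retained & removed


class TestHandCohort:
    """The 12-case fixture, checked cell by cell against manual enumeration."""

    @pytest.fixture(scope="class")
    def cohort(self, hand_corpus):
        return build_cohort(hand_corpus, load_ssri_dictionary(), "Rhabdomyolysis")

    def test_funnel_counts(self, cohort):
        assert cohort.n_total == HAND_EXPECTED["n_total"]
        assert cohort.dedup.primaryids == HAND_EXPECTED["survivors"]

    def test_drug_sets(self, cohort):
        assert cohort.drug_case_ids == HAND_EXPECTED["drug_case_ids"]
        assert cohort.excluded_multi_ps == HAND_EXPECTED["excluded_multi_ps"]

    def test_event_and_intersection(self, cohort):
        assert cohort.event_case_ids == HAND_EXPECTED["event_case_ids"]
        assert cohort.pooled_drug_event_case_ids == HAND_EXPECTED["pooled_drug_event"]

    def test_per_drug_sets_are_disjoint(self, cohort):
        ids = [i for s in cohort.drug_case_ids.values() for i in s]
        assert len(ids) == len(set(ids))

    def test_statin_exclusion(self, cohort, hand_corpus):
        retained, removed = exclude_comedicated(
            cohort.pooled_drug_case_ids, hand_corpus.drug, load_statin_dictionary()
        )
        assert removed == HAND_EXPECTED["statin_in_pooled_drug"]
        assert retained == cohort.pooled_drug_case_ids - removed


class TestGeneratorRecovery:
    def test_screen_recovers_ground_truth_sets(self):
        cfg = SynthConfig(seed=5, n_cases=20_000)
        tables, truth = simulate(cfg)
        cohort = build_cohort(corpus_from_tables(tables), load_ssri_dictionary(), "Rhabdomyolysis")
        assert cohort.n_total == truth.n_unique
        for d, caseids in truth.drug_cases.items():
            assert cohort.drug_case_ids[d] == truth.as_primaryids(caseids)
        assert cohort.event_case_ids == truth.as_primaryids(truth.event_cases["Rhabdomyolysis"])
        assert cohort.excluded_multi_ps == truth.as_primaryids(truth.multi_ps_cases)

    def test_cohort_invariant_to_quarter_load_order(self):
        cfg = SynthConfig(seed=6, n_cases=5_000)
        tables, _ = simulate(cfg)
        corpus = corpus_from_tables(tables)
        shuffled = corpus_from_tables(
            {t: tables[t].sample(frac=1.0, random_state=0).reset_index(drop=True) for t in tables}
        )
        ddict = load_ssri_dictionary()
        a = build_cohort(corpus, ddict, "Rhabdomyolysis")
        b = build_cohort(shuffled, ddict, "Rhabdomyolysis")
        assert a.drug_case_ids == b.drug_case_ids
        assert a.event_case_ids == b.event_case_ids
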