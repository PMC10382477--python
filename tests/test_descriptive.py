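"""Descriptive summaries: time-to-onset, outcomes, demographics."""

import numpy as np
import pandas as pd
import pytest

from conftest import HAND_EXPECTED

from faerspv.descriptive import (
    POOLED,
    demographics_table,
    normalize_age_years,
    outcome_summary,
    time_to_onset,
)
from faerspv.dictionary import load_ssri_dictionary
from faerspv.faers_io import Corpus
from faerspv.screening import build_cohort


@pytest.fixture(scope="module")
def hand_cohort_bits(hand_corpus):
    ddict = load_ssri_dictionary()
    cohort = build_cohort(hand_corpus, ddict, "Rhabdomyolysis")
    return cohort, hand_corpus, ddict


def _mini_tto_corpus(durations):
    """One sertraline-rhabdomyolysis case per requested duration (days)."""
    start = pd.Timestamp("2020-01-01")
    demo, drug, reac, ther = [], [], [], []
    for i, dur in enumerate(durations, 1):
        pid = i * 100 + 1
        demo.append((pid, str(i), "20210101", (start + pd.Timedelta(days=dur)).strftime("%Y%m%d")))
        drug.append((pid, "1", "PS", "SERTRALINE"))
        reac.append((pid, "Rhabdomyolysis"))
        ther.append((pid, "1", start.strftime("%Y%m%d"), ""))
    return Corpus(
        demo=pd.DataFrame(demo, columns=["primaryid", "caseid", "fda_dt", "event_dt"]),
        drug=pd.DataFrame(drug, columns=["primaryid", "drug_seq", "role_cod", "drugname"]),
        reac=pd.DataFrame(reac, columns=["primaryid", "pt"]),
        ther=pd.DataFrame(ther, columns=["primaryid", "dsg_drug_seq", "start_dt", "end_dt"]),
        outc=pd.DataFrame(columns=["primaryid", "outc_cod"]),
    )


class TestTimeToOnset:
    def test_median_and_within_year_on_fixture_durations(self):
        corpus = _mini_tto_corpus([0, 10, 21, 100, 400])
        ddict = load_ssri_dictionary()
        cohort = build_cohort(corpus, ddict, "Rhabdomyolysis")
        s = time_to_onset(cohort, corpus, ddict)
        assert s.overall.n_evaluable == 5
        assert s.overall.median == 21
        assert s.overall.within_one_year_fraction == pytest.approx(0.8)
        assert s.overall.q1 <= s.overall.median <= s.overall.q3

    def test_same_day_onset_included(self):
        corpus = _mini_tto_corpus([0])
        ddict = load_ssri_dictionary()
        cohort = build_cohort(corpus, ddict, "Rhabdomyolysis")
        s = time_to_onset(cohort, corpus, ddict)
        assert s.overall.n_evaluable == 1 and s.overall.median == 0

    def test_exclusion_reasons_partition_on_hand_fixture(self, hand_cohort_bits):
        cohort, corpus, ddict = hand_cohort_bits
        s = time_to_onset(cohort, corpus, ddict)
        assert s.exclusions == HAND_EXPECTED["tto_exclusions"]
        all_durs = sorted(np.concatenate(list(s.durations_by_drug.values())).tolist())
        assert all_durs == HAND_EXPECTED["tto_durations"]
        n_cohort = len(cohort.pooled_drug_event_case_ids)
        assert s.overall.n_evaluable + sum(s.exclusions.values()) == n_cohort

    def test_empty_evaluable_set_flagged(self, hand_corpus):
        ddict = load_ssri_dictionary()
        cohort = build_cohort(hand_corpus, ddict, "Nausea")  # no THER-linkable event cases
        s = time_to_onset(cohort, hand_corpus, ddict)
        assert s.overall.n_evaluable == 0 and np.isnan(s.overall.median)


class TestOutcomes:
    def test_multi_code_case_counts_in_each_code(self, hand_cohort_bits):
        cohort, corpus, _ = hand_cohort_bits
        s = outcome_summary(cohort, corpus.outc)
        assert {c: s.counts[POOLED][c] for c in s.counts[POOLED]} == HAND_EXPECTED["outcome_counts"]
        n = len(cohort.pooled_drug_event_case_ids)
        assert s.proportions[POOLED]["DE"] == pytest.approx(1 / n)

    def test_ca_code_folds_into_ot(self, hand_cohort_bits):
        cohort, corpus, _ = hand_cohort_bits
        s = outcome_summary(cohort, corpus.outc)
        assert s.counts["sertraline"]["OT"] == 1  # the CA row of case 11

    def test_empty_cohort_all_zero(self, hand_cohort_bits):
        cohort, corpus, ddict = hand_cohort_bits
        empty = build_cohort(corpus, ddict, "No such term")
        s = outcome_summary(empty, corpus.outc)
        assert all(v == 0 for v in s.counts[POOLED].values())


class TestDemographics:
    def test_hand_fixture_bands_sex_reporter(self, hand_cohort_bits):
        cohort, _, _ = hand_cohort_bits
        d = demographics_table(cohort)[POOLED]
        assert d.age_bands == HAND_EXPECTED["age_bands"]
        assert d.sex == HAND_EXPECTED["sex"]
        assert d.reporter == HAND_EXPECTED["reporter"]
        assert sum(d.age_bands.values()) == d.n
        assert sum(d.sex.values()) == d.n

    def test_age_65_in_middle_band_and_unit_conversion(self):
        years = normalize_age_years(pd.Series(["65", "793", "8", "200", ""]),
                                    pd.Series(["YR", "MON", "DEC", "YR", "YR"]))
        assert years[0] == 65.0
        assert years[1] == pytest.approx(793 / 12)
        assert years[2] == 80.0
        assert np.isnan(years[3])  # outside [0, 130]
        assert np.isnan(years[4])

    def test_country_fallback_to_reporter_country(self, hand_cohort_bits):
        cohort, _, _ = hand_cohort_bits
        d = demographics_table(cohort)[POOLED]
        assert d.countries.get("DE") == 1  # case 12: blank OCCR_COUNTRY
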