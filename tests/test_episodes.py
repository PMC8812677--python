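"""Episode classification: washout, follow-up attribution, assembly."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from conftest import make_contacts, random_registry, reference_labels
from rtiepi.episodes import (
    ContractViolation,
    StudyConfig,
    build_episodes,
    classify_contacts,
    count_hospitalized_patients,
    label_contacts,
)


@pytest.fixture(scope="module")
def config():
    return StudyConfig()


def labels_of(rows, config, codeset, base=dt.date(2019, 1, 1)):
    df = make_contacts(rows, base_date=base)
    return list(classify_contacts(df, config, codeset)["label"])


class TestClassify:
    def test_first_rti_contact_with_no_history_is_index(self, config, codeset):
        assert labels_of([{"day": 0, "diag1": "J06"}], config, codeset) == ["index"]

    def test_any_diagnosis_contact_within_30_days_is_followup(self, config, codeset):
        rows = [{"day": 0, "diag1": "J06"}, {"day": 10, "diag1": "Z000"}]
        assert labels_of(rows, config, codeset) == ["index", "follow_up"]

    def test_washout_clock_resets_on_every_rti_contact(self, config, codeset):
        # day 100 is 31-181 days after day 0, so limbo; it resets the clock,
        # leaving day 250 only 150 diagnosis-free days -> limbo again
        rows = [
            {"day": 0, "diag1": "J06"},
            {"day": 100, "diag1": "J06"},
            {"day": 250, "diag1": "J06"},
        ]
        assert labels_of(rows, config, codeset) == ["index", "limbo", "limbo"]

    def test_rti_contact_in_window_is_followup_not_new_index(self, config, codeset):
        rows = [{"day": 0, "diag1": "J06"}, {"day": 20, "diag1": "J20"}]
        assert labels_of(rows, config, codeset) == ["index", "follow_up"]

    def test_rti_followup_still_resets_washout(self, config, codeset):
        # day 40 is 20 days after the RTI follow-up on day 20 -> not index
        rows = [
            {"day": 0, "diag1": "J06"},
            {"day": 20, "diag1": "J20"},
            {"day": 40, "diag1": "J06"},
        ]
        assert labels_of(rows, config, codeset) == ["index", "follow_up", "limbo"]

    def test_gap_of_exactly_washout_days_still_blocks(self, config, codeset):
        rows = [{"day": 0, "diag1": "J06"}, {"day": 181, "diag1": "J06"}]
        assert labels_of(rows, config, codeset) == ["index", "limbo"]
        rows = [{"day": 0, "diag1": "J06"}, {"day": 182, "diag1": "J06"}]
        assert labels_of(rows, config, codeset) == ["index", "index"]

    def test_same_day_contact_is_not_a_followup(self, config, codeset):
        rows = [{"day": 0, "diag1": "J06"}, {"day": 0, "diag1": "Z000"}]
        assert labels_of(rows, config, codeset) == ["index", "other"]

    def test_two_same_day_rti_contacts_yield_one_index(self, config, codeset):
        rows = [{"day": 0, "diag1": "J06"}, {"day": 0, "diag1": "J20"}]
        assert labels_of(rows, config, codeset) == ["index", "limbo"]

    def test_inpatient_rti_contact_never_indexes_but_resets_clock(
        self, config, codeset
    ):
        rows = [
            {"day": 0, "diag1": "J18", "setting": "inpatient"},
            {"day": 50, "diag1": "J06"},
        ]
        assert labels_of(rows, config, codeset) == ["other", "limbo"]

    def test_non_physician_contacts_are_ignored_entirely(self, config, codeset):
        # a nurse RTI contact neither indexes nor resets the washout
        rows = [
            {"day": 0, "diag1": "J06", "profession": "other"},
            {"day": 50, "diag1": "J06"},
        ]
        assert labels_of(rows, config, codeset) == ["other", "index"]

    def test_inpatient_contact_in_window_is_not_followup(self, config, codeset):
        rows = [
            {"day": 0, "diag1": "J06"},
            {"day": 5, "diag1": "J18", "setting": "inpatient"},
        ]
        assert labels_of(rows, config, codeset) == ["index", "other"]

    def test_unsorted_input_raises(self, config, codeset):
        df = make_contacts([{"day": 10, "diag1": "J06"}, {"day": 0, "diag1": "J06"}])
        with pytest.raises(ContractViolation):
            classify_contacts(df, config, codeset)

    def test_multi_person_input_raises(self, config, codeset):
        df = make_contacts(
            [{"day": 0, "diag1": "J06"}, {"day": 1, "person_id": "P2", "diag1": "J06"}]
        )
        with pytest.raises(ContractViolation):
            classify_contacts(df, config, codeset)


class TestReferenceEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_random_registries(self, seed, config, codeset):
        rng = np.random.default_rng(seed)
        df = random_registry(rng, n_persons=5, max_contacts=40)
        labeled = label_contacts(df, config, codeset)
        ref_labels, ref_parents = reference_labels(labeled, codeset=codeset)
        assert list(labeled["label"]) == ref_labels
        assert list(labeled["parent_index_id"]) == ref_parents


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_longer_followup_window_never_loses_followups(self, seed, codeset):
        rng = np.random.default_rng(100 + seed)
        df = random_registry(rng)
        narrow = label_contacts(df, StudyConfig(followup_days=30), codeset)
        wide = label_contacts(df, StudyConfig(followup_days=45), codeset)
        assert (wide["label"] == "follow_up").sum() >= (
            narrow["label"] == "follow_up"
        ).sum()

    @pytest.mark.parametrize("seed", range(5))
    def test_longer_washout_never_gains_indexes(self, seed, codeset):
        rng = np.random.default_rng(200 + seed)
        df = random_registry(rng)
        short = label_contacts(df, StudyConfig(washout_days=181), codeset)
        long = label_contacts(df, StudyConfig(washout_days=240), codeset)
        assert (long["label"] == "index").sum() <= (short["label"] == "index").sum()

    @pytest.mark.parametrize("seed", range(8))
    def test_no_two_indexes_within_washout(self, seed, config, codeset):
        rng = np.random.default_rng(300 + seed)
        labeled = label_contacts(random_registry(rng), config, codeset)
        idx = labeled[labeled["label"] == "index"]
        for _, sub in idx.groupby("person_id"):
            gaps = sub["date"].sort_values().diff().dt.days.dropna()
            assert (gaps > config.washout_days).all()


class TestBuildEpisodes:
    def test_followup_after_period_end_stays_attached(self, config, codeset):
        df = make_contacts(
            [
                {"day": 0, "diag1": "J06"},
                {"day": 15, "diag1": ""},
            ],
            base_date=dt.date(2020, 6, 25),
        )
        eps = build_episodes(label_contacts(df, config, codeset), config)
        assert len(eps) == 1
        assert eps.iloc[0]["period"] == "2020H1"
        assert eps.iloc[0]["fu_total"] == 1

    def test_index_outside_all_periods_emits_no_episode(self, config, codeset):
        df = make_contacts([{"day": 0, "diag1": "J06"}], base_date=dt.date(2017, 12, 15))
        eps = build_episodes(label_contacts(df, config, codeset), config)
        assert len(eps) == 0

    def test_out_of_period_index_still_shapes_washout(self, config, codeset):
        # December index blocks a January one; only limbo remains in-period
        df = make_contacts(
            [{"day": 0, "diag1": "J06"}, {"day": 40, "diag1": "J06"}],
            base_date=dt.date(2017, 12, 15),
        )
        labeled = label_contacts(df, config, codeset)
        assert list(labeled["label"]) == ["index", "limbo"]
        assert len(build_episodes(labeled, config)) == 0

    def test_zero_indexes_give_empty_episode_list(self, config, codeset):
        df = make_contacts([{"day": 0, "diag1": "Z000"}])
        eps = build_episodes(label_contacts(df, config, codeset), config)
        assert len(eps) == 0

    def test_followup_typology_counts(self, config, codeset):
        df = make_contacts(
            [
                {"day": 0, "diag1": "J06"},
                {"day": 3, "mode": "remote"},
                {"day": 5, "mode": "remote", "provider_class": "telemedicine",
                 "source": "telemedicine_register"},
                {"day": 9},
            ],
            base_date=dt.date(2019, 2, 1),
        )
        eps = build_episodes(label_contacts(df, config, codeset), config)
        assert eps.iloc[0][["fu_in_person", "fu_remote_traditional",
                            "fu_telemedicine", "fu_total"]].tolist() == [1, 1, 1, 3]


class TestHospitalized:
    period = (dt.date(2019, 1, 1), dt.date(2019, 6, 30))

    def test_repeat_stays_count_once(self, codeset):
        rows = [
            {"day": d, "setting": "inpatient", "diag1": "J18"} for d in (5, 20, 40)
        ]
        df = make_contacts(rows)
        assert count_hospitalized_patients(df, codeset, self.period) == 1

    def test_no_inpatient_rows(self, codeset):
        df = make_contacts([{"day": 0, "diag1": "J06"}])
        assert count_hospitalized_patients(df, codeset, self.period) == 0

    def test_toy_table_five_patients_seven_stays(self, codeset):
        rows = [
            {"person_id": "A", "day": 1, "setting": "inpatient", "diag1": "J18"},
            {"person_id": "A", "day": 8, "setting": "inpatient", "diag1": "J18"},
            {"person_id": "B", "day": 3, "setting": "inpatient", "diag1": "U071"},
            {"person_id": "C", "day": 9, "setting": "inpatient", "diag1": "Z000"},
            {"person_id": "C", "day": 12, "setting": "inpatient", "diag1": "I109"},
            {"person_id": "D", "day": 400, "setting": "inpatient", "diag1": "J18"},
            {"person_id": "E", "day": 15, "setting": "inpatient", "diag1": "B342"},
        ]
        df = make_contacts(rows)
        # A (RTI, in period), B (RTI), E (RTI); C non-RTI; D out of period
        assert count_hospitalized_patients(df, codeset, self.period) == 3


def test_config_rejects_overlapping_periods():
    with pytest.raises(ValueError):
        StudyConfig(
            index_periods=(
                (dt.date(2018, 1, 1), dt.date(2018, 6, 30)),
                (dt.date(2018, 6, 1), dt.date(2018, 12, 31)),
            )
        )


def test_config_requires_washout_beyond_followup():
    with pytest.raises(ValueError):
        StudyConfig(washout_days=20, followup_days=30)
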