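from datetime import timedelta

import pytest

from newsfio2 import (CohortConfig, completeness_filter, filter_eligible,
                      gcs_to_avpu, rate_percent, summarize_cohort, tag_events)

from conftest import BASE_TIME


class TestGcsToAvpu:
    @pytest.mark.parametrize("gcs, avpu", [
        (15, "A"),   # maximal score is alert under any sane map
        (14, "V"), (12, "V"), (9, "V"),
        (8, "P"), (4, "P"),
        (3, "U"),    # minimal score is unresponsive
    ])
    def test_default_map(self, gcs, avpu):
        assert gcs_to_avpu(gcs) == avpu

    @pytest.mark.parametrize("gcs", [2, 16, 0])
    def test_out_of_range_rejected(self, gcs):
        with pytest.raises(ValueError):
            gcs_to_avpu(gcs)

    def test_map_must_cover_range(self):
        with pytest.raises(ValueError, match="3-15"):
            CohortConfig(gcs_to_avpu_map=((15, 15, "A"), (3, 13, "U")))


class TestCompleteness:
    def test_mixed_fixture_counts(self, make_obs):
        rows = ([make_obs() for _ in range(7)]
                + [make_obs(avpu=None, gcs=None),
                   make_obs(device="nasal_cannula"),  # flow missing
                   make_obs(device="fixed_performance_mask")])  # prescription missing
        complete, n_incomplete = completeness_filter(rows)
        assert len(complete) == 7 and n_incomplete == 3


class TestFilterEligible:
    def test_short_stay_discharged_event_free_is_excluded(self, make_admission, make_obs):
        adm = make_admission(discharge_time=BASE_TIME + timedelta(hours=20))
        res = filter_eligible([adm], [make_obs()])
        assert res.admissions == [] and res.exclusions["short_stay"] == 1

    def test_death_within_24h_is_retained(self, make_admission, make_obs):
        adm = make_admission(discharge_time=BASE_TIME + timedelta(hours=20),
                             outcome="death",
                             event_time=BASE_TIME + timedelta(hours=18))
        res = filter_eligible([adm], [make_obs()])
        assert len(res.admissions) == 1

    def test_age_boundary_below_sixteen_excluded(self, make_admission, make_obs):
        young = make_admission(age_years=15)
        adult = make_admission(admission_id="A2", age_years=16)
        obs = [make_obs(), make_obs(admission_id="A2")]
        res = filter_eligible([young, adult], obs)
        assert [a.admission_id for a in res.admissions] == ["A2"]
        assert res.exclusions["under_age"] == 1

    def test_post_icu_ward_period_excluded(self, make_admission, make_obs):
        adm = make_admission(planned_icu_before_ward=True)
        res = filter_eligible([adm], [make_obs()])
        assert res.exclusions["post_icu_ward"] == 1

    def test_no_complete_observation_excluded(self, make_admission, make_obs):
        adm = make_admission()
        res = filter_eligible([adm], [make_obs(avpu=None, gcs=None)])
        assert res.exclusions["no_complete_observations"] == 1
        assert res.n_incomplete_observations == 1

    def test_event_without_recent_observation_retained_and_tallied(
            self, make_admission, make_obs):
        adm = make_admission(outcome="death",
                             event_time=BASE_TIME + timedelta(days=4))
        obs = [make_obs()]  # 96 h before the event
        res = filter_eligible([adm], obs)
        assert len(res.admissions) == 1
        assert res.notes["event_without_recent_observation"] == 1

    def test_orphan_observations_reported(self, make_admission, make_obs):
        res = filter_eligible([make_admission()],
                              [make_obs(), make_obs(admission_id="ghost")])
        assert any("ghost" in d for d in res.diagnostics)

    def test_exclusion_tallies_conserve_admissions(self, make_admission, make_obs):
        admissions = [
            make_admission(admission_id="A1"),
            make_admission(admission_id="A2", age_years=10),
            make_admission(admission_id="A3",
                           discharge_time=BASE_TIME + timedelta(hours=5)),
            make_admission(admission_id="A4", planned_icu_before_ward=True),
            make_admission(admission_id="A5"),
        ]
        obs = [make_obs(admission_id="A1"), make_obs(admission_id="A5", avpu=None,
                                                     gcs=None)]
        res = filter_eligible(admissions, obs)
        assert len(res.admissions) + sum(res.exclusions.values()) == len(admissions)


class TestTagEvents:
    def _event_admission(self, make_admission, hours=100):
        return make_admission(outcome="unplanned_icu",
                              event_time=BASE_TIME + timedelta(hours=hours))

    def test_observation_outside_window_is_negative(self, make_admission, make_obs):
        adm = self._event_admission(make_admission, hours=25)
        labeled, _ = tag_events([make_obs()], [adm])
        assert labeled[0].label is False and labeled[0].time_to_event_h is None

    def test_boundary_at_exactly_window_is_positive_when_inclusive(
            self, make_admission, make_obs):
        adm = self._event_admission(make_admission, hours=24)
        labeled, _ = tag_events([make_obs()], [adm])
        assert labeled[0].label is True
        assert labeled[0].time_to_event_h == pytest.approx(24.0)
        labeled_excl, _ = tag_events([make_obs()], [adm],
                                     CohortConfig(window_inclusive=False))
        assert labeled_excl[0].label is False

    def test_post_event_observations_dropped(self, make_admission, make_obs):
        adm = self._event_admission(make_admission, hours=10)
        obs = [make_obs(), make_obs(timestamp=BASE_TIME + timedelta(hours=12))]
        labeled, _ = tag_events(obs, [adm])
        assert len(labeled) == 1 and labeled[0].label is True

    def test_calculated_fio2_attached(self, make_admission, make_obs):
        labeled, _ = tag_events(
            [make_obs(device="nasal_cannula", o2_flow_lpm=2, rr=18)],
            [make_admission()])
        assert labeled[0].calculated_fio2 == pytest.approx(0.405061728395, abs=1e-9)

    def test_event_before_first_observation_flagged(self, make_admission, make_obs):
        adm = self._event_admission(make_admission, hours=30)
        obs = [make_obs(timestamp=BASE_TIME + timedelta(hours=40))]
        labeled, diags = tag_events(obs, [adm])
        assert labeled == []
        assert any("precedes" in d for d in diags)

    def test_labels_partition_and_positives_lie_in_window(
            self, make_admission, make_obs):
        adm = self._event_admission(make_admission, hours=48)
        obs = [make_obs(timestamp=BASE_TIME + timedelta(hours=h))
               for h in (0, 10, 23, 30, 47.5, 50)]
        labeled, _ = tag_events(obs, [adm])
        assert len(labeled) == 5  # the post-event one is dropped
        for lo in labeled:
            if lo.label:
                assert 0 < lo.time_to_event_h <= 24

    def test_relabeling_is_idempotent(self, make_admission, make_obs):
        adm = self._event_admission(make_admission)
        obs = [make_obs(timestamp=BASE_TIME + timedelta(hours=h))
               for h in range(0, 99, 7)]
        first, _ = tag_events(obs, [adm])
        second, _ = tag_events(obs, [adm])
        assert first == second


class TestCohortSummary:
    def test_rate_percent_rounding(self):
        assert rate_percent(1669, 42764) == 3.9
        assert rate_percent(1, 3, decimals=2) == 33.33
        with pytest.raises(ValueError):
            rate_percent(1, 0)

    def test_summary_counts_and_shares(self, make_admission):
        admissions = [make_admission(admission_id=f"A{i}") for i in range(8)]
        admissions += [
            make_admission(admission_id="E1", outcome="death",
                           event_time=BASE_TIME + timedelta(days=1)),
            make_admission(admission_id="E2", outcome="unplanned_icu",
                           event_time=BASE_TIME + timedelta(days=2)),
        ]
        summary = summarize_cohort(admissions, oxygen_admission_ids={"A0", "A1", "E1"})
        assert summary["n_admissions"] == 10
        assert summary["event_admission_percent"] == 20.0
        assert summary["oxygen_admission_percent"] == 30.0
        assert summary["oxygen_event_percent"] == pytest.approx(33.3)
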