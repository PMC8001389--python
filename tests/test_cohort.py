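"""Domain types, CSV round trips and per-egg fate derivation."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ovitherm import cohort
from ovitherm.cohort import (
    ClusterObservation,
    Condition,
    EggFate,
    FieldRecord,
    TemperatureSeries,
    derive_fates,
)
from ovitherm.errors import SchemaError, ValidationError


def _obs(cid, age, alive, yellow=None, brown=0, blackhead=0, hatched=0, dead=0,
         temp=20.0, rh="medium"):
    if yellow is None:
        yellow = alive
    return ClusterObservation(
        cluster_id=cid,
        condition=Condition(temp, rh),
        age_days=age,
        n_alive=alive,
        n_yellow=yellow,
        n_brown=brown,
        n_blackhead=blackhead,
        n_hatched_cum=hatched,
        n_dead_cum=dead,
    )


class TestTypes:
    def test_condition_rejects_unknown_regime(self):
        with pytest.raises(ValidationError):
            Condition(20.0, "arid")

    def test_colour_counts_must_partition_alive(self):
        with pytest.raises(ValidationError, match="colour counts"):
            _obs("c1", 0, alive=10, yellow=5, brown=2, blackhead=2)

    def test_stage_durations_must_sum_to_event_age(self):
        with pytest.raises(ValidationError):
            EggFate("e1", "c1", Condition(20, "high"), "hatched", 10, (3, 4, 2))

    def test_stage_durations_only_for_hatched(self):
        with pytest.raises(ValidationError):
            EggFate("e1", "c1", Condition(20, "high"), "died", 9, (3, 4, 2))

    def test_temperature_series_requires_consecutive_days(self):
        with pytest.raises(ValidationError, match="consecutive"):
            TemperatureSeries(
                "A",
                (dt.date(2020, 1, 1), dt.date(2020, 1, 3)),
                (5.0, 6.0),
            )

    def test_field_record_count_positive(self):
        with pytest.raises(ValidationError):
            FieldRecord(dt.date(2020, 1, 1), "A", "larva", 0)


class TestCsvRoundTrips:
    def test_cluster_observations_round_trip(self, tmp_path, small_experiment):
        observations, _, _ = small_experiment
        path = tmp_path / "cohort.csv"
        cohort.write_cluster_observations(observations, path)
        loaded = cohort.load_cluster_observations(path)
        assert loaded == sorted(observations, key=lambda o: (o.cluster_id, o.age_days))

    def test_two_row_file_echoes_input(self, tmp_path):
        path = tmp_path / "cohort.csv"
        rows = [
            _obs("c1", 0, alive=12),
            _obs("c1", 5, alive=10, dead=2),
        ]
        cohort.write_cluster_observations(rows, path)
        loaded = cohort.load_cluster_observations(path)
        assert len(loaded) == 2
        assert loaded[0].initial_count == 12

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("cluster_id,age_days\nc1,0\n")
        with pytest.raises(SchemaError, match="n_alive"):
            cohort.load_cluster_observations(path)

    def test_temperature_series_round_trip(self, tmp_path):
        series = TemperatureSeries(
            "Urgell",
            tuple(dt.date(2020, 1, 1) + dt.timedelta(days=i) for i in range(5)),
            (4.0, 5.5, 6.25, 3.0, -1.5),
        )
        path = tmp_path / "temps.csv"
        cohort.write_temperature_series([series], path)
        assert cohort.load_temperature_series(path) == [series]

    def test_field_records_round_trip(self, tmp_path):
        records = [
            FieldRecord(dt.date(2019, 12, 20), "A", "larva", 3),
            FieldRecord(dt.date(2019, 11, 1), "A", "egg_yellow", 12),
        ]
        path = tmp_path / "field.csv"
        cohort.write_field_records(records, path)
        assert cohort.load_field_records(path) == sorted(
            records, key=lambda r: (r.area, r.date, r.record_kind)
        )

    def test_fates_round_trip(self, tmp_path, small_experiment):
        _, fates, _ = small_experiment
        path = tmp_path / "fates.csv"
        cohort.write_fates(fates, path)
        assert cohort.load_fates(path) == sorted(
            fates, key=lambda f: (f.cluster_id, f.egg_id)
        )


class TestDeriveFates:
    def test_all_hatched_single_transition(self):
        rows = [_obs("c1", a, alive=10) for a in range(14)]
        rows.append(_obs("c1", 14, alive=0, yellow=0, hatched=10))
        fates = derive_fates(rows)
        assert len(fates) == 10
        assert all(f.outcome == "hatched" and f.event_age_days == 14 for f in fates)

    def test_conservation_with_mixed_outcomes(self):
        rows = [
            _obs("c1", 0, alive=12),
            _obs("c1", 1, alive=11, dead=1),
            _obs("c1", 2, alive=9, dead=3),
            _obs("c1", 3, alive=0, yellow=0, dead=3, hatched=9),
        ]
        fates = derive_fates(rows)
        assert len(fates) == 12
        assert sum(f.outcome == "hatched" for f in fates) == 9
        assert sum(f.outcome == "died" for f in fates) == 3

    def test_death_ages_traced_from_daily_table(self):
        rows = [_obs("c1", a, alive=10 - (2 if a >= 3 else 0) - (1 if a >= 6 else 0),
                     dead=(2 if a >= 3 else 0) + (1 if a >= 6 else 0))
                for a in range(8)]
        fates = derive_fates(rows)
        died = sorted(f.event_age_days for f in fates if f.outcome == "died")
        assert died == [3, 3, 6]

    def test_alive_at_horizon_censored(self):
        rows = [_obs("c1", a, alive=6) for a in range(5)]
        fates = derive_fates(rows, horizon_days=5)
        assert all(f.outcome == "censored" and f.event_age_days == 5 for f in fates)

    def test_gap_in_daily_ages_named(self):
        rows = [_obs("c1", 0, alive=5), _obs("c1", 2, alive=5)]
        with pytest.raises(ValidationError, match="age 1"):
            derive_fates(rows)

    def test_decreasing_cumulative_rejected(self):
        rows = [
            _obs("c1", 0, alive=8, dead=2),
            _obs("c1", 1, alive=9, dead=1),
        ]
        with pytest.raises(ValidationError):
            derive_fates(rows)

    def test_row_order_within_cluster_is_irrelevant(self):
        rows = [
            _obs("c1", 0, alive=12),
            _obs("c1", 1, alive=11, dead=1),
            _obs("c1", 2, alive=0, yellow=0, dead=1, hatched=11),
        ]
        assert derive_fates(rows) == derive_fates(list(reversed(rows)))

    def test_lockstep_colour_history_yields_stage_durations(self):
        # all eggs yellow for 3 d, brown for 7 d, blackhead for 4 d, hatch at 14
        rows = []
        for a in range(15):
            if a < 3:
                colours = dict(yellow=5, brown=0, blackhead=0)
            elif a < 10:
                colours = dict(yellow=0, brown=5, blackhead=0)
            elif a < 14:
                colours = dict(yellow=0, brown=0, blackhead=5)
            else:
                colours = dict(yellow=0, brown=0, blackhead=0)
            alive = 5 if a < 14 else 0
            rows.append(
                _obs("c1", a, alive=alive, hatched=0 if a < 14 else 5, **colours)
            )
        fates = derive_fates(rows)
        assert all(f.stage_durations == (3, 7, 4) for f in fates)

    def test_generated_tables_reconcile_with_ground_truth(self, small_experiment):
        observations, truth, _ = small_experiment
        derived = derive_fates(observations)
        assert len(derived) == len(truth)
        for outcome in ("hatched", "died"):
            truth_ages = sorted(
                (f.cluster_id, f.event_age_days)
                for f in truth
                if f.outcome == outcome
            )
            derived_ages = sorted(
                (f.cluster_id, f.event_age_days)
                for f in derived
                if f.outcome == outcome
            )
            assert truth_ages == derived_ages

    @given(
        deaths=st.lists(st.integers(min_value=1, max_value=6), min_size=0, max_size=5),
        hatch_age=st.integers(min_value=7, max_value=9),
        n_hatch=st.integers(min_value=0, max_value=4),
    )
    def test_fate_counts_reconcile_with_final_row(self, deaths, hatch_age, n_hatch):
        """|fates| equals the initial count and tallies match the last row."""
        n0 = len(deaths) + n_hatch + 1  # one egg stays alive (censored)
        max_age = hatch_age + 1
        rows = []
        for a in range(max_age + 1):
            n_dead = sum(1 for d in deaths if d <= a)
            n_hat = n_hatch if a >= hatch_age else 0
            alive = n0 - n_dead - n_hat
            rows.append(_obs("c1", a, alive=alive, dead=n_dead, hatched=n_hat))
        fates = derive_fates(rows)
        assert len(fates) == n0
        assert sum(f.outcome == "died" for f in fates) == len(deaths)
        assert sum(f.outcome == "hatched" for f in fates) == n_hatch
        assert sum(f.outcome == "censored" for f in fates) == 1
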