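"""Detection-stream ingestion: parsing, visit collapsing, aggregation, masking."""
import datetime as dt
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forayfit.ingest import (
    BirdDayTable,
    StudyWindow,
    aggregate_daily,
    apply_exclusions,
    apply_mortality_rule,
    collapse_reads,
    read_detections,
)

from .conftest import make_window


def detections_csv(rows):
    body = "\n".join(f"{t},{f},{b}" for t, f, b in rows)
    return io.StringIO("timestamp,feeder_id,tag_id\n" + body + "\n")


class TestReadDetections:
    def test_clean_input_sorted_by_bird_then_time(self):
        rows = [
            ("2023-01-10T09:00:00", "F02", "B2"),
            ("2023-01-09T09:00:00", "F04", "B1"),
            ("2023-01-09T08:00:00", "F02", "B2"),
        ]
        df = read_detections(detections_csv(rows))
        assert len(df) == 3
        # naive full-sort oracle
        expect = sorted([(b, t) for t, f, b in rows])
        got = list(zip(df["tag_id"], df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")))
        assert got == expect

    def test_drop_policy_removes_undeclared_feeder(self):
        rows = [
            ("2023-01-09T09:00:00", "F02", "B1"),
            ("2023-01-09T09:01:00", "F14", "B1"),
        ]
        df = read_detections(detections_csv(rows), feeder_set={"F02"}, unknown_feeder="drop")
        assert set(df["feeder_id"]) == {"F02"}
        with pytest.raises(ValueError, match="undeclared"):
            read_detections(detections_csv(rows), feeder_set={"F02"}, unknown_feeder="error")

    def test_malformed_timestamp_names_line(self):
        rows = [("2023-01-09T09:00:00", "F02", "B1"), ("notadate", "F02", "B1")]
        with pytest.raises(ValueError, match=r"line.*3"):
            read_detections(detections_csv(rows))

    def test_empty_file_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            read_detections(io.StringIO("timestamp,feeder_id,tag_id\n"))


class TestCollapseReads:
    @staticmethod
    def reads(times, bird="B1", feeder="F02"):
        base = dt.datetime(2023, 1, 9, 9, 0, 0)
        return pd.DataFrame(
            {
                "timestamp": [base + dt.timedelta(seconds=float(s)) for s in times],
                "feeder_id": feeder,
                "tag_id": bird,
            }
        )

    def test_single_run_collapses(self):
        out = collapse_reads(self.reads([0, 1, 2]), gap_seconds=2)
        assert len(out) == 1
        assert out["n_raw_reads"].iloc[0] == 3

    def test_gap_zero_is_identity(self):
        out = collapse_reads(self.reads([0, 1, 2]), gap_seconds=0)
        assert len(out) == 3
        assert (out["n_raw_reads"] == 1).all()

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            collapse_reads(self.reads([0]), gap_seconds=-1)

    @settings(max_examples=25, deadline=None)
    @given(
        times=st.lists(st.integers(min_value=0, max_value=400), min_size=1, max_size=50),
        gap=st.integers(min_value=1, max_value=10),
    )
    def test_event_count_matches_bruteforce_gap_count(self, times, gap):
        """Events = (# sorted inter-read gaps > gap) + 1, per bird-feeder run."""
        out = collapse_reads(self.reads(times), gap_seconds=gap)
        ts = np.sort(np.asarray(times))
        expected = 1 + int(np.sum(np.diff(ts) > gap))
        assert len(out) == expected
        assert out["n_raw_reads"].sum() == len(times)

    def test_runs_do_not_cross_birds_or_feeders(self):
        df = pd.concat(
            [
                self.reads([0, 1], bird="B1", feeder="F02"),
                self.reads([0, 1], bird="B2", feeder="F02"),
                self.reads([2, 3], bird="B1", feeder="F04"),
            ]
        )
        out = collapse_reads(df, gap_seconds=10)
        assert len(out) == 3


class TestAggregateDaily:
    def meta(self, *tags):
        return pd.DataFrame({"tag_id": tags, "sex": "F", "age_bin": 0})

    def visits(self, rows):
        return pd.DataFrame(
            {
                "timestamp": [pd.Timestamp(t) for t, f, b in rows],
                "feeder_id": [f for t, f, b in rows],
                "tag_id": [b for t, f, b in rows],
            }
        )

    def test_zero_filled_days_and_counts(self):
        w = make_window(days=2)
        v = self.visits([("2023-01-09T09:00:00", "F02", "B1")] * 4)
        t = aggregate_daily(v, w, self.meta("B1"))
        assert len(t) == 2
        d1, d2 = t.counts.index.get_level_values("date")
        assert t.unique_feeder_count.loc[("B1", d1)] == 1
        assert t.total_visits.loc[("B1", d1)] == 4
        assert t.unique_feeder_count.loc[("B1", d2)] == 0
        assert t.total_visits.loc[("B1", d2)] == 0

    def test_two_feeders_one_day(self):
        w = make_window(days=1)
        v = self.visits(
            [("2023-01-09T09:00:00", "F02", "B1")] * 3 + [("2023-01-09T10:00:00", "F04", "B1")] * 2
        )
        t = aggregate_daily(v, w, self.meta("B1"))
        row = ("B1", dt.date(2023, 1, 9))
        assert t.unique_feeder_count.loc[row] == 2
        assert t.total_visits.loc[row] == 5

    def test_unknown_tag_listed_in_error(self):
        w = make_window(days=1)
        v = self.visits([("2023-01-09T09:00:00", "F02", "BX")])
        with pytest.raises(ValueError, match="BX"):
            aggregate_daily(v, w, self.meta("B1"))

    def test_grid_is_birds_times_days_and_visits_conserved(self, rng):
        w = make_window(days=37)
        n = 300
        days = rng.integers(0, 37, n)
        rows = [
            (
                (dt.datetime(2023, 1, 9, 8) + dt.timedelta(days=int(d), seconds=int(s))).isoformat(),
                rng.choice(["F02", "F04"]),
                rng.choice(["B1", "B2", "B3"]),
            )
            for d, s in zip(days, rng.integers(0, 3600, n))
        ]
        t = aggregate_daily(self.visits(rows), w, self.meta("B1", "B2", "B3"))
        assert len(t) == 3 * 37
        assert t.total_visits.sum() == n


class TestMortalityRule:
    def table(self, totals_by_bird, start="2023-01-09"):
        start = dt.date.fromisoformat(start)
        rows, idx = [], []
        for bird, totals in totals_by_bird.items():
            for i, v in enumerate(totals):
                idx.append((bird, start + dt.timedelta(days=i)))
                rows.append({"F02": float(v)})
        counts = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(idx, names=["bird", "date"]))
        return BirdDayTable(counts)

    def test_trailing_zeros_become_missing(self):
        t = apply_mortality_rule(self.table({"B1": [3, 2, 0, 0, 0]}), min_run_length=1)
        assert list(t.total_visits.isna()) == [False, False, True, True, True]

    def test_interior_zeros_untouched(self):
        t = apply_mortality_rule(self.table({"B1": [1, 0, 2, 4]}), min_run_length=1)
        assert not t.total_visits.isna().any()

    def test_min_run_length_respected(self):
        t = apply_mortality_rule(self.table({"B1": [1, 2, 3, 0, 0]}), min_run_length=3)
        assert not t.total_visits.isna().any()

    @settings(max_examples=30, deadline=None)
    @given(
        totals=st.lists(st.integers(min_value=0, max_value=4), min_size=1, max_size=10),
        min_run=st.integers(min_value=1, max_value=3),
    )
    def test_idempotent_and_only_trailing_changed(self, totals, min_run):
        t0 = self.table({"B1": totals})
        t1 = apply_mortality_rule(t0, min_run)
        t2 = apply_mortality_rule(t1, min_run)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        # any masked position must belong to the trailing zero run
        masked = t1.total_visits.isna().to_numpy()
        arr = np.asarray(totals, dtype=float)
        tail = len(arr) - np.max(np.nonzero(arr)[0]) - 1 if arr.any() else len(arr)
        assert masked[: len(arr) - tail].sum() == 0
        if masked.any():
            assert masked[len(arr) - tail:].all() or not masked.any()


class TestExclusions:
    def test_bird_feeder_and_range_exclusions(self, small_table):
        birds = small_table.birds
        w = StudyWindow(
            start=dt.date(2023, 1, 9),
            end=dt.date(2023, 1, 20),
            excluded_ranges=((dt.date(2023, 1, 12), dt.date(2023, 1, 13)),),
            excluded_feeders=frozenset({"F04"}),
            excluded_birds=frozenset({birds[0]}),
        )
        out = apply_exclusions(small_table, w)
        assert birds[0] not in out.birds
        assert "F04" not in out.feeders
        assert dt.date(2023, 1, 12) not in out.dates
        assert dt.date(2023, 1, 13) not in out.dates

    def test_no_exclusions_is_identity(self, small_table):
        w = StudyWindow(start=dt.date(2023, 1, 9), end=dt.date(2023, 1, 20))
        out = apply_exclusions(small_table, w)
        pd.testing.assert_frame_equal(out.counts, small_table.counts)

    def test_unknown_exclusion_warns_not_errors(self, small_table, caplog):
        w = StudyWindow(
            start=dt.date(2023, 1, 9),
            end=dt.date(2023, 1, 20),
            excluded_birds=frozenset({"NOSUCH"}),
        )
        out = apply_exclusions(small_table, w)
        assert len(out) == len(small_table)
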