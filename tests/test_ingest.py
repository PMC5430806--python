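"""Ping-log parsing, daytime windowing, dyad-slot collapse, overlap hours."""

from datetime import time as dtime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from motenet import (collapse_to_dyad_slots, dyad_overlap_hours,
                     filter_daytime, read_ping_log, read_presence)
from motenet.ingest import apply_swaps, daytime_hours, read_swaps
from motenet.errors import FormatError


def _write(tmp_path, text, name="pings.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPingLog:
    def test_well_formed_rows_are_read(self, tmp_path):
        p = _write(tmp_path, "emitter,receiver,timestamp\n"
                             "A,B,2014-02-01T08:00:00\n"
                             "B,A,2014-02-01T08:00:00\n"
                             "C,A,2014-02-01T08:02:00\n")
        df = read_ping_log(p)
        assert len(df) == 3
        assert df["emitter"].tolist() == ["A", "B", "C"]
        assert df["timestamp"].dtype.kind == "M"

    def test_ids_stay_strings(self, tmp_path):
        p = _write(tmp_path, "emitter,receiver,timestamp\n"
                             "001,010,2014-02-01T08:00:00\n")
        df = read_ping_log(p)
        assert df.loc[0, "emitter"] == "001"  # not coerced to 1

    def test_self_detection_rejected_and_logged(self, tmp_path, caplog):
        p = _write(tmp_path, "emitter,receiver,timestamp\n"
                             "A,A,2014-02-01T08:00:00\n"
                             "A,B,2014-02-01T08:00:00\n")
        with caplog.at_level("WARNING"):
            df = read_ping_log(p)
        assert len(df) == 1
        assert any("self-detection" in r.message for r in caplog.records)

    def test_malformed_timestamp_rejected(self, tmp_path):
        p = _write(tmp_path, "emitter,receiver,timestamp\n"
                             "A,B,not-a-time\n"
                             "A,B,2014-02-01T08:00:00\n")
        assert len(read_ping_log(p)) == 1

    def test_missing_column_raises(self, tmp_path):
        p = _write(tmp_path, "emitter,timestamp\nA,2014-02-01T08:00:00\n")
        with pytest.raises(FormatError):
            read_ping_log(p)

    def test_empty_file_warns(self, tmp_path, caplog):
        p = _write(tmp_path, "emitter,receiver,timestamp\n")
        with caplog.at_level("WARNING"):
            df = read_ping_log(p)
        assert df.empty


class TestFilterDaytime:
    @pytest.mark.parametrize("stamp,kept", [
        ("2014-02-01T04:58:00", False),
        ("2014-02-01T05:00:00", True),
        ("2014-02-01T19:58:00", True),
        ("2014-02-01T20:00:00", False),
    ])
    def test_half_open_window_boundaries(self, stamp, kept):
        df = pd.DataFrame({"emitter": ["A"], "receiver": ["B"],
                           "timestamp": [pd.Timestamp(stamp)]})
        assert (len(filter_daytime(df)) == 1) is kept

    def test_uniform_slots_retained_fraction(self):
        # one ping at the start of each 2-minute slot of a full day:
        # exactly 15/24 of them fall inside [05:00, 20:00)
        slots = pd.date_range("2014-02-01", periods=720, freq="2min")
        df = pd.DataFrame({"emitter": "A", "receiver": "B",
                           "timestamp": slots})
        kept = filter_daytime(df)
        assert len(kept) / len(df) == pytest.approx(15 / 24)

    def test_order_preserved(self):
        ts = [pd.Timestamp("2014-02-01T07:04"), pd.Timestamp("2014-02-01T06:00")]
        df = pd.DataFrame({"emitter": "A", "receiver": "B", "timestamp": ts})
        assert filter_daytime(df)["timestamp"].tolist() == ts


class TestCollapse:
    def test_reciprocal_pair_is_one_event(self):
        t = pd.Timestamp("2014-02-01T08:00:00")
        df = pd.DataFrame({"emitter": ["A", "B"], "receiver": ["B", "A"],
                           "timestamp": [t, t]})
        out = collapse_to_dyad_slots(df)
        assert len(out) == 1
        assert (out.loc[0, "id_a"], out.loc[0, "id_b"]) == ("A", "B")

    def test_one_sided_detection_kept(self):
        df = pd.DataFrame({"emitter": ["A"], "receiver": ["B"],
                           "timestamp": [pd.Timestamp("2014-02-01T08:00")]})
        assert len(collapse_to_dyad_slots(df)) == 1

    def test_reciprocal_only_mode_drops_one_sided(self):
        t = pd.Timestamp("2014-02-01T08:00:00")
        df = pd.DataFrame({
            "emitter": ["A", "B", "A"], "receiver": ["B", "A", "C"],
            "timestamp": [t, t, t]})
        out = collapse_to_dyad_slots(df, reciprocal_only=True)
        assert out[["id_a", "id_b"]].values.tolist() == [["A", "B"]]

    def test_matches_set_based_oracle_on_random_log(self, rng):
        ids = list("ABCDE")
        t0 = pd.Timestamp("2014-02-01T05:00:00")
        rows = []
        for _ in range(50):
            i, j = rng.choice(len(ids), 2, replace=False)
            rows.append({"emitter": ids[i], "receiver": ids[j],
                         "timestamp": t0 + pd.Timedelta(
                             minutes=int(rng.integers(0, 30)))})
        df = pd.DataFrame(rows)
        oracle = {(min(r.emitter, r.receiver), max(r.emitter, r.receiver),
                   r.timestamp.floor("2min")) for r in df.itertuples()}
        out = collapse_to_dyad_slots(df)
        got = set(map(tuple, out[["id_a", "id_b", "slot"]].itertuples(
            index=False)))
        assert got == oracle

    @given(st.lists(st.tuples(st.sampled_from("ABCD"), st.sampled_from("ABCD"),
                              st.integers(0, 20)), min_size=1, max_size=60))
    def test_collapse_shrinks_and_is_idempotent(self, raw):
        t0 = pd.Timestamp("2014-02-01T05:00:00")
        rows = [(e, r, t0 + pd.Timedelta(minutes=2 * k))
                for e, r, k in raw if e != r]
        if not rows:
            return
        df = pd.DataFrame(rows, columns=["emitter", "receiver", "timestamp"])
        out = collapse_to_dyad_slots(df)
        assert len(out) <= len(df)
        again = collapse_to_dyad_slots(out.rename(
            columns={"id_a": "emitter", "id_b": "receiver", "slot": "timestamp"}))
        assert len(again) == len(out)


def _pres(rows):
    df = pd.DataFrame(rows, columns=["individual", "camp", "enter", "exit"])
    df["enter"] = pd.to_datetime(df["enter"])
    df["exit"] = pd.to_datetime(df["exit"])
    return df


class TestOverlapHours:
    def test_full_week_is_105_hours(self):
        a = _pres([("A", "c", "2014-02-01T05:00", "2014-02-08T05:00")])
        b = _pres([("B", "c", "2014-02-01T05:00", "2014-02-08T05:00")])
        assert dyad_overlap_hours(a, b) == pytest.approx(7 * 15)

    def test_early_departure_truncates(self):
        # B leaves at noon on day 3: days 1-2 full (15 h each) plus
        # 05:00-12:00 on day 3 = 7 h
        a = _pres([("A", "c", "2014-02-01T05:00", "2014-02-08T05:00")])
        b = _pres([("B", "c", "2014-02-01T05:00", "2014-02-03T12:00")])
        assert dyad_overlap_hours(a, b) == pytest.approx(2 * 15 + 7)

    def test_disjoint_presence_is_zero(self):
        a = _pres([("A", "c", "2014-02-01T05:00", "2014-02-02T05:00")])
        b = _pres([("B", "c", "2014-02-03T05:00", "2014-02-04T05:00")])
        assert dyad_overlap_hours(a, b) == 0.0

    def test_different_camps_do_not_overlap(self):
        a = _pres([("A", "c1", "2014-02-01T05:00", "2014-02-02T05:00")])
        b = _pres([("B", "c2", "2014-02-01T05:00", "2014-02-02T05:00")])
        assert dyad_overlap_hours(a, b) == 0.0

    @given(st.integers(0, 200), st.integers(1, 200),
           st.integers(0, 200), st.integers(1, 200))
    def test_symmetric_and_bounded(self, s1, d1, s2, d2):
        t0 = pd.Timestamp("2014-02-01T05:00")
        h = pd.Timedelta(hours=1)
        a = _pres([("A", "c", t0 + s1 * h, t0 + (s1 + d1) * h)])
        b = _pres([("B", "c", t0 + s2 * h, t0 + (s2 + d2) * h)])
        ab = dyad_overlap_hours(a, b)
        assert ab == pytest.approx(dyad_overlap_hours(b, a))
        own_a = daytime_hours(a.loc[0, "enter"], a.loc[0, "exit"])
        own_b = daytime_hours(b.loc[0, "enter"], b.loc[0, "exit"])
        assert ab <= min(own_a, own_b) + 1e-9


class TestSwaps:
    def test_ids_remapped_from_swap_time(self, tmp_path):
        pings = pd.DataFrame({
            "emitter": ["M1", "M1"], "receiver": ["M2", "M2"],
            "timestamp": pd.to_datetime(["2014-02-01T08:00",
                                         "2014-02-01T12:00"])})
        p = tmp_path / "swaps.csv"
        p.write_text("time,old_id,new_id\n2014-02-01T10:00,M1,X9\n")
        out = apply_swaps(pings, read_swaps(p))
        assert out["emitter"].tolist() == ["M1", "X9"]

    def test_presence_reader_rejects_inverted_interval(self, tmp_path):
        p = tmp_path / "presence.csv"
        p.write_text("individual,camp,enter,exit\n"
                     "A,c,2014-02-02T05:00,2014-02-01T05:00\n")
        with pytest.raises(FormatError):
            read_presence(p)
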