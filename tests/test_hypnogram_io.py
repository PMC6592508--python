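"""Hypnogram reading, stage mapping, night selection and alignment."""

import json
from datetime import datetime, timedelta

import pytest
from hypothesis import given, strategies as st

from sleeptrans.hypnogram import (CLASSIC_LEVEL, FOUR_STAGES, Hypnogram,
                                  align_pair, map_five_to_four, read_epoch_csv,
                                  read_fitbit_sleep_json, select_analysis_night,
                                  write_epoch_csv, write_fitbit_sleep_json)

START = datetime(2019, 1, 8, 23, 30)

stage_sequences = st.lists(st.sampled_from(FOUR_STAGES), min_size=1, max_size=120)


def _write_csv(tmp_path, rows, header="epoch_index,stage", meta=()):
    path = tmp_path / "night.csv"
    lines = [f"# {k}={v}" for k, v in meta] + [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


class TestEpochCsv:
    def test_direct_parse_with_metadata(self, tmp_path):
        path = _write_csv(tmp_path, ["1,W", "2,wake", "3,Light"],
                          meta=[("subject_id", "S01"), ("epoch_seconds", "30"),
                                ("start_time", "2019-01-08T23:30:00")])
        h = read_epoch_csv(path, device="tracker")
        assert h.stages == ("W", "W", "L")
        assert h.subject_id == "S01"
        assert h.epoch_seconds == 30
        assert h.start_time == START

    def test_classic_tokens_flagged_unusable(self, tmp_path):
        path = _write_csv(tmp_path, ["1,awake", "2,restless"])
        h = read_epoch_csv(path)
        assert h.granularity == CLASSIC_LEVEL

    def test_unknown_token_names_row_and_token(self, tmp_path):
        path = _write_csv(tmp_path, ["1,W", "2,W", "3,W", "4,W", "5,X"])
        with pytest.raises(ValueError, match=r"'X'.*row 5"):
            read_epoch_csv(path)

    def test_non_contiguous_index_rejected(self, tmp_path):
        path = _write_csv(tmp_path, ["1,W", "3,L"])
        with pytest.raises(ValueError, match="non-contiguous"):
            read_epoch_csv(path)

    @given(stages=stage_sequences)
    def test_round_trip_preserves_stages(self, stages, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        h = Hypnogram(stages=tuple(stages), subject_id="S09", start_time=START)
        write_epoch_csv(h, tmp / "h.csv")
        back = read_epoch_csv(tmp / "h.csv")
        assert back.stages == h.stages
        assert back.subject_id == h.subject_id
        assert back.start_time == h.start_time


class TestSleepJson:
    @staticmethod
    def _doc(records, start="2019-01-08T23:30:00"):
        return {"sleep": [{"startTime": start, "levels": {"data": records}}]}

    @staticmethod
    def _records(specs, start=START, step=None):
        out, t = [], start
        for level, seconds in specs:
            out.append({"dateTime": t.isoformat(), "level": level, "seconds": seconds})
            t += timedelta(seconds=seconds)
        return out

    def test_rem_record_expands_to_epochs(self, tmp_path):
        path = tmp_path / "s.json"
        path.write_text(json.dumps(self._doc(self._records([("rem", 90), ("light", 60)]))))
        h = read_fitbit_sleep_json(path)
        assert h.stages == ("R", "R", "R", "L", "L")
        assert h.epoch_seconds == 30 and h.device == "tracker"

    def test_classic_only_document_is_flagged(self, tmp_path):
        path = tmp_path / "c.json"
        path.write_text(json.dumps(self._doc(self._records([("awake", 120), ("asleep", 600)]))))
        h = read_fitbit_sleep_json(path)
        assert h.granularity == CLASSIC_LEVEL

    def test_duration_not_multiple_of_epoch_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(self._doc(self._records([("deep", 45)]))))
        with pytest.raises(ValueError, match="multiple"):
            read_fitbit_sleep_json(path)

    def test_overlapping_records_rejected(self, tmp_path):
        recs = self._records([("light", 60), ("deep", 60)])
        recs[1]["dateTime"] = recs[0]["dateTime"]  # retrograde
        path = tmp_path / "o.json"
        path.write_text(json.dumps(self._doc(recs)))
        with pytest.raises(ValueError, match="overlapping|retrograde"):
            read_fitbit_sleep_json(path)

    @given(stages=stage_sequences)
    def test_json_round_trip(self, stages, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("json_rt")
        h = Hypnogram(stages=tuple(stages), device="tracker", start_time=START)
        write_fitbit_sleep_json(h, tmp / "h.json")
        back = read_fitbit_sleep_json(tmp / "h.json")
        assert back.stages == h.stages
        assert back.start_time == h.start_time


class TestStageMapping:
    @pytest.mark.parametrize("five, four", [
        (("W", "N1", "N2", "N3", "R"), ("W", "L", "L", "D", "R")),
        (("N3", "N3"), ("D", "D")),
    ])
    def test_defined_mapping(self, five, four):
        assert map_five_to_four(Hypnogram(stages=five)).stages == four

    def test_idempotent_on_four_stage(self):
        h = Hypnogram(stages=("W", "L", "D", "R"))
        assert map_five_to_four(h) is h

    @given(stages=st.lists(st.sampled_from(("W", "N1", "N2", "N3", "R")),
                           min_size=1, max_size=60))
    def test_preserves_length_and_wake_rem_positions(self, stages):
        h = Hypnogram(stages=tuple(stages))
        mapped = map_five_to_four(h)
        assert mapped.n_epochs == h.n_epochs
        for a, b in zip(h.stages, mapped.stages):
            assert (a == "W") == (b == "W")
            assert (a == "R") == (b == "R")


def _night(n=300, device="reference", start=START, classic=False):
    return Hypnogram(stages=("W",) * 2 + ("L",) * (n - 2) if not classic else ("awake",) * n,
                     device=device, start_time=start,
                     granularity="classic_level" if classic else "stage_level")


class TestNightSelection:
    def _pair(self, **kw):
        return (_night(device="tracker", **kw), _night())

    def test_second_night_preferred(self):
        nights = {1: self._pair(), 2: self._pair(), 3: self._pair()}
        assert select_analysis_night(nights).night_index == 2

    def test_third_night_fallback(self):
        nights = {1: self._pair(), 2: (None, _night()), 3: self._pair()}
        assert select_analysis_night(nights).night_index == 3

    def test_first_night_last_resort(self):
        nights = {1: self._pair(),
                  2: (_night(device="tracker", classic=True), _night()),
                  3: self._pair(n=100)}  # too short
        assert select_analysis_night(nights).night_index == 1

    def test_no_valid_night_is_exclusion_not_crash(self):
        sel = select_analysis_night({}, subject_id="S99")
        assert sel.excluded and sel.subject_id == "S99"
        sel = select_analysis_night({2: (None, None)})
        assert sel.excluded and "night 2" in sel.reason


class TestAlignment:
    def test_common_start_trims_to_min_length(self):
        t = Hypnogram(stages=("L",) * 960, device="tracker", start_time=START)
        r = Hypnogram(stages=("L",) * 950, start_time=START)
        assert align_pair(t, r).n_epochs == 950

    def test_later_tracker_start_drops_leading_reference_epochs(self):
        t = Hypnogram(stages=("D",) * 10, device="tracker",
                      start_time=START + timedelta(seconds=60))
        r = Hypnogram(stages=("W", "W") + ("L",) * 10, start_time=START)
        pair = align_pair(t, r)
        assert pair.reference.stages == ("L",) * 10
        assert pair.n_epochs == 10

    def test_disjoint_intervals_error(self):
        t = Hypnogram(stages=("L",) * 10, device="tracker",
                      start_time=START + timedelta(hours=12))
        r = Hypnogram(stages=("L",) * 10, start_time=START)
        with pytest.raises(ValueError, match="overlap"):
            align_pair(t, r)

    @given(nt=st.integers(2, 50), nr=st.integers(2, 50),
           offset_epochs=st.integers(-10, 10))
    def test_overlap_length_symmetric_under_swap(self, nt, nr, offset_epochs):
        t = Hypnogram(stages=("L",) * nt, device="tracker",
                      start_time=START + timedelta(seconds=30 * offset_epochs))
        r = Hypnogram(stages=("L",) * nr, start_time=START)
        try:
            n_forward = align_pair(t, r).n_epochs
        except ValueError:
            n_forward = None
        t2 = Hypnogram(stages=r.stages, device="tracker", start_time=r.start_time)
        r2 = Hypnogram(stages=t.stages, device="reference", start_time=t.start_time)
        try:
            n_swapped = align_pair(t2, r2).n_epochs
        except ValueError:
            n_swapped = None
        assert n_forward == n_swapped
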