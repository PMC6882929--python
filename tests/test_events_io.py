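"""Event-stream reading, writing, validation, and clock arithmetic."""

import pytest
from hypothesis import given, settings, strategies as st

from opic import (
    CodedObservation,
    EventError,
    EventRecord,
    EventType,
    ReadError,
    read_events,
    to_clock,
    validate_observation,
    write_events,
)

HEADER = "Observation id,Subject,Behavior,Modifiers,Behavior type,Start (s),Stop (s)"


def _write(tmp_path, rows, name="events.csv"):
    p = tmp_path / name
    p.write_text("\n".join([HEADER] + rows) + "\n")
    return p


class TestReadEvents:
    def test_three_row_fixture(self, tmp_path, ethogram):
        p = _write(tmp_path, [
            "n1,child,Settling routine,,STATE,0,600",
            "n1,child,Lights out,,POINT,600,600",
            "n1,child,Sleep,,STATE,900,28800",
        ])
        obs = read_events(p, ethogram)
        assert len(obs.events) == 3
        types = [e.event_type for e in obs.sorted_events()]
        assert types.count(EventType.STATE) == 2
        assert types.count(EventType.POINT) == 1
        assert obs.observation_id == "n1"

    def test_header_only(self, tmp_path, ethogram):
        obs = read_events(_write(tmp_path, []), ethogram)
        assert obs.events == ()

    def test_unknown_code_names_row(self, tmp_path, ethogram):
        p = _write(tmp_path, ["n1,child,Levitating,,STATE,0,10"])
        with pytest.raises(ReadError, match="row 2.*Levitating"):
            read_events(p, ethogram)

    def test_non_numeric_time_names_row(self, tmp_path, ethogram):
        p = _write(tmp_path, ["n1,child,Sleep,,STATE,abc,10"])
        with pytest.raises(ReadError, match="row 2"):
            read_events(p, ethogram)

    def test_stop_before_start_rejected(self, tmp_path, ethogram):
        p = _write(tmp_path, ["n1,child,Sleep,,STATE,100,50"])
        with pytest.raises(ReadError, match="stop"):
            read_events(p, ethogram)

    def test_tab_delimited_and_column_map(self, tmp_path, ethogram):
        p = tmp_path / "events.tsv"
        p.write_text("obs\twho\tcode\tbegin\tend\nn1\tchild\tSleep\t0\t100\n")
        obs = read_events(p, ethogram, column_map={
            "observation_id": "obs", "subject": "who", "behavior": "code",
            "start": "begin", "stop": "end",
        })
        assert len(obs.events) == 1
        assert obs.events[0].stop_s == 100.0


class TestEventRecord:
    def test_point_requires_equal_endpoints(self):
        with pytest.raises(EventError):
            EventRecord("child", "Lights out", EventType.POINT, 5.0, 6.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(EventError):
            EventRecord("child", "Sleep", EventType.STATE, 10.0, 5.0)


class TestValidation:
    def test_well_formed_night_clean(self, participant1_night, ethogram):
        report = validate_observation(participant1_night, ethogram)
        assert report.ok
        assert report.issues == []

    def test_point_coded_with_duration_flagged(self, ethogram):
        obs = CodedObservation("x", "20:00:00", "A", (
            EventRecord("child", "Sleep onset", EventType.STATE, 100.0, 200.0),
        ), 1000.0)
        report = validate_observation(obs, ethogram)
        assert any(i.rule == "type-mismatch" for i in report.errors)

    def test_modifier_outside_vocabulary_flagged(self, ethogram):
        obs = CodedObservation("x", "20:00:00", "A", (
            EventRecord("child", "In bed", EventType.STATE, 0.0, 100.0,
                        {"Position": "floating"}),
        ), 1000.0)
        report = validate_observation(obs, ethogram)
        assert any(i.rule == "modifier-value" for i in report.errors)

    def test_same_code_subject_overlap_is_error(self, ethogram):
        obs = CodedObservation("x", "20:00:00", "A", (
            EventRecord("child", "Sleep", EventType.STATE, 0.0, 100.0),
            EventRecord("child", "Sleep", EventType.STATE, 50.0, 150.0),
        ), 1000.0)
        assert any(i.rule == "state-overlap"
                   for i in validate_observation(obs, ethogram).errors)

    def test_touching_states_do_not_overlap(self, ethogram):
        # half-open intervals: [0, 100) then [100, 200) is legal
        obs = CodedObservation("x", "20:00:00", "A", (
            EventRecord("child", "Sleep", EventType.STATE, 0.0, 100.0),
            EventRecord("child", "Sleep", EventType.STATE, 100.0, 200.0),
        ), 1000.0)
        assert not any(i.rule == "state-overlap"
                       for i in validate_observation(obs, ethogram).errors)

    def test_different_codes_may_overlap(self, ethogram):
        obs = CodedObservation("x", "20:00:00", "A", (
            EventRecord("child", "Sleep", EventType.STATE, 0.0, 100.0),
            EventRecord("child", "In bed", EventType.STATE, 0.0, 100.0,
                        {"Position": "lying"}),
        ), 1000.0)
        assert not validate_observation(obs, ethogram).errors

    def test_missing_anchors_are_warnings(self, ethogram):
        obs = CodedObservation("x", "20:00:00", "A", (), 1000.0)
        report = validate_observation(obs, ethogram)
        assert report.ok
        assert {i.rule for i in report.warnings} == {"missing-anchor"}

    def test_validation_is_idempotent(self, participant1_night, ethogram):
        r1 = validate_observation(participant1_night, ethogram)
        r2 = validate_observation(participant1_night, ethogram)
        assert r1.issues == r2.issues


class TestToClock:
    def test_minute_floor(self):
        obs = CodedObservation("x", "20:00:00", "A", (), 40000.0)
        assert to_clock(obs, 2220.0) == "20:37"
        assert to_clock(obs, 2279.0) == "20:37"  # floored, not rounded

    def test_midnight_wrap(self):
        obs = CodedObservation("x", "21:00:00", "A", (), 40000.0)
        assert to_clock(obs, 33000.0) == "06:10"

    def test_identity_at_zero(self):
        obs = CodedObservation("x", "20:00:00", "A", (), 40000.0)
        assert to_clock(obs, 0.0) == "20:00"

    def test_outside_window_rejected(self):
        obs = CodedObservation("x", "20:00:00", "A", (), 100.0)
        with pytest.raises(EventError):
            to_clock(obs, 101.0)

    def test_monotone_modulo_wrap(self):
        obs = CodedObservation("x", "23:00:00", "A", (), 7200.0)
        clocks = [to_clock(obs, t) for t in range(0, 7200, 60)]
        # increases within each day segment; one wrap at midnight
        wraps = sum(1 for a, b in zip(clocks, clocks[1:]) if b < a)
        assert wraps == 1


# -- write -> read round trip over randomized observations ------------------

_codes = [
    ("Sleep", EventType.STATE), ("Night waking", EventType.STATE),
    ("Lights out", EventType.POINT), ("Sleep onset", EventType.POINT),
    ("In bed", EventType.STATE), ("Laughing", EventType.POINT),
]


@st.composite
def observations(draw):
    n = draw(st.integers(0, 12))
    events = []
    for _ in range(n):
        name, etype = draw(st.sampled_from(_codes))
        start = round(draw(st.floats(0, 30000, allow_nan=False)), 3)
        if etype is EventType.POINT:
            stop = start
        else:
            stop = round(start + draw(st.floats(0, 5000, allow_nan=False)), 3)
        mods = {}
        if name == "In bed":
            mods["Position"] = draw(st.sampled_from(["lying", "sitting", "mobile"]))
        events.append(EventRecord(
            draw(st.sampled_from(["child", "parent"])), name, etype, start, stop, mods,
        ))
    return CodedObservation(
        observation_id=draw(st.sampled_from(["n1", "night-2", "x"])),
        recording_start_clock=draw(st.sampled_from(["20:00:00", "21:15:30"])),
        coder_id=draw(st.sampled_from(["A", "B"])),
        events=tuple(events),
        recording_duration_s=36000.0,
    )


@settings(max_examples=50, deadline=None)
@given(obs=observations())
def test_write_read_roundtrip_identity(obs, tmp_path_factory, ethogram):
    path = tmp_path_factory.mktemp("io") / "obs.csv"
    write_events(obs, path)
    back = read_events(path, ethogram)
    assert back.sorted_events() == obs.sorted_events()
    assert back.observation_id == obs.observation_id
    assert back.recording_start_clock == obs.recording_start_clock
    assert back.coder_id == obs.coder_id
    assert back.recording_duration_s == pytest.approx(obs.recording_duration_s, abs=1e-3)


def test_modifier_serialization_roundtrip(tmp_path, ethogram):
    obs = CodedObservation("x", "20:00:00", "A", (
        EventRecord("parent", "Reading", EventType.STATE, 0.0, 60.0,
                    {"Helpful to sleep?": "soothing"}),
        EventRecord("child", "Laughing", EventType.POINT, 30.0, 30.0,
                    {"Helpful to sleep?": "neutral"}),
    ), 1000.0)
    path = tmp_path / "m.csv"
    write_events(obs, path)
    text = path.read_text()
    assert "Helpful to sleep?=soothing" in text
    back = read_events(path, ethogram)
    assert back.sorted_events() == obs.sorted_events()
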