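"""Shared fixtures: the default ethogram and constructed coded nights."""

from __future__ import annotations

import pytest

from opic import CodedObservation, EventRecord, EventType, default_opic_ethogram
from opic.ethogram import (
    LIGHTS_OUT,
    MORNING_WAKING,
    NIGHT_WAKING,
    SETTLING_ROUTINE,
    SLEEP,
    SLEEP_ONSET,
)


@pytest.fixture(scope="session")
def ethogram():
    return default_opic_ethogram()


def make_night(
    *,
    start_clock: str = "20:00:00",
    settling_stop_s: float = 1800.0,
    onset_s: float,
    offset_s: float,
    wakings: list[tuple[float, float]] = (),
    duration_s: float | None = None,
    observation_id: str = "constructed",
    coder_id: str = "A",
) -> CodedObservation:
    """A minimal well-formed night: settling routine, anchors, sleep segments
    split around the given (start, stop) night wakings."""
    S, P = EventType.STATE, EventType.POINT
    events = [
        EventRecord("child", SETTLING_ROUTINE, S, 0.0, settling_stop_s),
        EventRecord("child", LIGHTS_OUT, P, settling_stop_s, settling_stop_s),
        EventRecord("child", SLEEP_ONSET, P, onset_s, onset_s),
        EventRecord("child", MORNING_WAKING, P, offset_s, offset_s),
    ]
    cursor = onset_s
    for w_start, w_stop in wakings:
        events.append(EventRecord("child", NIGHT_WAKING, S, w_start, w_stop))
        if w_start > cursor:
            events.append(EventRecord("child", SLEEP, S, cursor, w_start))
        cursor = max(cursor, w_stop)
    if offset_s > cursor:
        events.append(EventRecord("child", SLEEP, S, cursor, offset_s))
    return CodedObservation(
        observation_id=observation_id,
        recording_start_clock=start_clock,
        coder_id=coder_id,
        events=tuple(events),
        recording_duration_s=duration_s if duration_s is not None else offset_s + 300.0,
    )


@pytest.fixture
def participant1_night():
    """A night embodying the first family's observed row: sleep onset 20:37,
    morning waking 06:10, 12 night wakings of 130 s each (26.0 min total)."""
    onset = 37 * 60.0  # 20:37 with recording start 20:00:00
    offset = (10 * 60 + 10) * 60.0  # 06:10 next morning
    wakings = [(onset + 1800.0 + k * 2400.0, onset + 1800.0 + k * 2400.0 + 130.0)
               for k in range(12)]
    return make_night(onset_s=onset, offset_s=offset, wakings=wakings,
                      observation_id="participant-1")
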