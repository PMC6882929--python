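"""Child sleep schedule and sleep quality derived from a coded night.

Sleep *schedule* means the sleep-onset and morning-waking clock times;
sleep *quality* means the number and total duration of night wakings.
Wakings are counted from coded "Night waking" state events whose start lies
strictly inside the sleep period; a waking overlapping morning waking is
truncated there. Durations are reported in minutes rounded half-up to 0.1.

Also provides the screening-total helper for the Disorders of Initiating and
Maintaining Sleep subscale of the Sleep Disturbance Scale for Children (SDSC):
7 items on a 5-point Likert scale, total out of 35, eligibility at >= 16.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .errors import MetricsError
from .ethogram import (
    Ethogram,
    MORNING_WAKING,
    MOVEMENT_AROUSAL,
    NIGHT_WAKING,
    SETTLING_ROUTINE,
    LIGHTS_OUT,
    SLEEP_ONSET,
)
from .events import CodedObservation, to_clock, parse_clock

__all__ = [
    "SleepMetrics",
    "ParentReport",
    "DiscrepancyRow",
    "DiscrepancyTable",
    "derive_sleep_metrics",
    "compare_with_report",
    "sdsc_screen",
    "round_min",
]


def round_min(seconds: float) -> float:
    """Seconds -> minutes rounded half-up to 0.1 (the reporting precision)."""
    # via repr so 9 s -> "0.15" -> 0.2 (a raw binary float of 0.15 would
    # quantize down to 0.1)
    return float(
        Decimal(repr(seconds / 60.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class SleepMetrics:
    """Derived schedule and quality numbers for one observed night."""

    settling_routine_duration_min: float | None
    lights_out_clock: str | None
    sleep_onset_clock: str
    sleep_offset_clock: str
    sleep_period_min: float
    n_night_wakings: int
    total_night_waking_min: float
    n_movement_arousals: int
    sleep_onset_s: float  # offsets into the recording, for discrepancy work
    sleep_offset_s: float

    def __post_init__(self) -> None:
        if self.sleep_offset_s <= self.sleep_onset_s:
            raise MetricsError("morning waking must come after sleep onset")
        if self.n_night_wakings < 0:
            raise MetricsError("negative waking count")
        if self.total_night_waking_min > self.sleep_period_min + 1e-9:
            raise MetricsError("waking time exceeds the sleep period")

    def to_dict(self) -> dict:
        return {
            "settling_routine_duration_min": self.settling_routine_duration_min,
            "lights_out_clock": self.lights_out_clock,
            "sleep_onset_clock": self.sleep_onset_clock,
            "sleep_offset_clock": self.sleep_offset_clock,
            "sleep_period_min": self.sleep_period_min,
            "n_night_wakings": self.n_night_wakings,
            "total_night_waking_min": self.total_night_waking_min,
            "n_movement_arousals": self.n_movement_arousals,
        }


@dataclass(frozen=True)
class ParentReport:
    """The caregiver's reported numbers for the same night."""

    reported_sleep_onset_clock: str
    reported_sleep_offset_clock: str
    reported_n_night_wakings: int
    reported_total_night_waking_min: float

    def __post_init__(self) -> None:
        parse_clock(self.reported_sleep_onset_clock)
        parse_clock(self.reported_sleep_offset_clock)
        if self.reported_n_night_wakings < 0:
            raise MetricsError("reported waking count must be non-negative")
        if self.reported_total_night_waking_min < 0:
            raise MetricsError("reported waking duration must be non-negative")


@dataclass(frozen=True)
class DiscrepancyRow:
    variable: str
    block: str  # "Sleep schedule" | "Sleep quality"
    reported: object
    observed: object
    difference: float  # observed - reported, minutes for times/durations
    unit: str
    under_report: bool


@dataclass(frozen=True)
class DiscrepancyTable:
    """Reported vs observed, with signed differences (observed − reported)."""

    rows: tuple[DiscrepancyRow, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "block": r.block,
                    "variable": r.variable,
                    "reported": r.reported,
                    "observed": r.observed,
                    "difference": r.difference,
                    "unit": r.unit,
                    "under_report": r.under_report,
                }
                for r in self.rows
            ]
        )

    def to_dict(self) -> list[dict]:
        return self.to_dataframe().to_dict(orient="records")


def _single_point(obs: CodedObservation, code_name: str) -> float:
    events = obs.events_with_code(code_name)
    if not events:
        raise MetricsError(f"no {code_name!r} event in observation")
    if len(events) > 1:
        raise MetricsError(
            f"{len(events)} {code_name!r} events; exactly one expected"
        )
    return events[0].start_s


def derive_sleep_metrics(obs: CodedObservation, e: Ethogram) -> SleepMetrics:
    """Derive schedule and quality metrics from the coded time-domain and
    child-global-state events.

    Requires exactly one "Sleep onset" and one "Morning waking" point event.
    Night wakings starting before sleep onset belong to the settling period
    and are excluded; a waking running past morning waking is truncated there.
    """
    onset_s = _single_point(obs, SLEEP_ONSET)
    offset_s = _single_point(obs, MORNING_WAKING)
    if offset_s <= onset_s:
        raise MetricsError(
            f"morning waking ({offset_s} s) not after sleep onset ({onset_s} s)"
        )

    settling = obs.events_with_code(SETTLING_ROUTINE)
    settling_min = round_min(settling[0].duration_s) if settling else None
    lights_out = obs.events_with_code(LIGHTS_OUT)
    lights_out_clock = to_clock(obs, lights_out[0].start_s) if lights_out else None

    waking_total_s = 0.0
    n_wakings = 0
    for ev in obs.events_with_code(NIGHT_WAKING):
        if not (onset_s < ev.start_s < offset_s):
            continue
        n_wakings += 1
        waking_total_s += min(ev.stop_s, offset_s) - ev.start_s

    n_arousals = sum(
        1
        for ev in obs.events_with_code(MOVEMENT_AROUSAL)
        if onset_s < ev.start_s < offset_s
    )

    return SleepMetrics(
        settling_routine_duration_min=settling_min,
        lights_out_clock=lights_out_clock,
        sleep_onset_clock=to_clock(obs, onset_s),
        sleep_offset_clock=to_clock(obs, offset_s),
        sleep_period_min=round_min(offset_s - onset_s),
        n_night_wakings=n_wakings,
        total_night_waking_min=round_min(waking_total_s),
        n_movement_arousals=n_arousals,
        sleep_onset_s=onset_s,
        sleep_offset_s=offset_s,
    )


def _clock_diff_min(observed: str, reported: str) -> float:
    """Signed observed − reported difference in minutes on a 24 h circle.

    The representative in (−720, 720] is chosen, so an onset reported 23:50
    and observed 00:05 is +15 min, not −1425. This anchors both clocks to the
    same night without needing the recording start.
    """
    d = (parse_clock(observed) - parse_clock(reported)) / 60.0
    d = d % (24 * 60)
    if d > 12 * 60:
        d -= 24 * 60
    return d


def compare_with_report(m: SleepMetrics, r: ParentReport) -> DiscrepancyTable:
    """Signed per-variable discrepancies (observed − reported).

    Schedule rows carry clock strings; quality rows carry counts/minutes.
    ``under_report`` flags quality variables where observation exceeded the
    report (the caregiver missed wakings or underestimated their length).
    """
    rows = (
        DiscrepancyRow(
            "Sleep onset time", "Sleep schedule",
            r.reported_sleep_onset_clock, m.sleep_onset_clock,
            _clock_diff_min(m.sleep_onset_clock, r.reported_sleep_onset_clock),
            "min", False,
        ),
        DiscrepancyRow(
            "Sleep offset time", "Sleep schedule",
            r.reported_sleep_offset_clock, m.sleep_offset_clock,
            _clock_diff_min(m.sleep_offset_clock, r.reported_sleep_offset_clock),
            "min", False,
        ),
        DiscrepancyRow(
            "Number of night wakings", "Sleep quality",
            r.reported_n_night_wakings, m.n_night_wakings,
            float(m.n_night_wakings - r.reported_n_night_wakings),
            "count", m.n_night_wakings > r.reported_n_night_wakings,
        ),
        DiscrepancyRow(
            "Total duration of night wakings", "Sleep quality",
            r.reported_total_night_waking_min, m.total_night_waking_min,
            round(m.total_night_waking_min - r.reported_total_night_waking_min, 1),
            "min",
            m.total_night_waking_min > r.reported_total_night_waking_min,
        ),
    )
    return DiscrepancyTable(rows=rows)


def sdsc_screen(item_scores: Sequence[int], cutoff: int = 16) -> dict:
    """Total and eligibility for the 7-item initiating/maintaining-sleep
    subscale (items scored 1–5, total out of 35, eligible when total >= cutoff).
    """
    items = list(item_scores)
    if len(items) != 7:
        raise ValueError(f"expected exactly 7 item scores, got {len(items)}")
    for i, s in enumerate(items):
        if not (isinstance(s, (int,)) and 1 <= s <= 5):
            raise ValueError(f"item {i + 1}: score {s!r} not an integer in 1..5")
    total = sum(items)
    return {"total": total, "eligible": total >= cutoff}
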