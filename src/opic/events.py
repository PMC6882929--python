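"""Coded observation event streams: reading, writing, and validation.

The tabular dialect is modeled on a behavioral-observation aggregated event
export: one row per coded event with columns
``Observation id, Subject, Behavior, Modifiers, Behavior type, Start (s), Stop (s)``
(comma- or tab-separated, auto-detected). A leading ``#`` comment line may
carry observation metadata (recording start clock, duration, coder id); files
without it parse with caller-supplied defaults.

Times are seconds from recording start. State events are half-open intervals
``[start, stop)``; point events have ``stop == start``. Wall-clock times are
presentation only (:func:`to_clock`).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import EventError, ReadError
from .ethogram import (
    Ethogram,
    EventType,
    MORNING_WAKING,
    SLEEP_ONSET,
    Subjects,
    _canon,
)

__all__ = [
    "EventRecord",
    "CodedObservation",
    "ValidationIssue",
    "ValidationReport",
    "read_events",
    "write_events",
    "validate_observation",
    "to_clock",
    "parse_clock",
    "DEFAULT_COLUMNS",
]

DEFAULT_COLUMNS = {
    "observation_id": "Observation id",
    "subject": "Subject",
    "behavior": "Behavior",
    "modifiers": "Modifiers",
    "behavior_type": "Behavior type",
    "start": "Start (s)",
    "stop": "Stop (s)",
}

_TIME_EPS = 5e-4  # half a millisecond: times are kept to ms precision


@dataclass(frozen=True)
class EventRecord:
    """One coded behavior with timing and modifiers.

    ``subject`` is ``child``, ``parent``, or any other label; ``modifiers``
    maps modifier-set names to values. A POINT event has ``stop_s == start_s``.
    """

    subject: str
    code: str
    event_type: EventType
    start_s: float
    stop_s: float
    modifiers: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_type", EventType(self.event_type))
        object.__setattr__(self, "start_s", float(self.start_s))
        object.__setattr__(self, "stop_s", float(self.stop_s))
        object.__setattr__(self, "modifiers", dict(self.modifiers))
        if self.start_s < 0:
            raise EventError(f"event {self.code!r}: negative start time {self.start_s}")
        if self.stop_s < self.start_s:
            raise EventError(
                f"event {self.code!r}: stop {self.stop_s} before start {self.start_s}"
            )
        if self.event_type is EventType.POINT and self.stop_s != self.start_s:
            raise EventError(
                f"point event {self.code!r}: stop must equal start "
                f"({self.start_s} != {self.stop_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s

    def shifted(self, dt: float) -> "EventRecord":
        return replace(self, start_s=self.start_s + dt, stop_s=self.stop_s + dt)


@dataclass(frozen=True)
class CodedObservation:
    """A full night's ordered event stream with its recording-start anchor."""

    observation_id: str
    recording_start_clock: str  # HH:MM:SS wall clock at t = 0 s
    coder_id: str
    events: tuple[EventRecord, ...]
    recording_duration_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "recording_duration_s", float(self.recording_duration_s))
        parse_clock(self.recording_start_clock)  # raises on bad format
        if self.recording_duration_s < 0:
            raise EventError("recording_duration_s must be non-negative")

    def sorted_events(self) -> tuple[EventRecord, ...]:
        return tuple(
            sorted(self.events, key=lambda e: (e.start_s, e.stop_s, _canon(e.code), e.subject))
        )

    def events_with_code(self, code_name: str) -> tuple[EventRecord, ...]:
        key = _canon(code_name)
        return tuple(e for e in self.sorted_events() if _canon(e.code) == key)


# ---------------------------------------------------------------------------
# Clock arithmetic
# ---------------------------------------------------------------------------

_CLOCK_RE = re.compile(r"^(\d{1,2}):(\d{2})(?::(\d{2}))?$")


def parse_clock(clock: str) -> int:
    """Parse ``HH:MM[:SS]`` into seconds after midnight."""
    m = _CLOCK_RE.match(str(clock).strip())
    if not m:
        raise EventError(f"bad clock time {clock!r}, expected HH:MM[:SS]")
    h, mi, s = int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)
    if h > 23 or mi > 59 or s > 59:
        raise EventError(f"bad clock time {clock!r}")
    return h * 3600 + mi * 60 + s


def to_clock(obs: CodedObservation, t_s: float) -> str:
    """Wall-clock ``HH:MM`` (floored to the minute) for an offset into the night.

    Wraps past midnight. Raises if ``t_s`` lies outside the recording window.
    """
    if not (0 <= t_s <= obs.recording_duration_s):
        raise EventError(
            f"t_s = {t_s} outside recording window [0, {obs.recording_duration_s}]"
        )
    total = parse_clock(obs.recording_start_clock) + t_s
    minutes = int(total // 60) % (24 * 60)
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


# ---------------------------------------------------------------------------
# Reading and writing the tabular dialect
# ---------------------------------------------------------------------------


def _format_modifiers(modifiers: Mapping[str, str]) -> str:
    return "|".join(f"{k}={v}" for k, v in modifiers.items())


def _parse_modifiers(cell: str) -> dict[str, str]:
    cell = (cell or "").strip()
    if not cell:
        return {}
    out: dict[str, str] = {}
    for part in cell.split("|"):
        if "=" not in part:
            raise ReadError(f"bad modifier cell {cell!r}: expected name=value pairs")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _parse_meta_line(line: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for part in line.lstrip("#").strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_events(
    path: str | Path,
    e: Ethogram,
    column_map: Mapping[str, str] | None = None,
    *,
    on_unknown: str = "error",
    recording_start_clock: str = "20:00:00",
    recording_duration_s: float | None = None,
    coder_id: str = "",
) -> CodedObservation:
    """Read a coded event stream and resolve behavior names against an ethogram.

    Parameters
    ----------
    path:
        CSV or TSV file (delimiter auto-detected) with a mandatory header.
    e:
        Ethogram used to resolve behavior names (case-insensitive) and
        canonicalize modifier values.
    column_map:
        Optional override of the default header names, keyed by the logical
        names ``observation_id, subject, behavior, modifiers, behavior_type,
        start, stop``.
    on_unknown:
        ``"error"`` rejects rows whose behavior is not in the ethogram,
        ``"warn"`` drops them silently into the returned observation's margin
        (they are skipped; validation later reports anything else).
    recording_start_clock, recording_duration_s, coder_id:
        Defaults used when the file carries no ``#`` metadata line. Duration
        defaults to the latest stop time.

    Raises
    ------
    ReadError
        On unresolvable header, unknown behavior codes (with row numbers),
        non-numeric times, or stop < start.
    """
    if on_unknown not in ("error", "warn"):
        raise ValueError("on_unknown must be 'error' or 'warn'")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    meta: dict[str, str] = {}
    body_start = 0
    while body_start < len(lines) and lines[body_start].startswith("#"):
        meta.update(_parse_meta_line(lines[body_start]))
        body_start += 1
    body = "\n".join(lines[body_start:])
    if not body.strip():
        raise ReadError(f"{path}: no header row found")

    header_line = lines[body_start]
    delimiter = "\t" if header_line.count("\t") >= header_line.count(",") and "\t" in header_line else ","
    reader = csv.DictReader(body.splitlines(), delimiter=delimiter)

    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    fieldnames = {_canon(f): f for f in (reader.fieldnames or [])}

    def col(logical: str, required: bool = True) -> str | None:
        want = cols[logical]
        actual = fieldnames.get(_canon(want))
        if actual is None and required:
            raise ReadError(f"{path}: missing required column {want!r}")
        return actual

    c_obs = col("observation_id", required=False)
    c_subj = col("subject")
    c_beh = col("behavior")
    c_mod = col("modifiers", required=False)
    c_type = col("behavior_type", required=False)
    c_start = col("start")
    c_stop = col("stop")

    events: list[EventRecord] = []
    problems: list[str] = []
    obs_id = meta.get("observation_id", "")
    for i, row in enumerate(reader, start=2 + body_start):
        name = (row.get(c_beh) or "").strip()
        code = e.get(name)
        if code is None:
            msg = f"row {i}: unknown behavior code {name!r}"
            if on_unknown == "error":
                problems.append(msg)
            continue
        try:
            start = float(row[c_start])
            raw_stop = row.get(c_stop) if c_stop else None
            stop = float(raw_stop) if raw_stop not in (None, "") else start
        except (TypeError, ValueError):
            problems.append(f"row {i}: non-numeric time ({row.get(c_start)!r}, {row.get(c_stop)!r})")
            continue
        if stop < start:
            problems.append(f"row {i}: stop {stop} before start {start}")
            continue
        etype = code.event_type
        if c_type and (row.get(c_type) or "").strip():
            try:
                etype = EventType((row[c_type] or "").strip().upper())
            except ValueError:
                problems.append(f"row {i}: bad behavior type {row[c_type]!r}")
                continue
        if etype is EventType.POINT:
            stop = start
        modifiers = _parse_modifiers(row.get(c_mod, "") if c_mod else "")
        if c_obs and not obs_id:
            obs_id = (row.get(c_obs) or "").strip()
        events.append(
            EventRecord(
                subject=(row.get(c_subj) or "").strip().lower() or "child",
                code=code.name,
                event_type=etype,
                start_s=round(start, 3),
                stop_s=round(stop, 3),
                modifiers=modifiers,
            )
        )
    if problems:
        raise ReadError(f"{path}: " + "; ".join(problems))

    duration = recording_duration_s
    if "recording_duration_s" in meta:
        duration = float(meta["recording_duration_s"])
    if duration is None:
        duration = max((ev.stop_s for ev in events), default=0.0)
    return CodedObservation(
        observation_id=obs_id or path.stem,
        recording_start_clock=meta.get("recording_start_clock", recording_start_clock),
        coder_id=meta.get("coder_id", coder_id),
        events=tuple(events),
        recording_duration_s=duration,
    )


def write_events(obs: CodedObservation, path: str | Path, *, delimiter: str = ",") -> Path:
    """Write an observation in the tabular dialect; read_events round-trips it."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(
            f"# recording_start_clock={obs.recording_start_clock}; "
            f"recording_duration_s={obs.recording_duration_s:.3f}; "
            f"coder_id={obs.coder_id}; observation_id={obs.observation_id}\n"
        )
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(DEFAULT_COLUMNS.values()))
        for ev in obs.sorted_events():
            writer.writerow(
                [
                    obs.observation_id,
                    ev.subject,
                    ev.code,
                    _format_modifiers(ev.modifiers),
                    ev.event_type.value,
                    f"{ev.start_s:.3f}",
                    f"{ev.stop_s:.3f}",
                ]
            )
    return path


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    rule: str
    severity: str  # "error" | "warning"
    ref: str
    message: str

    def to_dict(self) -> dict:
        return {"rule": self.rule, "severity": self.severity,
                "ref": self.ref, "message": self.message}


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps([i.to_dict() for i in self.issues], indent=2)


def validate_observation(obs: CodedObservation, e: Ethogram) -> ValidationReport:
    """Check an observation against the ethogram's semantics.

    Errors: unknown codes, state/point type mismatch, modifier values outside
    their vocabulary, same-code same-subject state overlap, events outside
    the recording window, codes applied to an inapplicable subject.
    Warnings: missing sleep-onset or morning-waking anchors.
    """
    report = ValidationReport()

    def add(rule: str, severity: str, ref: str, message: str) -> None:
        report.issues.append(ValidationIssue(rule, severity, ref, message))

    seen_states: dict[tuple[str, str], list[EventRecord]] = {}
    for idx, ev in enumerate(obs.sorted_events()):
        ref = f"event {idx} ({ev.code} @ {ev.start_s:.1f}s)"
        code = e.get(ev.code)
        if code is None:
            add("unknown-code", "error", ref, f"code {ev.code!r} not in ethogram")
            continue
        if code.event_type is not ev.event_type:
            add(
                "type-mismatch", "error", ref,
                f"{code.name!r} is a {code.event_type.value} event but coded as "
                f"{ev.event_type.value}",
            )
        if code.applicable_subjects is Subjects.CHILD and _canon(ev.subject) == "parent":
            add("subject", "error", ref, f"{code.name!r} applies to the child only")
        elif code.applicable_subjects is Subjects.PARENT and _canon(ev.subject) == "child":
            add("subject", "error", ref, f"{code.name!r} applies to the parent only")
        for mname, mvalue in ev.modifiers.items():
            mset = code.modifier_set(mname)
            if mset is None:
                add("modifier-set", "error", ref,
                    f"{code.name!r} has no modifier set {mname!r}")
            elif mset.resolve(mvalue) is None:
                add("modifier-value", "error", ref,
                    f"value {mvalue!r} not in vocabulary of {mname!r} "
                    f"({', '.join(mset.allowed_values)})")
        if ev.start_s < -_TIME_EPS or ev.stop_s > obs.recording_duration_s + _TIME_EPS:
            add("window", "error", ref,
                f"event outside recording window [0, {obs.recording_duration_s}]")
        if ev.event_type is EventType.STATE:
            key = (_canon(ev.code), _canon(ev.subject))
            for prev in seen_states.get(key, []):
                # half-open intervals: touching endpoints do not overlap
                if ev.start_s < prev.stop_s - _TIME_EPS and prev.start_s < ev.stop_s - _TIME_EPS:
                    add("state-overlap", "error", ref,
                        f"overlaps earlier {ev.code!r} state of the same subject "
                        f"[{prev.start_s:.1f}, {prev.stop_s:.1f})")
            seen_states.setdefault(key, []).append(ev)

    for anchor in (SLEEP_ONSET, MORNING_WAKING):
        if not obs.events_with_code(anchor):
            add("missing-anchor", "warning", "observation",
                f"no {anchor!r} event coded")
    return report
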