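"""Compare observed sleep metrics against a caregiver's report.

Builds a night whose observed schedule and quality match a realistic
under-reporting pattern — the parent noticed 4 of 12 wakings because the
child mostly self-soothed without signaling — and prints the discrepancy
table.
"""

from opic import (
    CodedObservation,
    EventRecord,
    EventType,
    ParentReport,
    compare_with_report,
    default_opic_ethogram,
    derive_sleep_metrics,
)

S, P = EventType.STATE, EventType.POINT
onset = 37 * 60.0           # 20:37 (recording starts 20:00)
offset = (10 * 60 + 10) * 60.0  # 06:10 next morning
events = [
    EventRecord("child", "Settling routine", S, 0.0, 1800.0),
    EventRecord("child", "Lights out", P, 1800.0, 1800.0),
    EventRecord("child", "Sleep onset", P, onset, onset),
    EventRecord("child", "Morning waking", P, offset, offset),
]
for k in range(12):  # 12 wakings of 130 s each -> 26.0 min total
    w0 = onset + 1800.0 + k * 2400.0
    events.append(EventRecord("child", "Night waking", S, w0, w0 + 130.0))
night = CodedObservation("demo", "20:00:00", "A", tuple(events), offset + 300.0)

e = default_opic_ethogram()
m = derive_sleep_metrics(night, e)
report = ParentReport(
    reported_sleep_onset_clock="20:30",
    reported_sleep_offset_clock="06:30",
    reported_n_night_wakings=4,
    reported_total_night_waking_min=12.0,
)
table = compare_with_report(m, report)
print(table.to_dataframe().to_string(index=False))

# Positive differences mean the observation exceeded the report. Schedule
# rows (clock times) are usually close; quality rows show the under-report:
# the caregiver missed 8 wakings and 14 minutes of wakefulness.
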