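"""Simulate a synthetic coded night and derive its sleep metrics.

Generates one ground-truth event stream (settling routine, lights out, sleep
onset, night wakings, morning waking), validates it, and scores the child's
sleep schedule and quality — the numbers a clinician would compare against
the caregiver's account.
"""

from opic import (
    NightScenario,
    default_opic_ethogram,
    derive_sleep_metrics,
    simulate_night,
    validate_observation,
)

e = default_opic_ethogram()
night = simulate_night(NightScenario(seed=42), e)
print(f"Simulated {len(night.events)} events "
      f"(recording starts {night.recording_start_clock}, "
      f"{night.recording_duration_s / 3600:.1f} h)")

report = validate_observation(night, e)
print(f"Validation: {len(report.errors)} errors, {len(report.warnings)} warnings")

m = derive_sleep_metrics(night, e)
print(f"\nSleep schedule: lights out {m.lights_out_clock}, "
      f"onset {m.sleep_onset_clock}, morning waking {m.sleep_offset_clock}")
print(f"Settling routine: {m.settling_routine_duration_min} min")
print(f"Sleep quality: {m.n_night_wakings} night wakings, "
      f"{m.total_night_waking_min} min awake in total")

# The onset/offset clocks are the child's sleep schedule; the waking count
# and total duration are the sleep-quality variables caregivers tend to
# under-report because self-soothed wakings go unnoticed.
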