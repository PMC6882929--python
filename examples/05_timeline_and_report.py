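"""Render a night's timeline and assemble the full report bundle.

Simulates a night and a second coder's rendition, then writes everything one
analysis produces — metrics, agreement, timelines, summary — into a bundle
directory.
"""

from pathlib import Path

from opic import (
    CoderNoise,
    MatchingConfig,
    NightScenario,
    agreement_between,
    build_report,
    default_opic_ethogram,
    derive_sleep_metrics,
    perturb_coder,
    render_timeline,
    simulate_night,
)

out = Path("example_output")
e = default_opic_ethogram()
truth = simulate_night(NightScenario(seed=11), e)
other = perturb_coder(truth, CoderNoise(seed=3, jitter_sd_s=2.0, p_miss=0.1), e)

svg = render_timeline(truth, path=out / "night_timeline.svg", e=e)
print(f"Timeline written to {svg}")

m = derive_sleep_metrics(truth, e)
agr = agreement_between(truth, other, MatchingConfig(), ethogram=e)
written = build_report(out / "bundle", observations=[truth, other],
                       metrics=m, agreement=agr, e=e)
print(f"Report bundle ({len(written)} artifacts):")
for name, path in written.items():
    print(f"  {name}: {path}")
print()
print((out / "bundle" / "summary.txt").read_text())

# The timeline is a Gantt-style chart: one lane per category, bars for state
# events, markers for point events, clock time on the x axis — the visual
# summary used to show a family what their bedtime routine actually looks like.
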