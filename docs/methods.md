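# Methods

This note documents the models, conventions, and numerical choices behind
`opic`, and what the synthetic-data tests do and do not establish about real
coded video.

## The coding model

A coded observation is an ordered stream of events on a common timeline
anchored at the recording start (a wall-clock `HH:MM:SS`). Each event carries
a subject (`child`, `parent`, or another label), a behavior code from an
ethogram, a type, timing, and optional modifier assignments.

- **State events** are ongoing behaviors with duration, stored as half-open
  intervals `[start, stop)` in seconds from recording start. Half-openness
  means back-to-back states of the same code touch without overlapping.
- **Point events** are instantaneous (`stop == start`).
- The system is deliberately **multi-layer**: events of different codes
  overlap freely (a child can be asleep, in bed, and lying down at once).
  Overlapping state events of the *same* code and subject are a validation
  error.
- Times are kept internally to millisecond precision; wall-clock output is
  floored to the minute, and reported durations are rounded half-up to
  0.1 min. Clock times are presentation only — all analytics run on seconds
  from recording start, which avoids midnight-wrap arithmetic.

The packaged ethogram has 26 codes in 6 categories (4 time domains, 3
physical environment, 3 child global state, 2 location, 12 activity, 2
physical interaction). Conventions where the published table is silent or
ambiguous, adopted once and documented here:

- The soothing modifier ("Helpful to sleep?": soothing / non-soothing /
  neutral) is attached to **all 12** activity codes; the source table's
  layout leaves ambiguous which activity rows it spans.
- The 6-value position modifier is attached to **both** location codes, not
  only "In bed" — a subject's posture out of bed is equally meaningful.
- Child-global-state codes apply to the child only; location, activity, and
  physical-interaction codes to either subject; time domains are properties
  of the night and carry no subject restriction.
- Modifiers are optional on a coded event; code and modifier labels match
  case- and whitespace-insensitively against the ethogram.

## Sleep metrics

Sleep **schedule** is the pair of clock times at the "Sleep onset" and
"Morning waking" point events (exactly one of each is required). Sleep
**quality** is the count and total duration of "Night waking" state events
whose start lies strictly inside the sleep period. Conventions:

- Wakings are counted from coded "Night waking" events, not inferred from
  gaps in the "Sleep" state: the coder, not the software, adjudicates
  wakefulness. "Movement arousal" is counted separately and never added to
  waking totals.
- A waking starting before sleep onset belongs to the settling period and is
  excluded; one running past morning waking is truncated there.
- Durations are rounded half-up to 0.1 min (via decimal string conversion,
  so 9 s → 0.15 min → 0.2, immune to binary-float ties); counts are exact.
- The screening subscale total assumes items scored 1–5 (a 5-point scale
  with a 35-point maximum forces a per-item maximum of 5); eligibility is
  total ≥ 16, boundary inclusive.

Discrepancy rows report observed − reported. Clock differences are the
representative of the difference in `(−720, 720]` minutes on the 24-hour
circle, so an onset reported 23:50 and observed 00:05 is +15 min. The
`under_report` flag is set for quality variables when observation exceeds
report.

## Inter-rater agreement

Two events are in *exact agreement* when they share the code name (and, by
default, subject and modifier assignments) and their timestamps fall within
the tolerance — 5 s by default. For state events the tolerance applies to
**both endpoints**; a point never matches a state of the same code. Design
choices on points the criterion itself leaves open:

- **Pairing** is a globally optimal one-to-one matching: maximum cardinality
  first, then minimal total cost `Σ(|Δstart| + |Δstop|)`. It is computed as
  a rectangular linear assignment in which ineligible pairs are priced above
  any feasible total cost (each eligible pair costs at most 2·tolerance and
  at most `min(N_a, N_b)` pairs can match), so cardinality dominates. Events
  are processed in (start time, code name) order, making ties deterministic.
  A brute-force enumerator over all one-to-one matchings serves as the
  independent oracle on small instances (≤ 8 events per coder).
- **Denominator**: agreement is `100·M/(N_a + N_b − M)` — matched pairs over
  distinct coded events after unification. It is symmetric and penalizes
  both omissions and insertions; with misses only, it reduces to the
  surviving fraction. The variant `100·2M/(N_a + N_b)` is available behind
  `MatchingConfig(mean_denominator=True)`.
- Categories with no events from either coder are reported "not assessable",
  never 0% or 100%. The 70% sufficiency threshold is a report-level
  annotation, not a gate.
- Chance-corrected coefficients (Cohen's kappa and relatives) are
  deliberately out of scope: with many rarely-used codes in a complex
  multi-layer system they are easily skewed, and chance agreement is
  negligible.

Useful identities, all enforced by tests: self-agreement is 100%; the
statistic is symmetric, monotone in the tolerance, and bounded by
`min(N_a,N_b)/max(N_a,N_b)` when every event of the smaller stream matches.

## The night simulator

`simulate_night` generates the behavioral skeleton the coding system
assumes: one settling-routine state ending at a "Lights out" point, a "Sleep
onset" point after an exponential latency, a Poisson number of
non-overlapping "Night waking" states inside the sleep period (placed by
stick-breaking, which is feasible whenever the total fits), "Sleep" states
filling the gaps, movement arousals, settling-period activities with
soothing modifiers, location states, and a "Morning waking" point shortly
before the recording ends. Signaled wakings (probability `p_signal`) add a
soothing parent verbalization and a brief-contact point. Every generated
night passes validation; generation is deterministic given the seed.

Defaults are chosen to echo the study conditions this kind of coding is used
under: recording starts 20:00 and runs 10.5 h (observed onsets fell between
20:15 and 21:04 and offsets around 06:10–06:15); the settling routine is
lognormal with mean 20 min (the length of a typical reliability segment);
the waking rate is Poisson(5) — the mean of the three observed per-night
counts 12, 2, and 1 — with lognormal durations of mean 2 min (observed
totals of 26.0, 1.8, and 3.1 min over those counts); most wakings are
self-soothed (`p_signal = 0.3`). The distribution *families* are
conventional stand-ins, not estimates of any population: the underlying raw
coder logs are not publicly available.

`perturb_coder` models the disagreement sources seen between human coders:
independent Gaussian jitter per recorded endpoint (endpoints swapped if
jitter inverts a state, clamped to the recording window), per-event misses,
code confusion within a category (type-preserving; modifiers the new code
cannot carry are dropped), and Poisson spurious insertions. Two renditions
with independent seeds emulate two coders watching one video. With all noise
zero the rendition equals the truth exactly.

`agreement_curve` seeds each night from (scenario seed, repetition) only, so
extending the noise grid never changes earlier rows.

A useful closed form anchors the statistic: against the ground truth, a
rendition that only omits events (probability `p_miss`) has `M = N_b`, so
`PA = N_b/N_a` with expectation `(1 − p_miss)·100`. The Monte-Carlo check
uses 200 nights and a 3-standard-error band; the default suite and the
acceptance script complete in seconds at these sizes.

**What passing these tests shows — and doesn't.** The simulator exercises
timing logic, matching optimality, and the statistic's algebra under
controlled noise. It does not reproduce real coder behavior: real
disagreements are correlated (an obstructed camera view degrades whole
stretches, not independent events), code confusion is not uniform within a
category, and real nights contain behaviors outside the packaged vocabulary.
Agreement figures computed on synthetic renditions therefore validate the
software, not the coding system's field reliability.

## Rendering and reporting

Timelines are Gantt-style SVGs: one lane per category (codes colored within
a lane), state bars, point markers, a clock-time axis. SVG output is
byte-deterministic for fixed input (fixed hash salt, no embedded date), and
each event's glyph carries a stable SVG id so a glyph census equals the
event census. The report bundle writes whatever components exist — metrics
(JSON/CSV), agreement (JSON), the discrepancy table (CSV), timelines, and a
plain-text summary flagging the 70% threshold — and lists missing components
rather than failing.

## Known limitations

- The event-file dialect is a reconstruction of an aggregated-export format;
  other exporters' headers are handled via `column_map`, but project files
  and media are out of scope.
- Equal-cost alternative matchings are resolved deterministically but the
  specific resolution among exact ties is an implementation detail of the
  assignment solver.
- The simulator's settling-period activity layer is simplified (consecutive
  non-overlapping slots); it does not model concurrent multi-subject
  activity bursts.
- No chance-corrected agreement coefficients, no sleep-stage inference, no
  actigraphy fusion, and no clinical-diagnosis logic.
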