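"""Synthetic overnight coded observations and simulated coder noise.

The generator emits the behavioral skeleton the coding system assumes: a
settling routine ending at "lights out", sleep onset after a latency, sleep
segments interrupted by a Poisson number of night wakings (some signaled,
drawing the parent in; most self-soothed), movement arousals, settling-period
activities with soothing modifiers, and location states — all as one
internally consistent event stream that passes validation.

Defaults echo the kind of nights the coding system was developed on: a
recording starting at 20:00 and running ~10.5 h, a settling routine around
20 min, and waking counts/durations on the scale seen when parents' reports
were compared with observation (a handful of wakings of a couple of minutes
each). Distribution families (lognormal durations, exponential latency,
Poisson counts) are conventional stand-ins, not estimates from any
population.

Coder noise perturbs a ground-truth stream the way human coders disagree:
Gaussian timestamp jitter per endpoint, missed events, code confusion within
a category, and spurious insertions. Two independent renditions of the same
truth emulate two coders watching one video.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import MatchingConfig, agreement_between
from .errors import GenerationError
from .ethogram import (
    Ethogram,
    EventType,
    LIGHTS_OUT,
    MORNING_WAKING,
    MOVEMENT_AROUSAL,
    NIGHT_WAKING,
    SETTLING_ROUTINE,
    SLEEP,
    SLEEP_ONSET,
    Subjects,
    default_opic_ethogram,
    _canon,
)
from .events import CodedObservation, EventRecord, validate_observation

__all__ = [
    "NightScenario",
    "CoderNoise",
    "simulate_night",
    "perturb_coder",
    "agreement_curve",
]

_DEFAULT_ACTIVITY_MIX = {
    "Reading": 0.30,
    "Verbalization": 0.25,
    "Playing": 0.15,
    "Singing": 0.10,
    "Personal care": 0.10,
    "Electronics": 0.05,
    "Laughing": 0.05,
}


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Sample a lognormal parameterized by its arithmetic mean and sd."""
    if mean <= 0:
        raise GenerationError(f"lognormal mean must be positive, got {mean}")
    if sd <= 0:
        return mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


@dataclass(frozen=True)
class NightScenario:
    """Generative parameters for one synthetic night.

    Durations are minutes; ``settling_duration_min`` and
    ``waking_duration_min`` are (mean, sd) of lognormals,
    ``sleep_latency_min`` the mean of an exponential, ``n_wakings_mean`` a
    Poisson rate. ``p_signal`` is the probability a waking draws the parent
    in (the rest are self-soothed); ``soothing_bias`` the probability a
    settling activity is coded soothing.
    """

    seed: int = 0
    settling_duration_min: tuple[float, float] = (20.0, 8.0)
    sleep_latency_min: float = 15.0
    n_wakings_mean: float = 5.0
    waking_duration_min: tuple[float, float] = (2.0, 1.5)
    p_signal: float = 0.3
    activity_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ACTIVITY_MIX)
    )
    soothing_bias: float = 0.6
    movement_arousal_mean: float = 2.0
    recording_start_clock: str = "20:00:00"
    total_recording_h: float = 10.5

    def __post_init__(self) -> None:
        for p, nm in ((self.p_signal, "p_signal"), (self.soothing_bias, "soothing_bias")):
            if not (0 <= p <= 1):
                raise GenerationError(f"{nm} must be in [0, 1]")
        if self.n_wakings_mean < 0 or self.movement_arousal_mean < 0:
            raise GenerationError("event rates must be non-negative")
        if self.sleep_latency_min < 0:
            raise GenerationError("sleep_latency_min must be non-negative")
        if self.total_recording_h <= 0:
            raise GenerationError("total_recording_h must be positive")
        if min(self.settling_duration_min[0], self.waking_duration_min[0]) <= 0:
            raise GenerationError("duration means must be positive")


@dataclass(frozen=True)
class CoderNoise:
    """Simulated coder error applied to a ground-truth stream.

    ``jitter_sd_s``: independent Gaussian noise per recorded endpoint.
    ``p_miss``: per-event omission probability. ``p_confuse``: probability
    the code is swapped for another code of the same category (and type).
    ``insertion_rate_per_h``: spurious events per hour of recording.
    """

    seed: int = 0
    jitter_sd_s: float = 0.0
    p_miss: float = 0.0
    p_confuse: float = 0.0
    insertion_rate_per_h: float = 0.0

    def __post_init__(self) -> None:
        for p, nm in ((self.p_miss, "p_miss"), (self.p_confuse, "p_confuse")):
            if not (0 <= p <= 1):
                raise GenerationError(f"{nm} must be in [0, 1]")
        if self.jitter_sd_s < 0 or self.insertion_rate_per_h < 0:
            raise GenerationError("jitter sd and insertion rate must be non-negative")


def _place_nonoverlapping(
    rng: np.random.Generator,
    window: tuple[float, float],
    durations: Sequence[float],
) -> list[tuple[float, float]]:
    """Place intervals of the given lengths inside a window without overlap.

    Stick-breaking: the free time left over after the intervals is split at
    sorted uniform points and inserted as gaps, which guarantees feasibility
    whenever total duration fits.
    """
    lo, hi = window
    total = float(sum(durations))
    free = (hi - lo) - total
    if free < 0:
        raise GenerationError(
            f"cannot fit {total / 60:.1f} min of events into a "
            f"{(hi - lo) / 60:.1f} min window"
        )
    n = len(durations)
    if n == 0:
        return []
    gaps = np.sort(rng.uniform(0.0, free, size=n))
    out = []
    cursor = lo
    consumed = 0.0
    for k, d in enumerate(durations):
        start = lo + float(gaps[k]) + consumed
        out.append((start, start + d))
        consumed += d
    return out


def simulate_night(s: NightScenario, e: Ethogram | None = None) -> CodedObservation:
    """Generate one internally consistent ground-truth night.

    Deterministic given ``s.seed``. The result passes
    :func:`~opic.events.validate_observation` with no errors; a scenario
    whose wakings cannot fit in the sleep period raises GenerationError.
    """
    e = e or default_opic_ethogram()
    rng = np.random.default_rng(s.seed)
    total_s = s.total_recording_h * 3600.0

    settling_d = min(_lognormal(rng, *[m * 60 for m in s.settling_duration_min]),
                     total_s / 4.0)
    settling_d = max(settling_d, 60.0)
    latency = float(rng.exponential(s.sleep_latency_min * 60.0))
    onset = settling_d + latency
    morning = total_s - 300.0
    if onset >= morning - 600.0:
        raise GenerationError(
            f"sleep onset at {onset / 3600:.1f} h leaves no sleep period before "
            f"morning waking at {morning / 3600:.1f} h"
        )

    events: list[EventRecord] = []
    S, P = EventType.STATE, EventType.POINT

    def add(subject, code, etype, start, stop=None, modifiers=None):
        start = round(start, 3)
        stop = start if stop is None else round(stop, 3)
        events.append(EventRecord(subject, code, etype, start, stop, modifiers or {}))

    # time domains
    add("child", SETTLING_ROUTINE, S, 0.0, settling_d)
    add("child", LIGHTS_OUT, P, settling_d)
    add("child", SLEEP_ONSET, P, onset)
    add("child", MORNING_WAKING, P, morning)

    # night wakings (non-overlapping inside the sleep period)
    n_w = int(rng.poisson(s.n_wakings_mean))
    wd_mean, wd_sd = s.waking_duration_min
    durations = [max(10.0, _lognormal(rng, wd_mean * 60.0, wd_sd * 60.0))
                 for _ in range(n_w)]
    wake_window = (onset + 60.0, morning - 60.0)
    wakings = _place_nonoverlapping(rng, wake_window, durations)
    for w_start, w_stop in wakings:
        add("child", NIGHT_WAKING, S, w_start, w_stop)
        if rng.random() < s.p_signal:
            v_start = min(w_start + 10.0, w_stop - 1.0)
            add("parent", "Verbalization", S, v_start, w_stop,
                {"Helpful to sleep?": "soothing"})
            add("parent", "Brief close physical contact", P, (v_start + w_stop) / 2.0)

    # sleep segments between wakings
    cursor = onset
    for w_start, w_stop in wakings:
        if w_start > cursor:
            add("child", SLEEP, S, cursor, w_start)
        cursor = max(cursor, w_stop)
    if morning > cursor:
        add("child", SLEEP, S, cursor, morning)

    # movement arousals: brief states inside the sleep period
    n_a = int(rng.poisson(s.movement_arousal_mean))
    arousal_durs = [float(rng.uniform(15.0, 60.0)) for _ in range(n_a)]
    for a_start, a_stop in _place_nonoverlapping(rng, (onset + 30.0, morning - 30.0),
                                                 arousal_durs):
        add("child", MOVEMENT_AROUSAL, S, a_start, a_stop)

    # settling-period activities in consecutive slots (no same-code overlap)
    mix = {k: v for k, v in s.activity_mix.items() if v > 0}
    if mix:
        names = sorted(mix, key=_canon)
        weights = np.array([mix[n] for n in names], dtype=float)
        weights /= weights.sum()
        n_act = max(1, int(rng.poisson(4.0)))
        slot = settling_d / n_act
        for k in range(n_act):
            name = names[int(rng.choice(len(names), p=weights))]
            code = e.get(name)
            if code is None:
                raise GenerationError(f"activity_mix code {name!r} not in ethogram")
            u = rng.random()
            helpful = ("soothing" if u < s.soothing_bias
                       else "non-soothing" if u < (1 + s.soothing_bias) / 2
                       else "neutral")
            mods = {"Helpful to sleep?": helpful} if code.modifier_set("Helpful to sleep?") else {}
            subject = "parent" if rng.random() < 0.5 else "child"
            if code.applicable_subjects is Subjects.CHILD:
                subject = "child"
            lo, hi = k * slot, (k + 1) * slot
            if code.event_type is P:
                add(subject, name, P, float(rng.uniform(lo, hi)), modifiers=mods)
            else:
                a_start = float(rng.uniform(lo, lo + slot * 0.3))
                a_stop = float(rng.uniform(a_start + 5.0, hi))
                add(subject, name, S, a_start, min(a_stop, hi), mods)

    # location layer
    add("child", "Out of bed", S, 0.0, settling_d, {"Position": "mobile"})
    add("child", "In bed", S, settling_d, morning, {"Position": "lying"})

    obs = CodedObservation(
        observation_id=f"sim-night-{s.seed}",
        recording_start_clock=s.recording_start_clock,
        coder_id="truth",
        events=tuple(events),
        recording_duration_s=total_s,
    )
    report = validate_observation(obs, e)
    if not report.ok:
        raise GenerationError(
            "generated night failed validation: "
            + "; ".join(i.message for i in report.errors)
        )
    return obs


def perturb_coder(
    truth: CodedObservation, n: CoderNoise, e: Ethogram | None = None
) -> CodedObservation:
    """One noisy coder rendition of a ground-truth stream.

    Each event is independently dropped with ``p_miss``; surviving endpoints
    get Gaussian jitter (clamped to the recording window, endpoints swapped
    if the jitter inverts a state); the code is confused with ``p_confuse``
    for a same-category, same-type code; spurious events arrive at
    ``insertion_rate_per_h``. Deterministic given ``n.seed``; with all noise
    parameters zero the rendition equals the truth.
    """
    e = e or default_opic_ethogram()
    rng = np.random.default_rng(n.seed)
    out: list[EventRecord] = []
    T = truth.recording_duration_s

    for ev in truth.sorted_events():
        if n.p_miss > 0 and rng.random() < n.p_miss:
            continue
        start, stop = ev.start_s, ev.stop_s
        if n.jitter_sd_s > 0:
            if ev.event_type is EventType.POINT:
                start = stop = float(np.clip(start + rng.normal(0, n.jitter_sd_s), 0, T))
            else:
                start = float(np.clip(start + rng.normal(0, n.jitter_sd_s), 0, T))
                stop = float(np.clip(stop + rng.normal(0, n.jitter_sd_s), 0, T))
                if stop < start:
                    start, stop = stop, start
            start, stop = round(start, 3), round(stop, 3)
        code_name, modifiers = ev.code, dict(ev.modifiers)
        if n.p_confuse > 0 and rng.random() < n.p_confuse:
            code = e.get(ev.code)
            if code is not None:
                others = [
                    c for c in e.codes_in_category(code.category)
                    if c.event_type is code.event_type and _canon(c.name) != _canon(code.name)
                ]
                if others:
                    new_code = others[int(rng.integers(len(others)))]
                    code_name = new_code.name
                    modifiers = {
                        k: v for k, v in modifiers.items()
                        if new_code.modifier_set(k) is not None
                    }
        out.append(EventRecord(ev.subject, code_name, ev.event_type, start, stop, modifiers))

    if n.insertion_rate_per_h > 0:
        n_ins = int(rng.poisson(n.insertion_rate_per_h * T / 3600.0))
        codes = list(e.codes)
        for _ in range(n_ins):
            code = codes[int(rng.integers(len(codes)))]
            subject = {
                Subjects.CHILD: "child",
                Subjects.PARENT: "parent",
                Subjects.EITHER: "child" if rng.random() < 0.5 else "parent",
            }[code.applicable_subjects]
            start = float(rng.uniform(0, T))
            if code.event_type is EventType.POINT:
                stop = start
            else:
                stop = min(T, start + float(rng.exponential(30.0)))
            mods = {
                m.name: m.allowed_values[int(rng.integers(len(m.allowed_values)))]
                for m in code.modifier_sets
            }
            out.append(EventRecord(subject, code.name, code.event_type,
                                   round(start, 3), round(stop, 3), mods))

    obs = CodedObservation(
        observation_id=truth.observation_id,
        recording_start_clock=truth.recording_start_clock,
        coder_id=f"coder-{n.seed}",
        events=tuple(sorted(out, key=lambda ev: (ev.start_s, _canon(ev.code), ev.stop_s))),
        recording_duration_s=T,
    )
    return obs


def _derived_seed(*parts: int) -> int:
    ss = np.random.SeedSequence(list(int(p) for p in parts))
    return int(ss.generate_state(1)[0] % (2**31))


def agreement_curve(
    s: NightScenario,
    noise_grid: Sequence[CoderNoise],
    reps: int,
    cfg: MatchingConfig | None = None,
    e: Ethogram | None = None,
    versus_truth: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo mean and sd of overall agreement per noise-grid point.

    Each rep simulates a fresh night (seed derived from the scenario seed and
    rep index only, so adding grid points never changes earlier rows) and
    scores either two independent noisy renditions against each other or,
    with ``versus_truth``, one rendition against the ground truth.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = cfg or MatchingConfig()
    e = e or default_opic_ethogram()
    rows = []
    for noise in noise_grid:
        vals = []
        for rep in range(reps):
            truth = simulate_night(replace(s, seed=_derived_seed(s.seed, rep)), e)
            nb = replace(noise, seed=_derived_seed(s.seed, rep, noise.seed, 2))
            b = perturb_coder(truth, nb, e)
            if versus_truth:
                a = truth
            else:
                na = replace(noise, seed=_derived_seed(s.seed, rep, noise.seed, 1))
                a = perturb_coder(truth, na, e)
            res = agreement_between(a, b, cfg)
            if res.overall_pct is not None:
                vals.append(res.overall_pct)
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "jitter_sd_s": noise.jitter_sd_s,
                "p_miss": noise.p_miss,
                "p_confuse": noise.p_confuse,
                "insertion_rate_per_h": noise.insertion_rate_per_h,
                "reps": len(arr),
                "mean_agreement_pct": float(arr.mean()) if arr.size else float("nan"),
                "sd_agreement_pct": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
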