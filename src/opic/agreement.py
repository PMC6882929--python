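"""Inter-rater agreement via tolerance-windowed one-to-one event matching.

Two coders who watched the same footage produce two event streams. Events are
paired one-to-one when they agree exactly on code (and, by default, subject
and modifiers) and their timestamps lie within a tolerance — 5 seconds by
default, applied to the single timestamp of a point event and to *both*
endpoints of a state event.

Pairing is globally optimal: maximum cardinality first, then minimum total
timestamp cost (|Δstart| + |Δstop|), computed as a linear assignment with a
large penalty on ineligible pairs so that cardinality dominates cost. This
makes the statistic independent of event order in the files.

The modified percentage agreement is 100·M / (N_a + N_b − M): matched pairs
over distinct coded events after unification, so omissions and insertions by
either coder are penalized symmetrically. The alternative 2M/(N_a+N_b)
("mean-denominator") is available behind a config flag. Agreement of 70% or
more is conventionally regarded as sufficient for complex multi-layer coding
systems; chance-corrected coefficients such as Cohen's kappa are deliberately
out of scope because rare-but-important codes skew them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import SizeError
from .ethogram import Ethogram, EventType, _canon
from .events import CodedObservation, EventRecord

__all__ = [
    "MatchingConfig",
    "MatchedPair",
    "Matching",
    "AgreementResult",
    "eligible",
    "match_events",
    "brute_force_match",
    "percentage_agreement",
    "agreement_between",
    "NOT_ASSESSABLE",
]

NOT_ASSESSABLE = "not assessable"


@dataclass(frozen=True)
class MatchingConfig:
    """Eligibility and reporting parameters for cross-coder matching.

    tolerance_s:
        Timestamp margin in seconds (default 5). Applied per endpoint for
        state events.
    require_modifiers / require_subject:
        Whether "exact agreement" includes modifier assignments and subject.
    sufficiency_threshold_pct:
        Report-level annotation only: the conventional 70% sufficiency bar.
    mean_denominator:
        If True, report 2M/(N_a+N_b) instead of the default M/(N_a+N_b−M).
    """

    tolerance_s: float = 5.0
    require_modifiers: bool = True
    require_subject: bool = True
    sufficiency_threshold_pct: float = 70.0
    mean_denominator: bool = False

    def __post_init__(self) -> None:
        if self.tolerance_s < 0:
            raise ValueError("tolerance_s must be >= 0")
        if not (0 <= self.sufficiency_threshold_pct <= 100):
            raise ValueError("sufficiency_threshold_pct must be in [0, 100]")


def eligible(a: EventRecord, b: EventRecord, cfg: MatchingConfig) -> bool:
    """True iff two events count as "exact agreement" under the tolerance.

    Same code name (case-insensitive); same event type (a point never matches
    a state of the same code); same subject and identical modifier
    assignments if required; |Δt| within tolerance for point events, both
    |Δstart| and |Δstop| within tolerance for state events.
    """
    if _canon(a.code) != _canon(b.code):
        return False
    if a.event_type is not b.event_type:
        return False
    if cfg.require_subject and _canon(a.subject) != _canon(b.subject):
        return False
    if cfg.require_modifiers:
        ma = {_canon(k): _canon(v) for k, v in a.modifiers.items()}
        mb = {_canon(k): _canon(v) for k, v in b.modifiers.items()}
        if ma != mb:
            return False
    if abs(a.start_s - b.start_s) > cfg.tolerance_s:
        return False
    if a.event_type is EventType.STATE and abs(a.stop_s - b.stop_s) > cfg.tolerance_s:
        return False
    return True


def _pair_cost(a: EventRecord, b: EventRecord) -> float:
    return abs(a.start_s - b.start_s) + abs(a.stop_s - b.stop_s)


@dataclass(frozen=True)
class MatchedPair:
    a: EventRecord
    b: EventRecord
    cost: float  # |Δstart| + |Δstop| in seconds


@dataclass(frozen=True)
class Matching:
    """A one-to-one pairing of two coders' events plus the leftovers."""

    pairs: tuple[MatchedPair, ...]
    unmatched_a: tuple[EventRecord, ...]
    unmatched_b: tuple[EventRecord, ...]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def total_cost(self) -> float:
        return sum(p.cost for p in self.pairs)


def _sorted_events(obs: CodedObservation) -> list[EventRecord]:
    # deterministic processing order: earliest start, then code name
    return sorted(
        obs.events, key=lambda e: (e.start_s, _canon(e.code), e.stop_s, e.subject)
    )


def match_events(
    a: CodedObservation, b: CodedObservation, cfg: MatchingConfig | None = None
) -> Matching:
    """Maximum-cardinality, then minimum-cost one-to-one event matching.

    Solved as a rectangular linear assignment over the eligibility graph with
    ineligible pairs priced above any feasible total cost, so the assignment
    first maximizes the number of eligible pairs and then minimizes the sum
    of timestamp offsets. Deterministic: events are processed in
    (start time, code name) order.
    """
    cfg = cfg or MatchingConfig()
    ev_a = _sorted_events(a)
    ev_b = _sorted_events(b)
    if not ev_a or not ev_b:
        return Matching(pairs=(), unmatched_a=tuple(ev_a), unmatched_b=tuple(ev_b))

    cost = np.full((len(ev_a), len(ev_b)), np.inf)
    any_edge = False
    for i, ea in enumerate(ev_a):
        for j, eb in enumerate(ev_b):
            if eligible(ea, eb, cfg):
                cost[i, j] = _pair_cost(ea, eb)
                any_edge = True
    if not any_edge:
        return Matching(pairs=(), unmatched_a=tuple(ev_a), unmatched_b=tuple(ev_b))

    # Penalty exceeding any feasible total cost: each eligible pair costs at
    # most 2*tolerance, and at most min(n_a, n_b) pairs can be matched.
    big = 2.0 * cfg.tolerance_s * min(len(ev_a), len(ev_b)) + 1.0
    penalized = np.where(np.isinf(cost), big, cost)
    rows, cols = linear_sum_assignment(penalized)

    pairs = []
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    for i, j in zip(rows, cols):
        if np.isfinite(cost[i, j]):
            pairs.append(MatchedPair(ev_a[i], ev_b[j], float(cost[i, j])))
            matched_a.add(i)
            matched_b.add(j)
    return Matching(
        pairs=tuple(pairs),
        unmatched_a=tuple(e for i, e in enumerate(ev_a) if i not in matched_a),
        unmatched_b=tuple(e for j, e in enumerate(ev_b) if j not in matched_b),
    )


def brute_force_match(
    a: CodedObservation, b: CodedObservation, cfg: MatchingConfig | None = None
) -> Matching:
    """Exhaustive-search oracle: enumerate every one-to-one matching on the
    eligibility graph and keep the max-cardinality, min-cost one.

    Only for tiny instances (n_a × n_b ≤ 64); raises SizeError beyond that.
    """
    cfg = cfg or MatchingConfig()
    ev_a = _sorted_events(a)
    ev_b = _sorted_events(b)
    if len(ev_a) * len(ev_b) > 64:
        raise SizeError(
            f"instance {len(ev_a)}×{len(ev_b)} too large for exhaustive search"
        )

    edges = {
        i: [j for j, eb in enumerate(ev_b) if eligible(ea, eb, cfg)]
        for i, ea in enumerate(ev_a)
    }

    best: tuple[int, float, list[tuple[int, int]]] = (0, 0.0, [])

    def recurse(i: int, used_b: set[int], chosen: list[tuple[int, int]], cost: float) -> None:
        nonlocal best
        if i == len(ev_a):
            cand = (len(chosen), cost)
            if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = (len(chosen), cost, list(chosen))
            return
        recurse(i + 1, used_b, chosen, cost)  # leave event i unmatched
        for j in edges[i]:
            if j not in used_b:
                chosen.append((i, j))
                used_b.add(j)
                recurse(i + 1, used_b, chosen, cost + _pair_cost(ev_a[i], ev_b[j]))
                used_b.discard(j)
                chosen.pop()

    recurse(0, set(), [], 0.0)
    _, _, chosen = best
    matched_a = {i for i, _ in chosen}
    matched_b = {j for _, j in chosen}
    return Matching(
        pairs=tuple(
            MatchedPair(ev_a[i], ev_b[j], _pair_cost(ev_a[i], ev_b[j]))
            for i, j in chosen
        ),
        unmatched_a=tuple(e for i, e in enumerate(ev_a) if i not in matched_a),
        unmatched_b=tuple(e for j, e in enumerate(ev_b) if j not in matched_b),
    )


@dataclass(frozen=True)
class AgreementResult:
    """Overall and per-category modified percentage agreement."""

    n_a: int
    n_b: int
    n_matched: int
    overall_pct: float | None  # None when not assessable (both coders empty)
    per_category_pct: Mapping[str, float | str] = field(default_factory=dict)
    meets_threshold: bool = False
    threshold_pct: float = 70.0
    denominator: str = "union"  # "union": M/(Na+Nb-M); "mean": 2M/(Na+Nb)

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_matched": self.n_matched,
            "overall_pct": self.overall_pct if self.overall_pct is not None else NOT_ASSESSABLE,
            "per_category_pct": dict(self.per_category_pct),
            "meets_threshold": self.meets_threshold,
            "threshold_pct": self.threshold_pct,
            "denominator": self.denominator,
        }


def _pct(m: int, n_a: int, n_b: int, mean_denominator: bool) -> float | None:
    if n_a == 0 and n_b == 0:
        return None
    if mean_denominator:
        return 100.0 * 2 * m / (n_a + n_b)
    return 100.0 * m / (n_a + n_b - m)


def percentage_agreement(
    m: Matching,
    per_category: bool = True,
    *,
    ethogram: Ethogram | None = None,
    cfg: MatchingConfig | None = None,
) -> AgreementResult:
    """Modified percentage agreement for a computed matching.

    Overall: 100·M/(N_a+N_b−M) (each agreed event counted once in the
    denominator), or 100·2M/(N_a+N_b) when the config selects the mean
    denominator. Per-category values are computed on category-restricted
    event sets (requires an ethogram to map codes to categories); a category
    with no events from either coder is reported "not assessable", never 0
    or 100. Two empty observations yield a not-assessable overall result.
    """
    cfg = cfg or MatchingConfig()
    events_a = [p.a for p in m.pairs] + list(m.unmatched_a)
    events_b = [p.b for p in m.pairs] + list(m.unmatched_b)
    n_a, n_b, n_m = len(events_a), len(events_b), m.n_matched
    overall = _pct(n_m, n_a, n_b, cfg.mean_denominator)

    per_cat: dict[str, float | str] = {}
    if per_category and ethogram is not None:
        def cat_of(ev: EventRecord) -> str | None:
            code = ethogram.get(ev.code)
            return code.category if code else None

        for category in ethogram.categories:
            ca = sum(1 for e in events_a if cat_of(e) == category)
            cb = sum(1 for e in events_b if cat_of(e) == category)
            cm = sum(1 for p in m.pairs if cat_of(p.a) == category)
            pct = _pct(cm, ca, cb, cfg.mean_denominator)
            per_cat[category] = NOT_ASSESSABLE if pct is None else pct

    return AgreementResult(
        n_a=n_a,
        n_b=n_b,
        n_matched=n_m,
        overall_pct=overall,
        per_category_pct=per_cat,
        meets_threshold=(overall is not None and overall >= cfg.sufficiency_threshold_pct),
        threshold_pct=cfg.sufficiency_threshold_pct,
        denominator="mean" if cfg.mean_denominator else "union",
    )


def agreement_between(
    a: CodedObservation,
    b: CodedObservation,
    cfg: MatchingConfig | None = None,
    ethogram: Ethogram | None = None,
) -> AgreementResult:
    """Convenience: match two observations and score the agreement."""
    cfg = cfg or MatchingConfig()
    return percentage_agreement(
        match_events(a, b, cfg), per_category=ethogram is not None,
        ethogram=ethogram, cfg=cfg,
    )
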