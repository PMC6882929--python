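"""Tolerance-windowed event matching and the modified percentage agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opic import (
    CodedObservation,
    EventRecord,
    EventType,
    MatchingConfig,
    SizeError,
    agreement_between,
    brute_force_match,
    eligible,
    match_events,
    percentage_agreement,
)

S, P = EventType.STATE, EventType.POINT


def obs(events, coder="A"):
    return CodedObservation("x", "20:00:00", coder, tuple(events), 90000.0)


def ev(code, start, stop=None, subject="child", etype=None, mods=None):
    if stop is None:
        stop, etype = start, etype or P
    else:
        etype = etype or S
    return EventRecord(subject, code, etype, start, stop, mods or {})


CFG = MatchingConfig()


class TestEligible:
    def test_within_margin_both_endpoints(self):
        a = ev("Sleep", 100.0, 200.0)
        b = ev("Sleep", 103.0, 198.0)
        assert eligible(a, b, CFG)

    def test_start_beyond_margin(self):
        assert not eligible(ev("Sleep", 100.0, 200.0), ev("Sleep", 106.0, 200.0), CFG)

    def test_stop_beyond_margin(self):
        assert not eligible(ev("Sleep", 100.0, 200.0), ev("Sleep", 100.0, 206.0), CFG)

    def test_different_codes_never_match(self):
        assert not eligible(ev("Sleep", 100.0, 200.0), ev("Night waking", 100.0, 200.0), CFG)

    def test_point_never_matches_state(self):
        assert not eligible(ev("Laughing", 100.0), ev("Laughing", 100.0, 100.0, etype=S), CFG)

    def test_subject_and_modifier_requirements_relaxable(self):
        a = ev("Reading", 0.0, 60.0, subject="parent",
               mods={"Helpful to sleep?": "soothing"})
        b = ev("Reading", 0.0, 60.0, subject="child",
               mods={"Helpful to sleep?": "neutral"})
        assert not eligible(a, b, CFG)
        relaxed = MatchingConfig(require_subject=False, require_modifiers=False)
        assert eligible(a, b, relaxed)

    def test_boundary_exactly_at_tolerance(self):
        assert eligible(ev("Lights out", 0.0), ev("Lights out", 5.0), CFG)


class TestMatchEvents:
    def test_identical_observations_fully_matched(self):
        events = [ev("Sleep", 0.0, 100.0), ev("Lights out", 50.0),
                  ev("Night waking", 200.0, 300.0)]
        m = match_events(obs(events), obs(events, "B"), CFG)
        assert m.n_matched == 3
        assert m.total_cost == 0.0
        assert not m.unmatched_a and not m.unmatched_b

    def test_min_cost_partner_chosen(self):
        """One event in A, two eligible partners in B: the closer one wins."""
        a = obs([ev("Lights out", 10.0)])
        b = obs([ev("Lights out", 14.0), ev("Lights out", 14.5)], "B")
        m = match_events(a, b, CFG)
        assert m.n_matched == 1
        assert m.pairs[0].b.start_s == 14.0
        # a point's offset counts at both endpoints: cost = 2 x 4 s
        assert m.total_cost == pytest.approx(8.0)

    def test_chain_beats_greedy_nearest(self):
        """A={0, 4}, B={4, 8}: greedy-nearest pairs 4-4 and strands the rest;
        the optimal matching pairs 0-4 and 4-8 for cardinality 2."""
        a = obs([ev("Lights out", 0.0), ev("Lights out", 4.0)])
        b = obs([ev("Lights out", 4.0), ev("Lights out", 8.0)], "B")
        m = match_events(a, b, CFG)
        assert m.n_matched == 2
        ref = brute_force_match(a, b, CFG)
        assert ref.n_matched == 2
        assert m.total_cost == pytest.approx(ref.total_cost) == pytest.approx(16.0)

    def test_empty_inputs(self):
        m = match_events(obs([]), obs([]), CFG)
        assert m.n_matched == 0

    def test_disjoint_codes_empty_matching(self):
        m = match_events(obs([ev("Sleep", 0.0, 10.0)]),
                         obs([ev("Night waking", 0.0, 10.0)], "B"), CFG)
        assert m.n_matched == 0
        assert len(m.unmatched_a) == len(m.unmatched_b) == 1

    def test_brute_force_size_guard(self):
        events = [ev("Lights out", float(i * 100)) for i in range(9)]
        with pytest.raises(SizeError):
            brute_force_match(obs(events), obs(events, "B"), CFG)


class TestOracleEquivalence:
    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_search(self, seed):
        """Randomized small instances: the assignment solver agrees with the
        exhaustive oracle in both cardinality and total cost."""
        rng = np.random.default_rng(seed)
        codes = ["Lights out", "Sleep onset", "Laughing"]

        def random_obs(coder):
            events = [
                ev(codes[rng.integers(len(codes))],
                   round(float(rng.uniform(0, 40)), 1))
                for _ in range(rng.integers(0, 9))
            ]
            return obs(events, coder)

        a, b = random_obs("A"), random_obs("B")
        fast = match_events(a, b, CFG)
        slow = brute_force_match(a, b, CFG)
        assert fast.n_matched == slow.n_matched
        assert fast.total_cost == pytest.approx(slow.total_cost)


class TestPercentageAgreement:
    def test_full_agreement_is_100(self):
        events = [ev("Lights out", float(i * 100)) for i in range(10)]
        res = agreement_between(obs(events), obs(events, "B"))
        assert res.overall_pct == 100.0
        assert res.meets_threshold

    def test_three_three_two_gives_50(self):
        """N_a = N_b = 3 with 2 matched: 100 x 2/(3+3-2) = 50%."""
        a = obs([ev("Lights out", 0.0), ev("Lights out", 100.0),
                 ev("Lights out", 200.0)])
        b = obs([ev("Lights out", 1.0), ev("Lights out", 101.0),
                 ev("Lights out", 500.0)], "B")
        res = agreement_between(a, b)
        assert res.n_matched == 2
        assert res.overall_pct == pytest.approx(50.0)
        assert not res.meets_threshold

    def test_no_matches_is_0(self):
        a = obs([ev("Lights out", float(i * 1000)) for i in range(5)])
        b = obs([ev("Lights out", float(i * 1000 + 500)) for i in range(5)], "B")
        res = agreement_between(a, b)
        assert res.overall_pct == 0.0

    def test_both_empty_not_assessable(self):
        res = agreement_between(obs([]), obs([], "B"))
        assert res.overall_pct is None
        assert not res.meets_threshold

    def test_mean_denominator_variant(self):
        a = obs([ev("Lights out", 0.0), ev("Lights out", 100.0),
                 ev("Lights out", 200.0)])
        b = obs([ev("Lights out", 1.0), ev("Lights out", 101.0),
                 ev("Lights out", 500.0)], "B")
        res = agreement_between(a, b, MatchingConfig(mean_denominator=True))
        assert res.overall_pct == pytest.approx(100.0 * 4 / 6)

    def test_per_category_and_not_assessable(self, ethogram):
        a = obs([ev("Lights out", 0.0), ev("Sleep", 10.0, 100.0)])
        b = obs([ev("Lights out", 2.0), ev("Night waking", 10.0, 100.0)], "B")
        res = agreement_between(a, b, ethogram=ethogram)
        assert res.per_category_pct["Time domains"] == 100.0
        assert res.per_category_pct["Child global state"] == 0.0
        assert res.per_category_pct["Physical environment"] == "not assessable"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)

        def random_obs(coder):
            return obs([ev("Lights out", round(float(rng.uniform(0, 50)), 1))
                        for _ in range(rng.integers(1, 8))], coder)

        a, b = random_obs("A"), random_obs("B")
        assert agreement_between(a, b).overall_pct == pytest.approx(
            agreement_between(b, a).overall_pct)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        a = obs([ev("Lights out", round(float(rng.uniform(0, 60)), 1))
                 for _ in range(6)])
        b = obs([ev("Lights out", round(float(rng.uniform(0, 60)), 1))
                 for _ in range(6)], "B")
        pcts = [agreement_between(a, b, MatchingConfig(tolerance_s=tol)).overall_pct
                for tol in (0.0, 2.0, 5.0, 10.0, 30.0)]
        assert all(x <= y + 1e-9 for x, y in zip(pcts, pcts[1:]))

    def test_unbalanced_counts_bound(self):
        """When every event of the smaller set matches, agreement equals
        min/max of the two counts (insertions still penalized)."""
        a = obs([ev("Lights out", float(i * 100)) for i in range(4)])
        b = obs([ev("Lights out", float(i * 100)) for i in range(8)], "B")
        res = agreement_between(a, b)
        assert res.n_matched == 4
        assert res.overall_pct == pytest.approx(100.0 * 4 / 8)
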