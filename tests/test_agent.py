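"""Agent state machine: controllers, Markov dynamics, blinks, determinism."""

import numpy as np
import pytest

from socialgaze.agent import (
    STRAIGHT,
    AgentParams,
    BlinkConfig,
    ConfigError,
    Dwell,
    MacroState,
    MicroState,
    blink_overlay,
    default_macro,
    ija_controller,
    markov_controller,
    rja_controller,
    run_block,
)
from socialgaze.defaults import OO_TRANSITIONS, AOI_LABELS
from socialgaze.distributions import DurationDistribution

D = DurationDistribution


def spans_cover_block(log):
    spans = log.spans()
    assert spans[0][0] == 0
    assert spans[-1][1] == log.duration
    for (a0, a1, _), (b0, b1, _) in zip(spans, spans[1:]):
        assert a1 == b0  # gapless, no overlap


class TestRunBlock:
    def test_timeline_closure(self):
        log = run_block(default_macro("OO"), None, 30_000, seed=1)
        spans_cover_block(log)

    def test_single_micro_state_self_loop(self):
        micro = MicroState("only", "O1", D("norm", 500.0, 50.0), {"only": 1.0})
        macro = MacroState("OO", {"only": micro}, "only")
        log = run_block(macro, None, 10_000, seed=2)
        assert {e.micro_state for e in log.events} == {"only"}
        spans_cover_block(log)

    def test_po_state_prefers_partner_gaze(self):
        """Under the partner-oriented defaults the agent spends more time
        gazing straight than at any single object."""
        macro = default_macro("PO")
        shares: dict[str, float] = {}
        for b in range(60):
            log = run_block(macro, None, 30_000, seed=1000 + b)
            for onset, end, ev in log.spans():
                shares[ev.gaze_target] = shares.get(ev.gaze_target, 0) + (end - onset)
        straight = shares.get(STRAIGHT, 0)
        assert all(straight > shares.get(o, 0) for o in ("O1", "O2", "O3", "O4"))

    def test_determinism(self):
        m = default_macro("OO")
        a = run_block(m, None, 30_000, seed=99)
        b = run_block(m, None, 30_000, seed=99)
        assert a == b

    def test_invalid_duration(self):
        with pytest.raises(ConfigError):
            run_block(default_macro("OO"), None, 0, seed=1)


class TestMarkovController:
    def test_deterministic_row(self, rng):
        macro = default_macro("OO")
        o1 = macro.micro_states["O1"]
        forced = MicroState("f", "O1", o1.duration_dist, {"O2": 1.0})
        macro2 = MacroState("OO", {**macro.micro_states, "f": forced}, "f")
        succ, dur = markov_controller(forced, macro2, rng)
        assert succ.id == "O2" and dur >= 1

    def test_all_zero_row_rejected(self, rng):
        with pytest.raises(ConfigError):
            micro = MicroState("dead", "O1", D("norm", 500.0, 1.0), {})
            markov_controller(micro, default_macro("OO"), rng)

    def test_symmetric_chain_occupancy(self, rng):
        dist = D("norm", 100.0, 1.0)
        a = MicroState("a", "O1", dist, {"b": 0.5, "a": 0.5})
        b = MicroState("b", "O2", dist, {"a": 0.5, "b": 0.5})
        macro = MacroState("OO", {"a": a, "b": b}, "a")
        counts = {"a": 0, "b": 0}
        cur = a
        for _ in range(100_000):
            cur, _d = markov_controller(cur, macro, rng)
            counts[cur.id] += 1
        assert abs(counts["a"] / 100_000 - 0.5) < 0.01

    def test_oo_row_frequencies(self, rng):
        """Transitions out of the left object follow the configured row."""
        macro = default_macro("OO")
        o1 = macro.micro_states["O1"]
        n = 100_000
        to_o2 = 0
        for _ in range(n):
            succ, _d = markov_controller(o1, macro, rng)
            to_o2 += succ.id == "O2"
        expected = OO_TRANSITIONS[0, 1]
        assert abs(to_o2 / n - expected) < 0.01


class TestRJAController:
    def make(self, pf):
        return default_macro("RJA", follow_probability=pf)

    def bids(self, n, spacing=5000, target="O1"):
        return [Dwell(target, spacing * (i + 1), spacing * (i + 1) + 1000)
                for i in range(n)]

    def follow_count(self, log):
        return sum(1 for e in log.events if e.cause == "follow")

    def test_always_follows(self, rng):
        log = rja_controller(self.make(1.0), self.bids(50), 60 * 5000, rng)
        assert self.follow_count(log) == 50

    def test_never_follows(self, rng):
        log = rja_controller(self.make(0.0), self.bids(50), 60 * 5000, rng)
        assert self.follow_count(log) == 0

    def test_low_probability_gating(self, rng):
        n = 10_000
        log = rja_controller(self.make(0.33), self.bids(n), (n + 2) * 5000, rng)
        assert abs(self.follow_count(log) / n - 0.33) < 0.02

    def test_no_spontaneous_object_gaze(self, rng):
        """With certain following, every agent object gaze is preceded by a
        human dwell onset on that object."""
        bids = self.bids(30, spacing=4000)
        log = rja_controller(self.make(1.0), bids, 35 * 4000, rng)
        onsets = {(d.target, d.onset) for d in bids}
        for ev in log.events:
            if ev.gaze_target.startswith("O"):
                assert any(t == ev.gaze_target and on < ev.onset for t, on in onsets)

    def test_rearming_ignores_mid_dwell_bids(self):
        """A bid arriving while the agent is still following is not queued."""
        macro = default_macro(
            "RJA", params=AgentParams(
                d_follow=D("norm", 100.0, 1e-6),
                d_object=D("norm", 3000.0, 1e-6),
                follow_probability=1.0))
        bids = [Dwell("O1", 1000, 1500), Dwell("O2", 2000, 2500)]
        log = rja_controller(macro, bids, 10_000, np.random.default_rng(0))
        followed = [e.gaze_target for e in log.events if e.cause == "follow"]
        assert followed == ["O1"]


class TestIJAController:
    def make(self, **kw):
        params = AgentParams(
            d_straight=D("norm", 500.0, 1e-6),
            d_object=D("norm", 600.0, 1e-6),
            **kw)
        return default_macro("IJA", params=params)

    def test_responsive_human_all_success(self, rng):
        def policy(shift_t, target, prng):
            return Dwell(target, shift_t + 450, shift_t + 1450)

        log = ija_controller(self.make(), policy, 120_000, rng)
        causes = [e.cause for e in log.events if e.cause in ("ja_success", "no_ja")]
        assert causes and set(causes) == {"ja_success"}

    def test_unresponsive_human_all_failure(self, rng):
        log = ija_controller(self.make(), None, 120_000, rng)
        causes = [e.cause for e in log.events if e.cause in ("ja_success", "no_ja")]
        assert causes and set(causes) == {"no_ja"}

    def test_probabilistic_human_success_rate(self, rng):
        def policy(shift_t, target, prng):
            if prng.random() < 0.85:
                return Dwell(target, shift_t + 450, shift_t + 1450)
            return None

        log = ija_controller(self.make(), policy, 4_000_000, rng)
        causes = [e.cause for e in log.events if e.cause in ("ja_success", "no_ja")]
        n = len(causes)
        frac = sum(c == "ja_success" for c in causes) / n
        assert n >= 1000
        assert abs(frac - 0.85) < 0.03

    def test_object_choice_uses_weights(self, rng):
        macro = self.make(object_weights={"O3": 1.0})
        log = ija_controller(macro, None, 60_000, rng)
        targets = {e.gaze_target for e in log.events if e.cause == "ija_bid"}
        assert targets == {"O3"}


class TestBlinkOverlay:
    def test_disabled_returns_log_unchanged(self):
        log = run_block(default_macro("PO"), None, 30_000, seed=4)
        assert blink_overlay(log, None, seed=1) is log
        assert blink_overlay(log, BlinkConfig(enabled=False), seed=1) is log

    def test_closed_segments_are_100ms(self):
        log = run_block(default_macro("PO"), None, 120_000, seed=4)
        out = blink_overlay(log, BlinkConfig(), seed=5)
        assert out.blinks and all(b1 - b0 == 100 for b0, b1 in out.blinks)
        assert out.events == log.events  # micro-state clock untouched

    def test_blink_rate_matches_renewal_mean(self):
        minutes = 60
        log = run_block(default_macro("PO"), None, minutes * 60_000, seed=4)
        out = blink_overlay(log, BlinkConfig(), seed=6)
        per_min = len(out.blinks) / minutes
        assert abs(per_min - 60_000 / 3529) < 1.0

    def test_overlapping_blink_config_rejected(self):
        log = run_block(default_macro("PO"), None, 30_000, seed=4)
        cfg = BlinkConfig(interval=D("norm", 150.0, 1.0))
        with pytest.raises(ConfigError):
            blink_overlay(log, cfg, seed=1)


def test_unknown_aoi_reference_rejected(rng):
    macro = default_macro("RJA")
    with pytest.raises(ConfigError):
        rja_controller(macro, [Dwell("Q7", 100, 600)], 10_000, rng)


def test_macro_validation():
    dist = D("norm", 100.0, 1.0)
    with pytest.raises(ConfigError):
        MacroState("OO", {"a": MicroState("a", "O1", dist, {"missing": 1.0})}, "a")
    with pytest.raises(ConfigError):
        MicroState("a", "O1", dist, {"a": 0.5})  # row does not sum to 1
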