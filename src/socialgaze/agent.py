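"""Event-driven simulation of the virtual agent's social-gaze state machine.

The agent's behaviour is organised in two layers. A *macro state* is a
persistent behavioural mode — initiating joint attention (IJA), responding
to joint attention (RJA), or one of three non-interactive modes: partner-
oriented (PO), object-oriented (OO) and introspective (INT). Each macro
state is realised as a stochastic sequence of *micro states*: atomic gaze
directions with a duration law, transition probabilities and, for the
interactive states, gaze-contingent triggers.

Non-interactive macro states advance by a first-order Markov chain over
micro states; the interactive states couple to the human's gaze stream:

* RJA — when the human's dwell starts on an object, the agent follows with
  probability ``follow_probability`` after a reaction-time draw, dwells on
  the object, and only then re-arms (bids arriving mid-follow are ignored).
* IJA — the agent waits for eye contact (or a maximum wait), dwells briefly,
  then shifts to an object chosen by weight; the bid succeeds if the human's
  dwell on that object starts within the response window.

Eye blinks are superimposed on any event log as 100 ms closed-eye segments
drawn from a renewal process; they overlay the display only and do not
perturb the underlying micro-state clock.

Time is integer milliseconds throughout and every draw comes from a single
seeded generator, so identical seeds and inputs give identical logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .defaults import (
    AGENT_AOI,
    AOI_LABELS,
    DEFAULT_BLINK_INTERVAL,
    DEFAULT_TIMING,
    INT_LABELS,
    INT_TRANSITIONS,
    OBJECT_AOIS,
    OFF_TARGET,
    OO_TRANSITIONS,
    PF_RJA_HIGH,
    PF_RJA_LOW,
    PO_TRANSITIONS,
)
from .distributions import DurationDistribution

__all__ = [
    "ConfigError",
    "Dwell",
    "GazeTrigger",
    "MicroState",
    "BlinkConfig",
    "AgentParams",
    "MacroState",
    "AgentEvent",
    "AgentEventLog",
    "markov_controller",
    "rja_controller",
    "ija_controller",
    "run_block",
    "blink_overlay",
    "default_macro",
]

#: Special (non-AOI) gaze targets of the agent.
STRAIGHT = "STRAIGHT"
DOWN = "DOWN"
CLOSED = "CLOSED"


class ConfigError(ValueError):
    """Raised for unresolvable or inconsistent agent configuration."""


class Dwell(NamedTuple):
    """A human gaze dwell: target AOI label with onset/offset in ms."""

    target: str
    onset: int
    offset: int

    @property
    def duration(self) -> int:
        return self.offset - self.onset


@dataclass(frozen=True)
class GazeTrigger:
    """Gaze-contingent exit from a micro state: when the human's gaze enters
    one of the watched AOIs (or makes eye contact), fire with a probability
    after a delay, moving to the action micro state."""

    watched: frozenset[str]
    fire_probability: float
    action: str
    delay_dist: DurationDistribution | None = None
    window: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fire_probability <= 1.0):
            raise ConfigError(f"fire_probability must be in [0,1], got {self.fire_probability}")
        if self.window is not None and not self.window > 0:
            raise ConfigError(f"window must be > 0 when present, got {self.window}")


@dataclass(frozen=True)
class MicroState:
    """Atomic behavioural unit: one gaze direction with a duration law,
    transition probabilities over successors, and optional triggers."""

    id: str
    gaze_target: str
    duration_dist: DurationDistribution
    transitions: dict[str, float] = field(default_factory=dict)
    triggers: tuple[GazeTrigger, ...] = ()

    def __post_init__(self) -> None:
        if self.transitions:
            total = sum(self.transitions.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"micro state {self.id!r}: transition row sums to {total}, not 1")


@dataclass(frozen=True)
class BlinkConfig:
    """Renewal-process eye blinks: closed-eye segments of ``closed_ms``
    at onset-to-onset intervals drawn from ``interval``."""

    interval: DurationDistribution | None = DEFAULT_BLINK_INTERVAL
    closed_ms: int = 100
    enabled: bool = True


@dataclass(frozen=True)
class AgentParams:
    """Agent-side timing laws and probabilities (the agent's d-parameters).

    Defaults mirror the measured human laws, since the original a-priori
    agent values are not public; everything is config-overridable.
    """

    d_straight: DurationDistribution = DEFAULT_TIMING["t_straight_IJA"]
    d_follow: DurationDistribution = DEFAULT_TIMING["t_follow_RJA"]
    d_object: DurationDistribution = DEFAULT_TIMING["t_object_RJA"]
    follow_probability: float = PF_RJA_HIGH
    object_weights: dict[str, float] | None = None
    response_window: int = 2000
    no_ja_timeout: int = 2000
    max_contact_wait: int = 5000
    blink: BlinkConfig | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.follow_probability <= 1.0):
            raise ConfigError("follow_probability must be in [0,1]")
        if self.object_weights is not None:
            if not self.object_weights or any(w < 0 for w in self.object_weights.values()):
                raise ConfigError("object_weights must be non-empty and non-negative")

    def objects(self) -> tuple[str, ...]:
        if self.object_weights:
            return tuple(self.object_weights)
        return OBJECT_AOIS

    def weights(self) -> np.ndarray:
        objs = self.objects()
        if self.object_weights:
            w = np.array([self.object_weights[o] for o in objs], dtype=float)
        else:
            w = np.ones(len(objs))
        return w / w.sum()


@dataclass(frozen=True)
class MacroState:
    """A macro state: its micro-state graph plus the agent-side parameters."""

    id: str
    micro_states: dict[str, MicroState]
    entry: str
    params: AgentParams = AgentParams()

    def __post_init__(self) -> None:
        if self.entry not in self.micro_states:
            raise ConfigError(f"entry {self.entry!r} not among micro states")
        for ms in self.micro_states.values():
            for succ in ms.transitions:
                if succ not in self.micro_states:
                    raise ConfigError(
                        f"micro state {ms.id!r} transitions to unknown {succ!r}")
            for trig in ms.triggers:
                if trig.action not in self.micro_states:
                    raise ConfigError(
                        f"trigger on {ms.id!r} targets unknown {trig.action!r}")


@dataclass(frozen=True)
class AgentEvent:
    """One segment of the agent timeline; it lasts until the next event's onset."""

    onset: int
    micro_state: str
    gaze_target: str
    macro_state: str
    cause: str = ""


@dataclass(frozen=True)
class AgentEventLog:
    """Gapless agent timeline over [0, duration) plus superimposed blinks."""

    duration: int
    events: tuple[AgentEvent, ...]
    blinks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.events:
            raise ConfigError("event log must contain at least one event")
        if self.events[0].onset != 0:
            raise ConfigError("timeline must start at 0")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ConfigError("event onsets must be strictly increasing")
        if onsets[-1] >= self.duration:
            raise ConfigError("last event onset must precede the block end")

    def spans(self) -> list[tuple[int, int, AgentEvent]]:
        """(onset, offset, event) triples; offsets chain gaplessly to ``duration``."""
        out = []
        for i, ev in enumerate(self.events):
            end = self.events[i + 1].onset if i + 1 < len(self.events) else self.duration
            out.append((ev.onset, end, ev))
        return out

    def gaze_at(self, t: int) -> str:
        """Displayed gaze target at time t (CLOSED during a blink)."""
        for b0, b1 in self.blinks:
            if b0 <= t < b1:
                return CLOSED
        target = self.events[0].gaze_target
        for ev in self.events:
            if ev.onset <= t:
                target = ev.gaze_target
            else:
                break
        return target

    def shifts_to_objects(self) -> list[tuple[int, str]]:
        """Onsets of gaze shifts toward object AOIs (bid/follow onsets)."""
        return [(e.onset, e.gaze_target) for e in self.events
                if e.gaze_target not in (STRAIGHT, DOWN, CLOSED, AGENT_AOI)]


def _draw_ms(dist: DurationDistribution, rng: np.random.Generator) -> int:
    return max(1, int(round(dist.sample_one(rng))))


def markov_controller(
    micro: MicroState, macro: MacroState, rng: np.random.Generator
) -> tuple[MicroState, int]:
    """Draw the successor micro state from the current transition row and a
    duration from the successor's law (non-interactive macro states)."""
    row = micro.transitions
    if not row or all(p <= 0 for p in row.values()):
        raise ConfigError(f"micro state {micro.id!r} has no usable transition row")
    ids = list(row)
    probs = np.array([row[i] for i in ids], dtype=float)
    probs = probs / probs.sum()
    succ_id = ids[int(rng.choice(len(ids), p=probs))]
    succ = macro.micro_states[succ_id]
    return succ, _draw_ms(succ.duration_dist, rng)


def _run_markov(macro: MacroState, duration: int, rng: np.random.Generator) -> AgentEventLog:
    entry = macro.micro_states[macro.entry]
    events = [AgentEvent(0, entry.id, entry.gaze_target, macro.id, "entry")]
    t = _draw_ms(entry.duration_dist, rng)
    cur = entry
    while t < duration:
        cur, dur = markov_controller(cur, macro, rng)
        events.append(AgentEvent(t, cur.id, cur.gaze_target, macro.id, "markov"))
        t += dur
    return AgentEventLog(duration=duration, events=tuple(events))


def rja_controller(
    macro: MacroState,
    human_dwells: Sequence[Dwell],
    duration: int,
    rng: np.random.Generator,
) -> AgentEventLog:
    """Responding-to-joint-attention agent over a human dwell stream.

    Each human dwell onset on an object is a bid: while armed, the agent
    follows with probability ``follow_probability`` after a reaction-time
    draw, dwells on the object, then returns to straight gaze and re-arms.
    Bids arriving mid-follow or mid-dwell are ignored (not queued).
    """
    p = macro.params
    objects = set(p.objects())
    events = [AgentEvent(0, "straight", STRAIGHT, macro.id, "entry")]
    ready = 0
    for d in sorted(human_dwells, key=lambda d: d.onset):
        if d.onset >= duration:
            break
        if d.target not in objects:
            if d.target not in AOI_LABELS and d.target != OFF_TARGET:
                raise ConfigError(f"unresolvable human gaze target {d.target!r}")
            continue
        if d.onset < ready:
            continue  # not yet re-armed
        if rng.random() >= p.follow_probability:
            continue  # bid not taken
        t_shift = d.onset + _draw_ms(p.d_follow, rng)
        if t_shift >= duration:
            break
        events.append(AgentEvent(t_shift, "follow", d.target, macro.id, "follow"))
        t_back = t_shift + _draw_ms(p.d_object, rng)
        if t_back < duration:
            events.append(AgentEvent(t_back, "straight", STRAIGHT, macro.id, "rearm"))
        ready = t_back
    return AgentEventLog(duration=duration, events=tuple(events))


HumanPolicy = Callable[[int, str, np.random.Generator], Dwell | None]


def _earliest_on(dwells: Sequence[Dwell], target: str, t: int) -> int | None:
    """Earliest time >= t at which the human is dwelling on ``target``."""
    best: int | None = None
    for d in dwells:
        if d.target != target or d.offset <= t:
            continue
        cand = max(d.onset, t)
        if best is None or cand < best:
            best = cand
    return best


def ija_controller(
    macro: MacroState,
    human: Sequence[Dwell] | HumanPolicy | None,
    duration: int,
    rng: np.random.Generator,
) -> AgentEventLog:
    """Initiating-joint-attention agent.

    Per bid cycle the agent gazes straight, waits for eye contact (human
    dwell on the agent AOI) up to ``max_contact_wait``, keeps contact for a
    straight-dwell draw, then shifts to an object chosen by weight. The bid
    is a JA success iff the human's dwell on that object begins within the
    response window of the shift onset; the agent returns to straight gaze
    after an object-dwell draw (success) or the no-JA timeout (failure).

    ``human`` may be a static dwell sequence, a policy called per bid as
    ``policy(shift_onset, object, rng) -> Dwell | None``, or ``None`` (no
    responses). A policy human is assumed to keep eye contact between bids.
    """
    p = macro.params
    objects = p.objects()
    weights = p.weights()
    static = list(human) if isinstance(human, (list, tuple)) else None
    events = [AgentEvent(0, "straight", STRAIGHT, macro.id, "entry")]
    t = 0
    while t < duration:
        if static is not None:
            contact = _earliest_on(static, AGENT_AOI, t)
            if contact is None or contact > t + p.max_contact_wait:
                shift_t = t + p.max_contact_wait
            else:
                shift_t = contact + _draw_ms(p.d_straight, rng)
        else:
            shift_t = t + _draw_ms(p.d_straight, rng)
        if shift_t >= duration:
            break
        o = objects[int(rng.choice(len(objects), p=weights))]
        events.append(AgentEvent(shift_t, "bid", o, macro.id, "ija_bid"))

        response: Dwell | None = None
        if static is not None:
            onset = None
            for d in static:
                if d.target == o and shift_t <= d.onset <= shift_t + p.response_window:
                    onset = d.onset if onset is None else min(onset, d.onset)
                    response = d if response is None or d.onset < response.onset else response
        elif callable(human):
            cand = human(shift_t, o, rng)
            if cand is not None and shift_t <= cand.onset <= shift_t + p.response_window:
                response = cand

        if response is not None:
            back_t = response.onset + _draw_ms(p.d_object, rng)
            cause = "ja_success"
        else:
            back_t = shift_t + p.no_ja_timeout
            cause = "no_ja"
        if back_t < duration:
            events.append(AgentEvent(back_t, "straight", STRAIGHT, macro.id, cause))
        t = back_t
    return AgentEventLog(duration=duration, events=tuple(events))


def run_block(
    macro: MacroState,
    human_stream: Sequence[Dwell] | HumanPolicy | None,
    duration: int,
    seed: int | np.random.Generator,
) -> AgentEventLog:
    """Simulate one block of the agent under ``macro``.

    Non-interactive macro states ignore ``human_stream``; RJA requires a
    dwell sequence; IJA accepts a dwell sequence, a per-bid policy or None.
    Identical (seed, inputs) produce identical logs.
    """
    if duration <= 0:
        raise ConfigError(f"duration must be > 0, got {duration}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if macro.id in ("PO", "OO", "INT"):
        return _run_markov(macro, duration, rng)
    if macro.id == "RJA":
        return rja_controller(macro, list(human_stream or ()), duration, rng)
    if macro.id == "IJA":
        return ija_controller(macro, human_stream, duration, rng)
    raise ConfigError(f"unknown macro state {macro.id!r}")


def blink_overlay(
    log: AgentEventLog,
    blink_cfg: BlinkConfig | None,
    seed: int | np.random.Generator,
) -> AgentEventLog:
    """Superimpose closed-eye segments on an event log.

    Blink onsets form a renewal process with onset-to-onset intervals drawn
    from ``blink_cfg.interval``; each closed segment lasts ``closed_ms``.
    The micro-state clock underneath is untouched. A disabled config returns
    the log unchanged; an interval mean below 2x the closed duration is
    rejected (overlapping blinks).
    """
    if blink_cfg is None or not blink_cfg.enabled or blink_cfg.interval is None:
        return log
    if blink_cfg.interval.mean() < 2 * blink_cfg.closed_ms:
        raise ConfigError(
            f"blink interval mean {blink_cfg.interval.mean():.0f} ms is below "
            f"{2 * blink_cfg.closed_ms} ms; blinks would overlap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blinks: list[tuple[int, int]] = []
    t = _draw_ms(blink_cfg.interval, rng)
    while t + blink_cfg.closed_ms <= log.duration:
        blinks.append((t, t + blink_cfg.closed_ms))
        t += max(_draw_ms(blink_cfg.interval, rng), blink_cfg.closed_ms + 1)
    return replace(log, blinks=tuple(blinks))


def _markov_macro(
    state_id: str,
    labels: Sequence[str],
    matrix: np.ndarray,
    timing_object: DurationDistribution,
    timing_agent: DurationDistribution,
    params: AgentParams,
    entry: str,
) -> MacroState:
    micro_states: dict[str, MicroState] = {}
    for i, label in enumerate(labels):
        row = {labels[j]: float(matrix[i, j]) for j in range(len(labels))
               if matrix[i, j] > 0}
        if label == AGENT_AOI:
            target, dist = STRAIGHT, timing_agent
        elif label == OFF_TARGET:
            target, dist = DOWN, timing_agent
        else:
            target, dist = label, timing_object
        micro_states[label] = MicroState(label, target, dist, row)
    return MacroState(state_id, micro_states, entry, params)


def default_macro(state: str, follow_probability: float | None = None,
                  params: AgentParams | None = None) -> MacroState:
    """Build a macro state with the package defaults.

    ``state`` is one of IJA, RJA, RJA_high, RJA_low, PO, OO, INT. The RJA
    variants differ only in their follow probability (1.0 vs 0.33).
    """
    base = params or AgentParams()
    if state in ("RJA", "RJA_high", "RJA_low"):
        pf = follow_probability
        if pf is None:
            pf = PF_RJA_LOW if state == "RJA_low" else PF_RJA_HIGH
        p = replace(base, follow_probability=pf,
                    d_follow=base.d_follow, d_object=base.d_object)
        micro = {
            "straight": MicroState("straight", STRAIGHT, p.d_straight),
            "follow": MicroState("follow", "O1", p.d_object),  # target bound at runtime
        }
        return MacroState("RJA", micro, "straight", p)
    if state == "IJA":
        p = replace(base, d_object=DEFAULT_TIMING["t_object_IJA"])
        micro = {
            "straight": MicroState("straight", STRAIGHT, p.d_straight),
            "bid": MicroState("bid", "O1", p.d_object),  # target bound at runtime
        }
        return MacroState("IJA", micro, "straight", p)
    if state == "OO":
        return _markov_macro("OO", AOI_LABELS, OO_TRANSITIONS,
                             DEFAULT_TIMING["t_object_OO"], DEFAULT_TIMING["t_agent_OO"],
                             base, entry="O1")
    if state == "PO":
        return _markov_macro("PO", AOI_LABELS, PO_TRANSITIONS,
                             DEFAULT_TIMING["t_object_PO"], DEFAULT_TIMING["t_agent_PO"],
                             base, entry=AGENT_AOI)
    if state == "INT":
        return _markov_macro("INT", INT_LABELS, INT_TRANSITIONS,
                             DEFAULT_TIMING["t_object_INT"], DEFAULT_TIMING["t_agent_INT"],
                             base, entry=OFF_TARGET)
    raise ConfigError(f"unknown macro state {state!r}")
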