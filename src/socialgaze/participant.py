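"""Synthetic human participant: event-level behaviour and raw gaze samples.

The generator emulates a participant instructed to display one of the five
social-gaze states while interacting with the virtual agent, closing the
loop that a live eye tracker would otherwise provide:

* instructed RJA — the participant keeps eye contact and follows the
  agent's joint-attention bids with ``response_probability`` after a
  gaze-following latency, dwelling on the object before returning.
* instructed IJA — the participant dwells on the agent, shifts to an
  object to invite a follow, and leaves the object after a short dwell if
  the agent followed (optionally moving straight to the next object) or a
  longer one if it did not.
* instructed PO / OO / INT — a Markov walk over AOIs with the state's
  transition matrix and dwell laws.

``render_samples`` turns the event stream into a tracker-like raw sample
stream (fixed rate, anchor positions plus micro-saccadic jitter and
measurement noise, optional dropout), which the parsing module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import defaults
from .agent import (
    AgentEventLog,
    ConfigError,
    Dwell,
    MacroState,
    default_macro,
    ija_controller,
    run_block,
)
from .defaults import (
    AGENT_AOI,
    AOI_LABELS,
    DEFAULT_TIMING,
    INT_LABELS,
    INT_TRANSITIONS,
    OBJECT_AOIS,
    OFF_TARGET,
    OO_TRANSITIONS,
    PO_TRANSITIONS,
)
from .distributions import DurationDistribution
from .parsing import AOILayout

__all__ = [
    "ParticipantProfile",
    "SampleConfig",
    "GazeSampleStream",
    "simulate_participant",
    "simulate_block",
    "render_samples",
]

#: Constant saccade transit time between AOIs (ms); excluded from dwells.
SACCADE_MS = 30


def _check_matrix(m: np.ndarray, n: int, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n, n):
        raise ConfigError(f"{name} matrix must be {n}x{n}, got {m.shape}")
    if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
        raise ConfigError(f"{name} matrix must be row-stochastic")
    return m


@dataclass(frozen=True)
class ParticipantProfile:
    """Statistical profile of the synthetic participant.

    ``timing`` maps the eleven timing-parameter labels to duration laws;
    ``oo/po/int_matrix`` are the AOI-walk transition matrices of the
    non-interactive states. ``response_probability`` is the chance of
    answering an agent bid; ``direct_next_object_probability`` is the chance
    of moving straight to the next object after a successful own bid instead
    of re-fixating the agent first.
    """

    timing: Mapping[str, DurationDistribution] = field(
        default_factory=lambda: dict(DEFAULT_TIMING))
    oo_matrix: np.ndarray = field(default_factory=lambda: OO_TRANSITIONS.copy())
    po_matrix: np.ndarray = field(default_factory=lambda: PO_TRANSITIONS.copy())
    int_matrix: np.ndarray = field(default_factory=lambda: INT_TRANSITIONS.copy())
    response_probability: float = 0.85
    direct_next_object_probability: float = 0.2
    response_window: int = 2000

    def __post_init__(self) -> None:
        for p, name in ((self.response_probability, "response_probability"),
                        (self.direct_next_object_probability, "direct_next_object_probability")):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        _check_matrix(self.oo_matrix, len(AOI_LABELS), "OO")
        _check_matrix(self.po_matrix, len(AOI_LABELS), "PO")
        _check_matrix(self.int_matrix, len(INT_LABELS), "INT")

    def law(self, name: str) -> DurationDistribution:
        try:
            return self.timing[name]
        except KeyError:
            raise ConfigError(f"profile is missing timing law {name!r}") from None


def _draw_ms(dist: DurationDistribution, rng: np.random.Generator) -> int:
    return max(1, int(round(dist.sample_one(rng))))


def _simulate_rja_human(
    profile: ParticipantProfile,
    agent_macro: MacroState,
    duration: int,
    rng: np.random.Generator,
) -> tuple[AgentEventLog, list[Dwell]]:
    """Instructed RJA: agent initiates (IJA), participant responds."""
    responses: list[Dwell] = []

    def policy(shift_t: int, target: str, prng: np.random.Generator) -> Dwell | None:
        if prng.random() >= profile.response_probability:
            return None
        latency = _draw_ms(profile.law("t_follow_RJA"), prng)
        onset = shift_t + latency
        offset = onset + _draw_ms(profile.law("t_object_RJA"), prng)
        if onset >= duration:
            return None
        if responses and onset <= responses[-1].offset + SACCADE_MS:
            return None  # still dwelling on the previous object; bid not taken
        d = Dwell(target, onset, min(offset, duration))
        if d.offset > d.onset:
            responses.append(d)
            return d
        return None

    log = ija_controller(agent_macro, policy, duration, rng)

    # Human timeline: on the agent's face except while answering a bid.
    dwells: list[Dwell] = []
    cursor = 0
    for r in sorted(responses, key=lambda d: d.onset):
        a_end = r.onset - SACCADE_MS
        if a_end > cursor:
            dwells.append(Dwell(AGENT_AOI, cursor, a_end))
        if dwells and dwells[-1].target == r.target and dwells[-1].offset > r.onset:
            continue  # overlapping rare draw; keep the earlier dwell
        dwells.append(r)
        cursor = r.offset + SACCADE_MS
    if cursor < duration:
        dwells.append(Dwell(AGENT_AOI, cursor, duration))
    return log, dwells


def _simulate_ija_human(
    profile: ParticipantProfile,
    agent_macro: MacroState,
    duration: int,
    rng: np.random.Generator,
) -> tuple[AgentEventLog, list[Dwell]]:
    """Instructed IJA: participant initiates, agent responds (RJA variant)."""
    p = agent_macro.params
    dwells: list[Dwell] = []
    agent_events = [("straight", 0, "entry")]
    agent_ready = 0
    t_a_start: int | None = 0  # current agent-face dwell onset; None after a direct shift
    onset = 0
    prev_object: str | None = None

    while True:
        if t_a_start is not None:
            leave = t_a_start + _draw_ms(profile.law("t_straight_IJA"), rng)
            if leave >= duration:
                dwells.append(Dwell(AGENT_AOI, t_a_start, duration))
                break
            dwells.append(Dwell(AGENT_AOI, t_a_start, leave))
            onset = leave + SACCADE_MS
        if onset >= duration:
            break
        candidates = [o for o in OBJECT_AOIS if o != prev_object]
        o = candidates[int(rng.integers(len(candidates)))]

        followed = onset >= agent_ready and rng.random() < p.follow_probability
        arrival = onset + _draw_ms(p.d_follow, rng) if followed else None
        if arrival is not None and arrival - onset <= profile.response_window:
            agent_events.append((o, arrival, "follow"))
            back = arrival + _draw_ms(p.d_object, rng)
            if back < duration:
                agent_events.append(("straight", back, "rearm"))
            agent_ready = back
            departure = arrival + _draw_ms(profile.law("t_object_IJA"), rng)
            departure = max(departure, onset + 1)
            dwells.append(Dwell(o, onset, min(departure, duration)))
            if departure >= duration:
                break
            if rng.random() < profile.direct_next_object_probability:
                t_a_start = None
                onset = departure + SACCADE_MS
                prev_object = o
                continue
            t_a_start = departure + SACCADE_MS
        else:
            departure = onset + _draw_ms(profile.law("t_back_IJA"), rng)
            dwells.append(Dwell(o, onset, min(departure, duration)))
            if departure >= duration:
                break
            t_a_start = departure + SACCADE_MS
        prev_object = None
        if t_a_start is not None and t_a_start >= duration:
            break

    from .agent import STRAIGHT, AgentEvent
    events = []
    last_onset = -1
    for target, t, cause in sorted(agent_events, key=lambda e: e[1]):
        if t >= duration or t <= last_onset:
            continue
        gaze = STRAIGHT if target == "straight" else target
        micro = "straight" if target == "straight" else "follow"
        events.append(AgentEvent(t, micro, gaze, agent_macro.id, cause))
        last_onset = t
    if not events or events[0].onset != 0:
        events.insert(0, AgentEvent(0, "straight", STRAIGHT, agent_macro.id, "entry"))
    log = AgentEventLog(duration=duration, events=tuple(events))
    return log, dwells


_NONINT_LABELS = {"OO": AOI_LABELS, "PO": AOI_LABELS, "INT": INT_LABELS}


def _simulate_nonint_human(
    state: str,
    profile: ParticipantProfile,
    duration: int,
    rng: np.random.Generator,
) -> list[Dwell]:
    labels = _NONINT_LABELS[state]
    matrix = {"OO": profile.oo_matrix, "PO": profile.po_matrix,
              "INT": profile.int_matrix}[state]

    def law_for(label: str) -> DurationDistribution:
        if label in OBJECT_AOIS:
            return profile.law(f"t_object_{state}")
        if label == AGENT_AOI:
            return profile.law(f"t_agent_{state}")
        return profile.law("t_agent_INT")  # off-AOI dwell; not an estimand

    if state == "PO":
        cur = AGENT_AOI
    elif state == "OO":
        cur = OBJECT_AOIS[int(rng.integers(len(OBJECT_AOIS)))]
    else:
        cur = OFF_TARGET

    dwells: list[Dwell] = []
    t = 0
    idx = {lab: i for i, lab in enumerate(labels)}
    while t < duration:
        dur = _draw_ms(law_for(cur), rng)
        # merge Markov self-transitions into one continued dwell
        while t + dur < duration:
            nxt = labels[int(rng.choice(len(labels), p=matrix[idx[cur]]))]
            if nxt != cur:
                break
            dur += _draw_ms(law_for(cur), rng)
        else:
            nxt = cur
        end = min(t + dur, duration)
        if end > t:
            dwells.append(Dwell(cur, t, end))
        t = end + SACCADE_MS
        cur = nxt
    return dwells


def simulate_block(
    instructed_state: str,
    profile: ParticipantProfile,
    duration: int,
    seed: int | np.random.Generator,
    agent_macro: MacroState | None = None,
) -> tuple[AgentEventLog, list[Dwell]]:
    """Simulate one coupled agent/participant block.

    Returns the agent event log and the participant's ground-truth dwell
    stream. The agent macro defaults to the standard pairing: instructed RJA
    pairs with an initiating agent, instructed IJA with a responding agent,
    and non-interactive instructions with the matching non-interactive agent.
    """
    if instructed_state not in defaults.MACRO_STATES:
        raise ConfigError(f"unknown instructed state {instructed_state!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if agent_macro is None:
        pairing = {"RJA": "IJA", "IJA": "RJA_high"}
        agent_macro = default_macro(pairing.get(instructed_state, instructed_state))

    if instructed_state == "RJA":
        return _simulate_rja_human(profile, agent_macro, duration, rng)
    if instructed_state == "IJA":
        return _simulate_ija_human(profile, agent_macro, duration, rng)
    human = _simulate_nonint_human(instructed_state, profile, duration, rng)
    log = run_block(agent_macro, None, duration, rng)
    return log, human


def simulate_participant(
    instructed_state: str,
    profile: ParticipantProfile,
    duration: int,
    seed: int | np.random.Generator,
    agent_macro: MacroState | None = None,
) -> list[Dwell]:
    """Human gaze event stream for one instructed block (see ``simulate_block``)."""
    return simulate_block(instructed_state, profile, duration, seed, agent_macro)[1]


@dataclass(frozen=True)
class SampleConfig:
    """Tracker emulation: sample rate, measurement noise, micro-saccadic
    jitter (piecewise-constant offset re-drawn at a fixed cadence) and
    uniform sample dropout."""

    rate: float = 60.0
    noise_sd: float = 2.0
    jitter_sd: float = 3.0
    jitter_interval_ms: float = 100.0
    dropout_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ConfigError(f"rate must be > 0, got {self.rate}")
        if not (0.0 <= self.dropout_probability <= 1.0):
            raise ConfigError("dropout_probability must be in [0,1]")


@dataclass(frozen=True)
class GazeSampleStream:
    """Raw gaze samples: equally spaced timestamps (ms), screen positions
    (px) and validity flags, as an eye tracker would deliver."""

    rate: float
    noise_sd: float
    dropout_probability: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return int(self.t.size)

    def valid_fraction(self) -> float:
        return float(np.asarray(self.valid).mean()) if len(self) else 0.0


def _anchor_for(target: str, layout: AOILayout) -> tuple[float, float]:
    if target == OFF_TARGET:
        return defaults.OFF_ANCHOR
    return layout.anchor(target)


def render_samples(
    events: Sequence[Dwell],
    layout: AOILayout,
    cfg: SampleConfig = SampleConfig(),
    seed: int | np.random.Generator = 0,
    duration: int | None = None,
) -> GazeSampleStream:
    """Render a dwell event stream into a raw gaze sample stream.

    Samples during a dwell sit at the target's anchor plus micro-saccadic
    jitter and white measurement noise; samples inside saccade gaps
    interpolate linearly between anchors. Each sample is invalid with
    ``dropout_probability``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = sorted(events, key=lambda d: d.onset)
    if duration is None:
        duration = int(events[-1].offset) if events else 0
    n = int(np.floor(cfg.rate * duration / 1000.0))
    period = 1000.0 / cfg.rate
    t = np.arange(n) * period
    x = np.empty(n)
    y = np.empty(n)

    if not events:
        x.fill(0.0)
        y.fill(0.0)
    else:
        anchors = [_anchor_for(d.target, layout) for d in events]
        onsets = np.array([d.onset for d in events], dtype=float)
        offsets = np.array([d.offset for d in events], dtype=float)
        # index of the dwell each sample falls into, or the gap after it
        k = np.searchsorted(onsets, t, side="right") - 1
        k = np.clip(k, 0, len(events) - 1)
        for i in range(len(events)):
            ax, ay = anchors[i]
            sel = (k == i) & (t <= offsets[i]) & (t >= onsets[i])
            idx = np.flatnonzero(sel)
            if idx.size:
                seg = ((t[idx] - onsets[i]) // cfg.jitter_interval_ms).astype(int)
                nseg = int(seg.max()) + 1
                jx = rng.normal(0.0, cfg.jitter_sd, nseg)
                jy = rng.normal(0.0, cfg.jitter_sd, nseg)
                x[idx] = ax + jx[seg]
                y[idx] = ay + jy[seg]
            # gap between this dwell and the next: linear transit
            gap = np.flatnonzero((k == i) & (t > offsets[i]))
            if gap.size:
                if i + 1 < len(events):
                    bx, by = anchors[i + 1]
                    span = max(onsets[i + 1] - offsets[i], 1.0)
                    f = np.clip((t[gap] - offsets[i]) / span, 0.0, 1.0)
                    x[gap] = ax + f * (bx - ax)
                    y[gap] = ay + f * (by - ay)
                else:
                    x[gap] = ax
                    y[gap] = ay
        before = np.flatnonzero(t < onsets[0])
        if before.size:
            x[before], y[before] = anchors[0]

    x += rng.normal(0.0, cfg.noise_sd, n)
    y += rng.normal(0.0, cfg.noise_sd, n)
    valid = rng.random(n) >= cfg.dropout_probability
    return GazeSampleStream(
        rate=cfg.rate, noise_sd=cfg.noise_sd,
        dropout_probability=cfg.dropout_probability,
        t=t, x=x, y=y, valid=valid,
    )
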