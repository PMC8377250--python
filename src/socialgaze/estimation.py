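"""Estimation pipeline: timing parameters, transition matrices, attention
ratios and fixation heatmaps from paired agent logs and human dwell streams.

The eleven timing parameters are read off the event grammar of the paired
streams. In an instructed-RJA block (agent initiates), each agent gaze
shift to an object is a bid; the first human dwell on that object within
the response window yields the gaze-following latency, and that dwell's
duration the post-JA object dwell. In an instructed-IJA block (agent
responds), each human object dwell is a bid: the preceding agent-face
dwell gives the pre-bid straight time, and the object dwell is timed from
the agent's gaze arrival (bid followed) or in full (bid not followed).
In non-interactive blocks every human dwell contributes a dwell-time
observation keyed by AOI class (object vs agent face).

Each parameter is then fitted per participant, the family is chosen by
pooled BIC, and parameters are averaged across participants
(:func:`fit_summary_table`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .agent import AgentEventLog, Dwell
from .defaults import (
    AGENT_AOI,
    AOI_LABELS,
    OBJECT_AOIS,
    PARAMETER_DESCRIPTIONS,
    PARAMETER_LABELS,
)
from .distributions import (
    FAMILIES,
    MIN_FIT_SIZE,
    InsufficientDataError,
    ParameterSummary,
    select_family,
    summarize_parameter,
)
from .parsing import DwellEvent, Fixation

__all__ = [
    "TimingObservation",
    "TransitionMatrix",
    "RateSummary",
    "HeatmapGrid",
    "extract_timing",
    "estimate_rates",
    "fit_summary_table",
    "summary_to_frame",
    "write_summary_tsv",
    "estimate_transition_matrix",
    "attention_ratios",
    "attention_table",
    "build_heatmap",
]

@dataclass(frozen=True)
class TimingObservation:
    """One measured reaction or dwell time, tagged with its parameter label."""

    parameter_name: str
    value: float
    participant: str = "p0"
    block: str = "b0"

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"timing observation must be positive, got {self.value}")


def _as_dwells(dwells: Sequence) -> list[DwellEvent]:
    out = []
    for d in dwells:
        if isinstance(d, DwellEvent):
            out.append(d)
        elif isinstance(d, Dwell):
            out.append(DwellEvent(d.target, float(d.onset), float(d.offset)))
        else:
            raise TypeError(f"cannot interpret {d!r} as a dwell event")
    return out


def extract_timing(
    agent_log: AgentEventLog,
    dwells: Sequence[DwellEvent] | Sequence[Dwell],
    instructed_state: str,
    participant: str = "p0",
    block: str = "b0",
    window: int = 2000,
    boundary_guard_ms: float = 50.0,
) -> list[TimingObservation]:
    """Extract timing observations from one block's paired streams.

    ``instructed_state`` is the state the *human* was instructed to display;
    ``window`` is the response window (ms) used to classify a bid as
    followed. Both streams must share the block clock (ms from block start).
    Dwells reaching into the last ``boundary_guard_ms`` of the block are
    right-censored by the block end and contribute no duration observation
    (reaction-time onsets are unaffected).
    """
    if instructed_state not in ("IJA", "RJA", "PO", "OO", "INT"):
        raise ValueError(f"unknown instructed state {instructed_state!r}")
    ds = sorted(_as_dwells(dwells), key=lambda d: d.onset)
    obs: list[TimingObservation] = []
    censor_after = agent_log.duration - boundary_guard_ms

    def censored(d: DwellEvent) -> bool:
        return d.offset >= censor_after

    def emit(name: str, value: float) -> None:
        if value > 0:
            obs.append(TimingObservation(name, float(value), participant, block))

    if instructed_state == "RJA":
        for t_shift, target in agent_log.shifts_to_objects():
            # first human dwell on the cued object within the window
            first = None
            for d in ds:
                if d.aoi == target and t_shift <= d.onset <= t_shift + window:
                    first = d
                    break
                if d.onset > t_shift + window:
                    break
            if first is not None:
                emit("t_follow_RJA", first.onset - t_shift)
                if not censored(first):
                    emit("t_object_RJA", first.duration)
    elif instructed_state == "IJA":
        follows = agent_log.shifts_to_objects()
        for i, d in enumerate(ds):
            if d.aoi == AGENT_AOI:
                if i + 1 < len(ds) and ds[i + 1].aoi in OBJECT_AOIS and not censored(d):
                    emit("t_straight_IJA", d.duration)
                continue
            if d.aoi not in OBJECT_AOIS or censored(d):
                continue
            arrival = None
            for t_a, target in follows:
                if target == d.aoi and d.onset <= t_a <= d.onset + window:
                    arrival = t_a
                    break
            if arrival is None:
                emit("t_back_IJA", d.duration)
            elif arrival < d.offset:
                emit("t_object_IJA", d.offset - arrival)
    else:
        for d in ds:
            if censored(d):
                continue
            if d.aoi in OBJECT_AOIS:
                emit(f"t_object_{instructed_state}", d.duration)
            elif d.aoi == AGENT_AOI:
                emit(f"t_agent_{instructed_state}", d.duration)
    return obs


@dataclass(frozen=True)
class RateSummary:
    """Interaction rates: agent joint-attention bids per minute, human
    initiations per minute, and the human response fraction. Rates are NaN
    when the corresponding exposure time is zero."""

    agent_bids_per_min: float
    human_initiations_per_min: float
    response_fraction: float
    n_agent_bids: int
    n_human_bids: int


def estimate_rates(
    blocks: Iterable[tuple[str, AgentEventLog, Sequence]],
    window: int = 2000,
) -> RateSummary:
    """Bid and response rates over ``(instructed_state, agent_log, dwells)`` blocks."""
    bid_count = followed = 0
    ija_ms = 0
    init_count = 0
    rja_ms = 0
    for state, log, dwells in blocks:
        ds = sorted(_as_dwells(dwells), key=lambda d: d.onset)
        if state == "RJA":
            ija_ms += log.duration
            for t_shift, target in log.shifts_to_objects():
                bid_count += 1
                if any(d.aoi == target and t_shift <= d.onset <= t_shift + window
                       for d in ds):
                    followed += 1
        elif state == "IJA":
            rja_ms += log.duration
            for i, d in enumerate(ds):
                if d.aoi in OBJECT_AOIS and (i == 0 or ds[i - 1].aoi == AGENT_AOI):
                    init_count += 1
    return RateSummary(
        agent_bids_per_min=bid_count / (ija_ms / 60000.0) if ija_ms else math.nan,
        human_initiations_per_min=init_count / (rja_ms / 60000.0) if rja_ms else math.nan,
        response_fraction=followed / bid_count if bid_count else math.nan,
        n_agent_bids=bid_count,
        n_human_bids=init_count,
    )


def _group_observations(
    observations: Iterable[TimingObservation],
) -> dict[str, dict[str, list[float]]]:
    grouped: dict[str, dict[str, list[float]]] = {}
    for o in observations:
        grouped.setdefault(o.parameter_name, {}).setdefault(o.participant, []).append(o.value)
    return grouped


def fit_summary_table(
    observations: Iterable[TimingObservation],
    candidates: Sequence[str] = FAMILIES,
    min_n: int = MIN_FIT_SIZE,
) -> tuple[list[ParameterSummary], dict[str, str]]:
    """Fit and summarize every timing parameter present in ``observations``.

    Per parameter: per-participant maximum-likelihood fits, family chosen by
    pooled BIC, parameters and closed-form moments averaged across
    participants. Returns the summaries plus a map of parameters that could
    not be fitted (too little data) to the reason.
    """
    summaries: list[ParameterSummary] = []
    skipped: dict[str, str] = {}
    grouped = _group_observations(observations)
    order = [p for p in PARAMETER_LABELS if p in grouped]
    order += [p for p in grouped if p not in order]
    for name in order:
        per_part = grouped[name]
        pooled = [v for vals in per_part.values() for v in vals]
        try:
            family, fits = select_family(per_part, candidates, min_n)
        except InsufficientDataError as err:
            skipped[name] = str(err)
            continue
        summaries.append(summarize_parameter(name, fits, pooled))
    return summaries, skipped


def summary_to_frame(summaries: Sequence[ParameterSummary]) -> pd.DataFrame:
    """Summary table as a DataFrame with one row per timing parameter."""
    rows = []
    for s in summaries:
        mu, rho = s.mean_params[0], s.mean_params[1]
        eta = s.mean_params[2] if len(s.mean_params) > 2 else math.nan
        rows.append({
            "parameter": s.parameter_name,
            "description": PARAMETER_DESCRIPTIONS.get(s.parameter_name, ""),
            "raw_mean": s.raw_mean,
            "raw_sd": s.raw_sd,
            "family": s.family,
            "mu": mu,
            "rho": rho,
            "eta": eta,
            "est_mean": s.est_mean,
            "est_sd": s.est_sd,
            "n_participants": s.n_participants,
            "n_obs": s.n_obs,
        })
    return pd.DataFrame(rows)


def write_summary_tsv(summaries: Sequence[ParameterSummary], path) -> None:
    summary_to_frame(summaries).to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic AOI-to-AOI gaze-shift probabilities.

    The diagonal is structurally zero: a merged dwell cannot follow itself,
    so self-transitions are dwell continuations, not shifts. Rows without
    any observed outgoing shift are NaN.
    """

    labels: tuple[str, ...]
    probs: np.ndarray
    row_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(self.labels), columns=list(self.labels))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        return float(self.probs[self.labels.index(a), self.labels.index(b)])


def _count_matrix(sequences: Iterable[Sequence[str]], labels: Sequence[str]) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for seq in sequences:
        for a, b in zip(seq, seq[1:]):
            if a == b or a not in idx or b not in idx:
                continue
            counts[idx[a], idx[b]] += 1
    return counts


def estimate_transition_matrix(
    dwell_sequences: Mapping[str, Iterable[Sequence]],
    labels: Sequence[str] = AOI_LABELS,
) -> TransitionMatrix:
    """Empirical AOI gaze-shift matrix, averaged across participants.

    ``dwell_sequences`` maps each participant to an iterable of per-block
    dwell sequences (dwell events or plain AOI-label sequences); transitions
    never cross block boundaries. Per participant, ``p(a -> b)`` is the
    observed frequency among consecutive dwell pairs with ``a != b``; rows
    without outgoing shifts are undefined and excluded from the average,
    which is renormalized row-wise afterwards.
    """
    labels = tuple(labels)
    per_participant: list[np.ndarray] = []
    pooled_counts = np.zeros((len(labels), len(labels)))
    for pid, blocks in dwell_sequences.items():
        seqs = []
        for block in blocks:
            seq = [d.aoi if isinstance(d, DwellEvent) else
                   (d.target if isinstance(d, Dwell) else str(d)) for d in block]
            seqs.append(seq)
        counts = _count_matrix(seqs, labels)
        pooled_counts += counts
        row_sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(row_sums > 0, counts / row_sums, np.nan)
        per_participant.append(probs)
    if not per_participant:
        raise InsufficientDataError("no participants with dwell sequences")
    stacked = np.stack(per_participant)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
        avg = np.nanmean(stacked, axis=0)
    row_sums = np.nansum(avg, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(row_sums > 0, avg / row_sums, np.nan)
    return TransitionMatrix(labels, avg, pooled_counts.sum(axis=1))


def attention_ratios(
    dwells: Sequence[DwellEvent] | Sequence[Dwell],
    state_duration: float,
) -> tuple[float, float]:
    """(on-AOI ratio, face-object ratio) for one state's dwell collection.

    The on-AOI ratio is total dwell time on any AOI over the state duration;
    the face-object ratio is agent-face dwell time over agent-plus-object
    dwell time (NaN when there are no dwells at all). Both lie in [0, 1] and
    are invariant under uniform time translation.
    """
    if not state_duration > 0:
        raise ValueError(f"state duration must be > 0, got {state_duration}")
    ds = _as_dwells(dwells)
    agent_ms = sum(d.duration for d in ds if d.aoi == AGENT_AOI)
    object_ms = sum(d.duration for d in ds if d.aoi in OBJECT_AOIS)
    aoi_ms = sum(d.duration for d in ds if d.aoi in AOI_LABELS)
    r_aoi = min(aoi_ms / state_duration, 1.0)
    denom = agent_ms + object_ms
    r_a_o = agent_ms / denom if denom > 0 else math.nan
    return r_aoi, r_a_o


def attention_table(
    blocks: Iterable[tuple[str, str, float, Sequence]],
) -> pd.DataFrame:
    """Per-participant, per-state attention ratios.

    ``blocks`` holds ``(participant, instructed_state, duration_ms, dwells)``
    records; dwell times and durations are pooled within participant and
    state before forming the ratios.
    """
    acc: dict[tuple[str, str], dict[str, float]] = {}
    for pid, state, duration, dwells in blocks:
        a = acc.setdefault((pid, state), {"agent": 0.0, "object": 0.0, "aoi": 0.0, "dur": 0.0})
        for d in _as_dwells(dwells):
            if d.aoi == AGENT_AOI:
                a["agent"] += d.duration
            if d.aoi in OBJECT_AOIS:
                a["object"] += d.duration
            if d.aoi in AOI_LABELS:
                a["aoi"] += d.duration
        a["dur"] += duration
    rows = []
    for (pid, state), a in sorted(acc.items()):
        denom = a["agent"] + a["object"]
        rows.append({
            "participant": pid,
            "state": state,
            "r_aoi": min(a["aoi"] / a["dur"], 1.0) if a["dur"] else math.nan,
            "r_a_o": a["agent"] / denom if denom > 0 else math.nan,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HeatmapGrid:
    """Duration-weighted fixation density on a (downsampled) screen grid.

    ``mass`` is the raw deposited mass (proportional to total fixation
    duration); ``grid`` is ``log1p(mass)`` for display. ``radius`` is the
    kernel radius in screen px.
    """

    grid: np.ndarray
    mass: np.ndarray
    radius: float
    downsample: int
    transform: str = "log1p"


def build_heatmap(
    fixations: Sequence[Fixation],
    canvas: tuple[int, int] = (1920, 1080),
    downsample: int = 4,
    min_radius: float = 5.0,
) -> HeatmapGrid:
    """Fixation heatmap: each fixation deposits a duration-weighted quadratic
    kernel ``max(0, 1 - (r/R)^2)`` of radius R equal to the pooled SD of the
    fixation positions about their mean (``sqrt((var_x + var_y)/2)``, with a
    floor for degenerate clouds); the displayed map is ``log1p`` of the mass.
    """
    if not fixations:
        raise ValueError("need at least one fixation to build a heatmap")
    xs = np.array([f.x for f in fixations])
    ys = np.array([f.y for f in fixations])
    radius = math.sqrt((xs.var() + ys.var()) / 2.0)
    if not radius > min_radius:
        radius = min_radius

    w = int(math.ceil(canvas[0] / downsample))
    h = int(math.ceil(canvas[1] / downsample))
    mass = np.zeros((h, w))
    r_cells = radius / downsample
    span = int(math.ceil(r_cells))
    for f in fixations:
        cx = f.x / downsample
        cy = f.y / downsample
        x0 = max(int(math.floor(cx - r_cells)), 0)
        x1 = min(int(math.ceil(cx + r_cells)) + 1, w)
        y0 = max(int(math.floor(cy - r_cells)), 0)
        y1 = min(int(math.ceil(cy + r_cells)) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.arange(x0, x1) + 0.5
        gy = np.arange(y0, y1) + 0.5
        r2 = ((gx[None, :] - cx) ** 2 + (gy[:, None] - cy) ** 2) / (r_cells**2)
        mass[y0:y1, x0:x1] += f.duration * np.clip(1.0 - r2, 0.0, None)
    return HeatmapGrid(grid=np.log1p(mass), mass=mass, radius=radius, downsample=downsample)
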