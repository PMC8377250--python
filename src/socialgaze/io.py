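"""File formats and configuration.

Event logs, dwell events and raw samples are plain CSV with a small comment
header carrying provenance (package version, master seed, config digest).
Configurations are YAML trees mirroring the dataclasses in the other
modules. Malformed rows are rejected with their line number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .agent import AgentEvent, AgentEventLog, Dwell
from .defaults import DEFAULT_LAYOUT, DEFAULT_TIMING
from .distributions import DurationDistribution
from .parsing import AOILayout, DwellEvent, ParseConfig
from .participant import ParticipantProfile, SampleConfig, GazeSampleStream

__all__ = [
    "ParseError",
    "ExperimentConfig",
    "EVENT_KINDS",
    "ACTORS",
    "write_event_log",
    "read_event_log",
    "write_dwells",
    "read_dwells",
    "write_samples",
    "read_samples",
]

EVENT_KINDS = ("gaze_shift", "dwell_onset", "dwell_offset", "blink_on", "blink_off",
               "state_change")
ACTORS = ("agent", "human")


class ParseError(ValueError):
    """Raised for schema violations, carrying the offending line number."""


def _provenance_header(seed: int | None, config_digest: str | None) -> str:
    parts = ["# socialgaze"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_digest is not None:
        parts.append(f"config={config_digest}")
    return " ".join(parts) + "\n"


def event_records(
    log: AgentEventLog,
    dwells: Sequence[Dwell] | None = None,
    participant: str = "p0",
    block: str = "b0",
) -> pd.DataFrame:
    """Flatten an agent log (and optional human dwells) into the log schema."""
    rows = []
    for ev in log.events:
        rows.append((ev.onset, "agent", "gaze_shift", ev.gaze_target,
                     ev.macro_state, block, participant))
    for b0, b1 in log.blinks:
        rows.append((b0, "agent", "blink_on", "CLOSED", log.events[0].macro_state,
                     block, participant))
        rows.append((b1, "agent", "blink_off", "CLOSED", log.events[0].macro_state,
                     block, participant))
    for d in dwells or ():
        rows.append((d.onset, "human", "dwell_onset", d.target, "", block, participant))
        rows.append((d.offset, "human", "dwell_offset", d.target, "", block, participant))
    df = pd.DataFrame(rows, columns=["t", "actor", "kind", "target",
                                     "macro_state", "block", "participant"])
    return df.sort_values(["participant", "block", "t"], kind="stable").reset_index(drop=True)


def write_event_log(df: pd.DataFrame, path, seed: int | None = None,
                    config_digest: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(seed, config_digest))
        df.to_csv(fh, index=False)


def read_event_log(path) -> pd.DataFrame:
    """Read and validate an event-log CSV; raises :class:`ParseError` with
    the 1-based file line of the first malformed row."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = ["t", "actor", "kind", "target", "macro_state", "block", "participant"]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    for col in ("actor", "kind", "target", "macro_state", "block", "participant"):
        df[col] = df[col].fillna("").astype(str)
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            header_lines += 1
            if not line.startswith("#"):
                break  # the CSV header row
    for i, row in df.iterrows():
        line_no = header_lines + 1 + int(i)
        if row["actor"] not in ACTORS:
            raise ParseError(f"{path}:{line_no}: unknown actor {row['actor']!r}")
        if row["kind"] not in EVENT_KINDS:
            raise ParseError(f"{path}:{line_no}: unknown kind {row['kind']!r}")
        try:
            float(row["t"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}:{line_no}: non-numeric t {row['t']!r}") from None
    t = pd.to_numeric(df["t"])
    if not t.groupby([df["participant"], df["block"]], observed=True).apply(
            lambda s: bool(s.is_monotonic_increasing)).all():
        raise ParseError(f"{path}: records not time-sorted within (participant, block)")
    return df


def write_dwells(dwells: Sequence[DwellEvent], path, participant: str = "p0",
                 block: str = "b0", seed: int | None = None) -> None:
    df = pd.DataFrame(
        [(d.aoi, d.onset, d.offset, d.fixation_count, block, participant) for d in dwells],
        columns=["aoi", "onset", "offset", "fixation_count", "block", "participant"])
    with open(path, "w") as fh:
        fh.write(_provenance_header(seed, None))
        df.to_csv(fh, index=False)


def read_dwells(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("aoi", "onset", "offset"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def write_samples(stream: GazeSampleStream, path, seed: int | None = None) -> None:
    df = pd.DataFrame({"t": stream.t, "x": stream.x, "y": stream.y,
                       "valid": stream.valid.astype(int)})
    with open(path, "w") as fh:
        fh.write(f"# socialgaze rate={stream.rate}"
                 + (f" seed={seed}" if seed is not None else "") + "\n")
        df.to_csv(fh, index=False, float_format="%.3f")


def read_samples(path) -> GazeSampleStream:
    rate = 60.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "rate=" in first:
        rate = float(first.split("rate=")[1].split()[0])
    df = pd.read_csv(path, comment="#")
    for col in ("t", "x", "y", "valid"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return GazeSampleStream(
        rate=rate, noise_sd=float("nan"), dropout_probability=float("nan"),
        t=df["t"].to_numpy(float), x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float), valid=df["valid"].to_numpy(bool))


@dataclass
class ExperimentConfig:
    """Complete, serialisable description of a session."""

    n_blocks: int = 60
    block_ms: int = 30000
    seed: int = 0
    timing: dict[str, DurationDistribution] = field(
        default_factory=lambda: dict(DEFAULT_TIMING))
    response_probability: float = 0.85
    direct_next_object_probability: float = 0.2
    response_window: int = 2000
    layout: AOILayout = DEFAULT_LAYOUT
    sampling: SampleConfig = SampleConfig()
    parsing: ParseConfig = ParseConfig()

    def profile(self) -> ParticipantProfile:
        return ParticipantProfile(
            timing=self.timing,
            response_probability=self.response_probability,
            direct_next_object_probability=self.direct_next_object_probability,
            response_window=self.response_window,
        )

    def to_dict(self) -> dict:
        return {
            "schedule": {"n_blocks": self.n_blocks, "block_ms": self.block_ms,
                         "seed": self.seed},
            "profile": {
                "timing": {k: v.to_dict() for k, v in self.timing.items()},
                "response_probability": self.response_probability,
                "direct_next_object_probability": self.direct_next_object_probability,
                "response_window": self.response_window,
            },
            "layout": self.layout.to_dict(),
            "sampling": {
                "rate": self.sampling.rate, "noise_sd": self.sampling.noise_sd,
                "jitter_sd": self.sampling.jitter_sd,
                "jitter_interval_ms": self.sampling.jitter_interval_ms,
                "dropout_probability": self.sampling.dropout_probability,
            },
            "parsing": {
                "dispersion_px": self.parsing.dispersion_px,
                "min_fixation_ms": self.parsing.min_fixation_ms,
                "gap_bridge_ms": self.parsing.gap_bridge_ms,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        sched = d.get("schedule", {})
        prof = d.get("profile", {})
        timing = {k: DurationDistribution.from_dict(v)
                  for k, v in prof.get("timing", {}).items()} or dict(DEFAULT_TIMING)
        layout = AOILayout.from_dict(d["layout"]) if "layout" in d else DEFAULT_LAYOUT
        return cls(
            n_blocks=int(sched.get("n_blocks", 60)),
            block_ms=int(sched.get("block_ms", 30000)),
            seed=int(sched.get("seed", 0)),
            timing=timing,
            response_probability=float(prof.get("response_probability", 0.85)),
            direct_next_object_probability=float(
                prof.get("direct_next_object_probability", 0.2)),
            response_window=int(prof.get("response_window", 2000)),
            layout=layout,
            sampling=SampleConfig(**d.get("sampling", {})),
            parsing=ParseConfig(**d.get("parsing", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
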