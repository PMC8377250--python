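"""Raw gaze samples -> fixations -> AOI dwell events, plus data-quality rules.

Fixation detection is dispersion-based (I-DT): maximal runs of valid samples
whose per-axis positional range stays within a dispersion threshold and that
last at least a minimum duration. Short invalid gaps (tracker dropouts,
blinks) are bridged. Fixation on/offsets are refined to the midpoint between
the boundary sample and its neighbour, which removes the half-sample-period
quantisation bias of the raw sample clock.

Consecutive fixations whose centroids fall inside the same area of interest
(AOI) are merged into a single dwell event; the dwell time (DT) is the span
from the first fixation's onset to the last fixation's offset, ignoring
micro-saccades inside the AOI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AOILayout",
    "Fixation",
    "DwellEvent",
    "ParseConfig",
    "ExclusionLedger",
    "detect_fixations",
    "merge_to_dwells",
    "block_quality",
    "exclusion_ledger",
    "QUALITY_THRESHOLD",
]

#: Blocks with a valid-sample fraction below 2/3 are excluded; exactly 2/3 is kept.
QUALITY_THRESHOLD = 2.0 / 3.0


class LayoutError(ValueError):
    """Raised for degenerate or inconsistent AOI layouts."""


@dataclass(frozen=True)
class AOILayout:
    """Named axis-aligned screen regions, 0-based, half-open [x0,x1) x [y0,y1).

    The origin is the top-left screen corner. Overlapping regions are
    permitted and resolved by declaration order (first match wins).
    """

    regions: tuple[tuple[str, float, float, float, float], ...]

    def __post_init__(self) -> None:
        names = [r[0] for r in self.regions]
        if len(set(names)) != len(names):
            raise LayoutError(f"duplicate AOI names in {names}")
        for name, x0, y0, x1, y1 in self.regions:
            if not (x1 > x0 and y1 > y0):
                raise LayoutError(f"degenerate AOI {name!r}: ({x0},{y0})-({x1},{y1})")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.regions)

    def hit(self, x: float, y: float) -> str | None:
        """Name of the first region containing (x, y), or None."""
        for name, x0, y0, x1, y1 in self.regions:
            if x0 <= x < x1 and y0 <= y < y1:
                return name
        return None

    def anchor(self, name: str) -> tuple[float, float]:
        """Centre point of a region, used as the gaze anchor when rendering."""
        for rname, x0, y0, x1, y1 in self.regions:
            if rname == name:
                return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
        raise LayoutError(f"unknown AOI {name!r}")

    def to_dict(self) -> dict:
        return {name: [x0, y0, x1, y1] for name, x0, y0, x1, y1 in self.regions}

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[float]]) -> "AOILayout":
        return cls(tuple((str(k), *(float(v) for v in box)) for k, box in d.items()))


@dataclass(frozen=True)
class Fixation:
    """A spatially stable run of valid gaze samples."""

    onset: float
    offset: float
    x: float
    y: float
    n_samples: int

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(f"fixation offset {self.offset} must exceed onset {self.onset}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class DwellEvent:
    """Merged run of consecutive fixations inside one AOI."""

    aoi: str
    onset: float
    offset: float
    fixation_count: int = 1

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(f"dwell offset {self.offset} must exceed onset {self.onset}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class ParseConfig:
    """I-DT thresholds (screen px / ms). Defaults are conventional desktop-
    eye-tracking values; the upstream tracker-side algorithm is not public,
    so these are declared substitutes and fully configurable."""

    dispersion_px: float = 40.0
    min_fixation_ms: float = 60.0
    gap_bridge_ms: float = 75.0


def _refine_edges(t_all: np.ndarray, first_t: float, last_t: float,
                  period: float) -> tuple[float, float]:
    """Midpoint-refine a fixation's onset/offset against neighbouring sample times."""
    i = int(np.searchsorted(t_all, first_t))
    onset = first_t
    if i > 0 and first_t - t_all[i - 1] <= 2.5 * period:
        onset = (first_t + t_all[i - 1]) / 2.0
    j = int(np.searchsorted(t_all, last_t, side="right"))
    offset = last_t
    if j < t_all.size and t_all[j] - last_t <= 2.5 * period:
        offset = (last_t + t_all[j]) / 2.0
    else:
        offset = last_t + period / 2.0
    return onset, offset


def detect_fixations(stream, config: ParseConfig = ParseConfig()) -> list[Fixation]:
    """Dispersion-based (I-DT) fixation detection.

    ``stream`` needs arrays ``t`` (ms), ``x``, ``y`` and boolean ``valid``
    (a :class:`~socialgaze.participant.GazeSampleStream` qualifies). Invalid
    samples break runs unless the gap is at most the bridge threshold.
    Dispersion is the larger of the per-axis sample ranges.
    """
    t_all = np.asarray(stream.t, dtype=float)
    if t_all.size == 0:
        return []
    x_all = np.asarray(stream.x, dtype=float)
    y_all = np.asarray(stream.y, dtype=float)
    valid = np.asarray(stream.valid, dtype=bool)

    t = t_all[valid]
    if t.size == 0:
        return []
    x = x_all[valid]
    y = y_all[valid]
    period = float(np.median(np.diff(t_all))) if t_all.size > 1 else 1000.0

    # split valid samples into runs with no unbridgeable gap
    gaps = np.diff(t)
    breaks = np.flatnonzero(gaps > config.gap_bridge_ms)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))

    fixations: list[Fixation] = []
    min_span = config.min_fixation_ms - period  # a 60 ms event at 60 Hz has a ~50 ms sample span
    for s, e in zip(starts, ends):
        i = s
        while i <= e:
            # minimal window spanning the minimum fixation duration
            j = i
            while j < e and t[j] - t[i] < min_span:
                j += 1
            if t[j] - t[i] < min_span:
                break
            xmin = xmax = x[i]
            ymin = ymax = y[i]
            for k in range(i + 1, j + 1):
                xmin = min(xmin, x[k]); xmax = max(xmax, x[k])
                ymin = min(ymin, y[k]); ymax = max(ymax, y[k])
            if max(xmax - xmin, ymax - ymin) > config.dispersion_px:
                i += 1
                continue
            while j < e:
                nx, ny = x[j + 1], y[j + 1]
                if max(max(xmax, nx) - min(xmin, nx),
                       max(ymax, ny) - min(ymin, ny)) > config.dispersion_px:
                    break
                j += 1
                xmin = min(xmin, nx); xmax = max(xmax, nx)
                ymin = min(ymin, ny); ymax = max(ymax, ny)
            onset, offset = _refine_edges(t_all, float(t[i]), float(t[j]), period)
            fixations.append(Fixation(
                onset=onset, offset=offset,
                x=float(x[i : j + 1].mean()), y=float(y[i : j + 1].mean()),
                n_samples=j - i + 1,
            ))
            i = j + 1
    return fixations


def merge_to_dwells(fixations: Sequence[Fixation], layout: AOILayout) -> list[DwellEvent]:
    """Merge consecutive same-AOI fixations into dwell events.

    Fixations outside every AOI produce no dwell and break a merge run.
    """
    dwells: list[DwellEvent] = []
    cur_aoi: str | None = None
    cur_onset = cur_offset = 0.0
    cur_count = 0

    def flush() -> None:
        nonlocal cur_aoi, cur_count
        if cur_aoi is not None:
            dwells.append(DwellEvent(cur_aoi, cur_onset, cur_offset, cur_count))
        cur_aoi = None
        cur_count = 0

    for fx in fixations:
        aoi = layout.hit(fx.x, fx.y)
        if aoi is None:
            flush()
            continue
        if aoi == cur_aoi:
            cur_offset = fx.offset
            cur_count += 1
        else:
            flush()
            cur_aoi = aoi
            cur_onset, cur_offset, cur_count = fx.onset, fx.offset, 1
    flush()
    return dwells


def block_quality(stream) -> tuple[float, bool]:
    """(valid fraction, include flag). Inclusion requires at least 2/3 valid samples."""
    valid = np.asarray(stream.valid, dtype=bool)
    if valid.size == 0:
        return 0.0, False
    frac = float(valid.mean())
    return frac, frac >= QUALITY_THRESHOLD


@dataclass(frozen=True)
class ExclusionLedger:
    """Block-exclusion accounting. Flags are mutually exclusive, applied in
    priority order, so the survivor count is the total minus all exclusions."""

    total: int
    excluded: tuple[tuple[str, int], ...]
    survivors: int
    survivor_percent: int

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "excluded": dict(self.excluded),
            "survivors": self.survivors,
            "survivor_percent": self.survivor_percent,
        }


def exclusion_ledger(
    flags: Iterable[str | None],
    order: Sequence[str] = ("instruction_bug", "blink_bug", "quality"),
) -> ExclusionLedger:
    """Tally excluded blocks per reason and the surviving count.

    ``flags`` holds one entry per block: an exclusion reason or ``None``.
    Reasons outside ``order`` are appended in first-seen order.
    """
    counts: dict[str, int] = {r: 0 for r in order}
    total = 0
    for f in flags:
        total += 1
        if f is None:
            continue
        counts[f] = counts.get(f, 0) + 1
    excluded_total = sum(counts.values())
    survivors = total - excluded_total
    pct = int(round(100.0 * survivors / total)) if total else 0
    return ExclusionLedger(
        total=total,
        excluded=tuple((r, c) for r, c in counts.items()),
        survivors=survivors,
        survivor_percent=pct,
    )
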