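"""Default study configuration: timing laws, AOI transition matrices, layout.

The defaults reproduce the empirical parameter estimates from an adult
screen-based joint-attention study: eleven timing parameters (one duration
law each), AOI gaze-shift transition matrices for the object-oriented (OO)
and partner-oriented (PO) states, and an agent blink rate of about 17 blinks
per minute. They drive both the agent's behaviour and the synthetic
participant, so the estimation pipeline can be validated by parameter
recovery against known generating values.

The five macro states are: IJA (initiating joint attention), RJA
(responding to joint attention), and the non-interactive states PO
(partner-oriented), OO (object-oriented) and INT (introspective).
"""

from __future__ import annotations

import math

import numpy as np

from .distributions import DurationDistribution as _D
from .parsing import AOILayout

__all__ = [
    "AOI_LABELS",
    "OBJECT_AOIS",
    "AGENT_AOI",
    "OFF_TARGET",
    "MACRO_STATES",
    "PARAMETER_LABELS",
    "PARAMETER_DESCRIPTIONS",
    "DEFAULT_TIMING",
    "OO_TRANSITIONS",
    "PO_TRANSITIONS",
    "INT_LABELS",
    "INT_TRANSITIONS",
    "DEFAULT_BLINK_INTERVAL",
    "DEFAULT_LAYOUT",
    "OFF_ANCHOR",
    "PF_RJA_HIGH",
    "PF_RJA_LOW",
]

#: AOI labels: four household objects at left / up-left / right / up-right
#: plus the agent's face at screen centre.
AOI_LABELS = ("O1", "O2", "O3", "O4", "A")
OBJECT_AOIS = ("O1", "O2", "O3", "O4")
AGENT_AOI = "A"
#: Off-AOI gaze target (gaze lowered / averted), used by the introspective state.
OFF_TARGET = "OFF"

MACRO_STATES = ("IJA", "RJA", "PO", "OO", "INT")

#: Follow probabilities of the two responding-agent variants: the high variant
#: always follows the human's joint-attention bids, the low one in a third of cases.
PF_RJA_HIGH = 1.0
PF_RJA_LOW = 0.33

PARAMETER_LABELS = (
    "t_straight_IJA",
    "t_object_IJA",
    "t_back_IJA",
    "t_follow_RJA",
    "t_object_RJA",
    "t_object_PO",
    "t_agent_PO",
    "t_object_OO",
    "t_agent_OO",
    "t_object_INT",
    "t_agent_INT",
)

PARAMETER_DESCRIPTIONS = {
    "t_straight_IJA": "DT on partner before trying to initiate JA",
    "t_object_IJA": "RT after successful JA before gazing back at partner again",
    "t_back_IJA": "DT on object when trying to initiate JA, but partner is not following",
    "t_follow_RJA": "RT after which agent follows partner on AOI",
    "t_object_RJA": "DT on object after JA was successfully initiated",
    "t_object_PO": "DT on objects",
    "t_agent_PO": "DT on face",
    "t_object_OO": "DT on objects",
    "t_agent_OO": "DT on face",
    "t_object_INT": "DT on objects",
    "t_agent_INT": "DT on face",
}

#: Empirical duration laws for the eleven timing parameters (ms / log-ms).
DEFAULT_TIMING: dict[str, _D] = {
    "t_straight_IJA": _D("lnorm", 6.72, 0.46),
    "t_object_IJA": _D("lnorm", 6.50, 0.58),
    "t_back_IJA": _D("lnorm", 7.26, 0.44),
    "t_follow_RJA": _D("exgauss", 350.0, 34.2, 124.0),
    "t_object_RJA": _D("lnorm", 6.84, 0.27),
    "t_object_PO": _D("lnorm", 5.92, 0.53),
    "t_agent_PO": _D("norm", 2480.0, 1670.0),
    "t_object_OO": _D("exgauss", 566.0, 358.0, 824.0),
    "t_agent_OO": _D("lnorm", 6.27, 0.67),
    "t_object_INT": _D("lnorm", 6.04, 0.59),
    "t_agent_INT": _D("lnorm", 7.27, 1.04),
}


def _row_normalized(rows: list[list[float]]) -> np.ndarray:
    m = np.asarray(rows, dtype=float)
    sums = m.sum(axis=1, keepdims=True)
    return m / sums


# Published empirical AOI gaze-shift probabilities are rounded to two
# decimals, so some rows sum to 0.97..1.03; rows are renormalized here to be
# exactly stochastic. Order: O1, O2, O3, O4, A; the diagonal is structurally
# zero (a merged dwell cannot follow itself).
OO_TRANSITIONS = _row_normalized([
    [0.00, 0.65, 0.08, 0.09, 0.15],
    [0.38, 0.00, 0.50, 0.04, 0.08],
    [0.05, 0.45, 0.00, 0.43, 0.08],
    [0.15, 0.10, 0.55, 0.00, 0.23],
    [0.28, 0.31, 0.19, 0.21, 0.00],
])

PO_TRANSITIONS = _row_normalized([
    [0.00, 0.17, 0.01, 0.06, 0.76],
    [0.27, 0.00, 0.42, 0.02, 0.29],
    [0.00, 0.33, 0.00, 0.21, 0.46],
    [0.03, 0.01, 0.12, 0.00, 0.84],
    [0.35, 0.15, 0.07, 0.43, 0.00],
])

#: Introspective state: mostly off-AOI self-dwell with only occasional shifts
#: to the partner or an object (no published matrix; documented default).
INT_LABELS = (OFF_TARGET,) + AOI_LABELS
INT_TRANSITIONS = _row_normalized([
    # OFF   O1     O2     O3     O4     A
    [0.80, 0.025, 0.025, 0.025, 0.025, 0.10],  # OFF
    [0.80, 0.000, 0.040, 0.040, 0.040, 0.08],  # O1
    [0.80, 0.040, 0.000, 0.040, 0.040, 0.08],  # O2
    [0.80, 0.040, 0.040, 0.000, 0.040, 0.08],  # O3
    [0.80, 0.040, 0.040, 0.040, 0.000, 0.08],  # O4
    [0.80, 0.050, 0.050, 0.050, 0.050, 0.00],  # A
])

#: Inter-blink onset interval: log-normal with mean ~3,529 ms, i.e. ~17 blinks
#: per minute; the log-sd of 0.3 is a documented default.
DEFAULT_BLINK_INTERVAL = _D("lnorm", math.log(3529.0) - 0.5 * 0.3**2, 0.3)

#: Default AOI layout on a 1920x1080 canvas: agent face at centre, objects at
#: left, up-left, right and up-right (exact study coordinates are not public;
#: these are documented defaults).
DEFAULT_LAYOUT = AOILayout.from_dict({
    "A": [760, 340, 1160, 740],
    "O1": [80, 460, 440, 820],    # left
    "O2": [380, 10, 740, 370],    # up left
    "O3": [1480, 460, 1840, 820],  # right
    "O4": [1180, 10, 1540, 370],  # up right
})

#: Screen anchor for off-AOI (lowered) gaze; outside every default AOI.
OFF_ANCHOR = (960.0, 950.0)
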