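"""Stimulus encodings and input drives.

All inputs are Gaussian bumps over the node grid.  Exogenous stimuli (cues,
targets) drive the sensory field and decay exponentially in amplitude after
their (delayed) onset — they matter mainly when they appear.  Endogenous
inputs drive the decision field: a constant fixation preactivation at the
centre node and, optionally, temporal-expectation signals at every possible
target location whose amplitude ramps up linearly after the cue
(I(t) = I0 + m * t, the foreperiod effect).  Perceptual delays are pure time
shifts of drive onset: 70 ms for exogenous, 120 ms for endogenous input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "StimulusSpec",
    "gaussian_profile",
    "exogenous_drive",
    "expectation_drive",
    "fixation_drive",
    "FIXATION_NODE",
    "EXPECTATION_NODES",
]

logger = logging.getLogger(__name__)

FIXATION_NODE = 50
#: possible target locations in the two-alternative-plus-catch layout
EXPECTATION_NODES = (25, 50, 75)


def distribution_peak(I_max: float, sigma: float) -> float:
    """Peak of a stimulus of strength ``I_max`` and width ``sigma``.

    Stimuli are encoded as spatially normalized Gaussian distributions of
    excitation: the nominal strength I_max is spread over the bump, so the
    peak drive is I_max / (sigma * sqrt(2 pi)).  With the published
    amplitudes this puts the sensory field's response in the partially
    saturated range of its rate sigmoid (the cue habituates the field
    appreciably, yet an extra coincident stimulus still adds a little) and
    keeps the fixation and expectation inputs a genuinely small
    preactivation of the decision field.
    """
    return I_max / (sigma * math.sqrt(2.0 * math.pi))


# kept as an alias for internal callers
_endogenous_peak = distribution_peak


@dataclass
class StimulusSpec:
    """One input signal.

    ``kind`` routes the drive: ``exogenous`` enters the sensory field,
    ``fixation`` and ``expectation`` enter the decision field.  ``duration``
    is in ms; ``None`` means open-ended (targets stay on until the trial
    terminates).  Only exogenous stimuli decay.
    """

    kind: str
    center: int
    sigma: float
    I_max: float
    onset: float = 0.0
    duration: float | None = None
    decays: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("exogenous", "fixation", "expectation"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.onset < 0 and self.kind == "exogenous":
            raise ValueError("exogenous onset must be >= 0")
        if self.decays and self.kind != "exogenous":
            raise ValueError("only exogenous stimuli decay")


def cue_spec(center: int, onset: float = 0.0, I_max: float = 40.0,
             sigma: float = 8.0, duration: float = 50.0) -> StimulusSpec:
    return StimulusSpec("exogenous", center, sigma, I_max, onset, duration, decays=True)


def target_spec(center: int, onset: float, I_max: float = 60.0,
                sigma: float = 8.0, duration: float | None = None) -> StimulusSpec:
    return StimulusSpec("exogenous", center, sigma, I_max, onset, duration, decays=True)


def gaussian_profile(
    center: int, sigma: float, amplitude: float, n_nodes: int
) -> np.ndarray:
    """Gaussian bump exp(-(x-l)^2 / 2 sigma^2) peaking at ``amplitude``.

    Node labels are 1-based (1..n_nodes), matching the layout with cue/target
    at Nodes 25/75 and fixation at Node 50.
    """
    if not 1 <= center <= n_nodes:
        raise ValueError(f"center node {center} off the 1..{n_nodes} grid")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.arange(1, n_nodes + 1, dtype=float)
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def exogenous_drive(spec: StimulusSpec, t: float, params: ModelParams) -> np.ndarray:
    """Sensory-field drive of one exogenous stimulus at time ``t`` (ms).

    Zero before the delayed onset (onset + delay_exo) and, for finite
    durations, from (delayed onset + duration) on.  While active the
    strength is I_max * exp(-beta_stim * tau) with tau the time in seconds
    since the delayed onset (beta_stim is printed in 1/s, so the decay is
    slow relative to a 50 ms cue).
    """
    if spec.kind != "exogenous":
        raise ValueError("exogenous_drive expects an exogenous spec")
    n = params.n_nodes
    arrival = spec.onset + params.delay_exo
    if t < arrival:
        return np.zeros(n)
    if spec.duration is not None and t >= arrival + spec.duration:
        return np.zeros(n)
    tau = t - arrival
    amp = spec.I_max
    if spec.decays:
        amp *= math.exp(-params.beta_stim * tau / 1000.0)
    return gaussian_profile(
        spec.center, spec.sigma, distribution_peak(amp, spec.sigma), n
    )


def expectation_amplitude(cue_onset: float, t: float, params: ModelParams) -> float:
    """Ramp amplitude I0 + m * tau, tau in s since the (delayed) ramp start.

    The ramp clock is referenced to cue onset — the conditional probability
    of target appearance rises during the post-cue interval — and the whole
    time course is shifted by the endogenous delay.
    """
    start = cue_onset + params.delay_endo
    if t < start:
        return 0.0
    return params.I0 + params.m * (t - start) / 1000.0


def expectation_drive(
    target_locations,
    cue_onset: float,
    t: float,
    params: ModelParams,
    sigma: float = 8.0,
) -> np.ndarray:
    """Summed expectation bumps at every possible target location."""
    n = params.n_nodes
    locations = tuple(target_locations)
    if len(locations) == 0:
        logger.warning("expectation_drive called with no target locations")
        return np.zeros(n)
    amp = expectation_amplitude(cue_onset, t, params)
    if amp == 0.0:
        return np.zeros(n)
    peak = _endogenous_peak(amp, sigma)
    out = np.zeros(n)
    for loc in locations:
        out += gaussian_profile(loc, sigma, peak, n)
    return out


def fixation_drive(
    t: float,
    params: ModelParams,
    onset: float = 0.0,
    center: int = FIXATION_NODE,
    sigma: float = 4.0,
    I_max: float = 10.0,
) -> np.ndarray:
    """Constant fixation preactivation at the centre node, after delay_endo."""
    if t < onset + params.delay_endo:
        return np.zeros(params.n_nodes)
    return gaussian_profile(center, sigma, _endogenous_peak(I_max, sigma), params.n_nodes)
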