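"""Trial simulation: Euler integration, threshold crossing, reaction times.

A trial runs on a millisecond clock with cue onset at t = 0 and target onset
at t = CTOA.  A configurable fixation-only warm-up precedes the cue so the
decision field starts from its fixation-driven steady state rather than from
the bare resting level.  Integration is first-order Euler with a 5 ms step.
A response is triggered at the first step where any node's external decision
activation reaches the threshold; the reaction time is the crossing time
minus the physical target onset plus the motor delay, quantized to the
integration grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    FieldState,
    decision_rate,
    field_derivatives,
    lateral_interaction,
    mexican_hat_weights,
    sensory_rate,
)
from .params import ModelParams
from .stimuli import (
    EXPECTATION_NODES,
    FIXATION_NODE,
    _endogenous_peak,
    expectation_amplitude,
    gaussian_profile,
)

__all__ = ["TrialSpec", "TrialResult", "euler_step", "run_trial"]

logger = logging.getLogger(__name__)


@dataclass
class TrialSpec:
    """Cue/target placement and timing for one trial.

    A trial is *cued* when ``cue_node == target_node``.  ``ctoa`` is the
    cue-target onset asynchrony in ms.  ``max_time`` is the safety horizon
    after target onset; ``warmup`` the fixation-only settling period before
    cue onset.  ``terminate_on_threshold=False`` lets the stimuli run their
    course (used by the habituation protocol, which measures sensory peaks,
    not reaction times).
    """

    cue_node: int = 25
    target_node: int = 25
    ctoa: float = 0.0
    cue_duration: float = 50.0
    cue_I_max: float = 40.0
    target_I_max: float = 60.0
    # exogenous stimuli decay slowly (beta_stim is in 1/s) after arrival
    cue_decays: bool = True
    target_decays: bool = True
    target_duration: float | None = None  # None: until threshold / horizon
    stim_sigma: float = 8.0
    expectation_enabled: bool = True
    fixation_enabled: bool = True
    cue_enabled: bool = True
    target_enabled: bool = True
    terminate_on_threshold: bool = True
    max_time: float = 3000.0
    warmup: float = 500.0
    expectation_nodes: tuple = EXPECTATION_NODES

    def __post_init__(self) -> None:
        if self.ctoa < 0:
            raise ValueError("ctoa must be >= 0")

    @property
    def cued(self) -> bool:
        return self.cue_node == self.target_node


@dataclass
class TrialResult:
    """Outcome of one simulated trial.

    ``rt`` is absent (None) when no node crossed the threshold before the
    horizon.  ``peak_target_rate`` is the post-target-onset maximum of the
    external sensory activation at the target node (the habituation-protocol
    readout).  ``traces``, when recorded, maps names to arrays over the step
    grid: ``t``, field profiles ``D``/``S``/``H`` and rates ``a_D``/``a_S``
    (steps x nodes), and the scalar ``expectation_amplitude`` series.
    """

    responded: bool
    rt: float | None
    crossing_time: float | None
    crossing_node: int | None
    peak_target_rate: float
    traces: dict | None = None
    spec: TrialSpec | None = None


def euler_step(
    state: FieldState,
    drives: tuple[np.ndarray, np.ndarray],
    params: ModelParams,
    kernel: np.ndarray | None = None,
) -> FieldState:
    """One first-order Euler step: state + dt * field_derivatives.

    ``drives`` is (endogenous drive to D, exogenous drive to S).  H is only
    clamped as a guard — the dynamics keep it inside [0, 1] intrinsically —
    and any clamp is logged.
    """
    inputs_D, inputs_S = drives
    dD, dS, dH = field_derivatives(state, inputs_D, inputs_S, params, kernel)
    dt = params.dt
    D = state.D + dt * dD
    S = state.S + dt * dS
    H = state.H + dt * dH
    for arr, name in ((D, "D"), (S, "S"), (H, "H")):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                f"non-finite {name} profile at t={state.t + dt} ms; "
                f"state dump: D={state.D}, S={state.S}, H={state.H}"
            )
    if np.any(H < 0.0) or np.any(H > 1.0):
        logger.warning("habituation left [0, 1] at t=%s ms; clamping", state.t + dt)
        H = np.clip(H, 0.0, 1.0)
    return FieldState(state.t + dt, D, S, H)


def run_trial(
    trial: TrialSpec,
    params: ModelParams,
    record: bool = False,
) -> TrialResult:
    """Simulate one trial and return its reaction time and readouts.

    Deterministic: identical spec and parameters give bit-identical results.
    """
    n = params.n_nodes
    dt = params.dt
    kernel = mexican_hat_weights(params)

    for node in (trial.cue_node, trial.target_node):
        if not 1 <= node <= n:
            raise ValueError(f"node {node} off the 1..{n} grid")

    # unit-strength spatial shapes (normalized-distribution peaks), scaled
    # per step by scalar stimulus strengths
    cue_shape = gaussian_profile(
        trial.cue_node, trial.stim_sigma, _endogenous_peak(1.0, trial.stim_sigma), n
    )
    target_shape = gaussian_profile(
        trial.target_node, trial.stim_sigma, _endogenous_peak(1.0, trial.stim_sigma), n
    )
    fix_shape = gaussian_profile(FIXATION_NODE, 4.0, _endogenous_peak(10.0, 4.0), n)
    if trial.expectation_enabled and len(trial.expectation_nodes) > 0:
        exp_shape = np.zeros(n)
        for loc in trial.expectation_nodes:
            exp_shape += gaussian_profile(
                loc, trial.stim_sigma, _endogenous_peak(1.0, trial.stim_sigma), n
            )
    else:
        exp_shape = None

    cue_arrival = 0.0 + params.delay_exo
    cue_off = cue_arrival + trial.cue_duration
    target_onset = trial.ctoa
    target_arrival = target_onset + params.delay_exo
    target_off = (
        None if trial.target_duration is None else target_arrival + trial.target_duration
    )
    fix_on = -trial.warmup + params.delay_endo

    t0 = -trial.warmup
    t_end = target_onset + trial.max_time
    n_steps = int(round((t_end - t0) / dt))

    state = FieldState.resting(params, t=t0)
    D, S, H = state.D, state.S, state.H
    a_D = decision_rate(D, params)
    a_S = sensory_rate(S, H, params)

    tau_D_ms, tau_S_ms, tau_H_ms = params.tau_D_ms, params.tau_S_ms, params.tau_H_ms
    target_idx = trial.target_node - 1

    responded = False
    crossing_time = crossing_node = None
    peak_target_rate = 0.0

    if record:
        times, trD, trS, trH, traD, traS, trExp = [], [], [], [], [], [], []

    def drives_at(t: float) -> tuple[np.ndarray, np.ndarray, float]:
        inputs_S = np.zeros(n)
        if trial.cue_enabled and cue_arrival <= t < cue_off:
            amp = trial.cue_I_max
            if trial.cue_decays:
                amp *= np.exp(-params.beta_stim * (t - cue_arrival) / 1000.0)
            inputs_S += cue_shape * amp
        if trial.target_enabled and t >= target_arrival and (
            target_off is None or t < target_off
        ):
            amp = trial.target_I_max
            if trial.target_decays:
                amp *= np.exp(-params.beta_stim * (t - target_arrival) / 1000.0)
            inputs_S += target_shape * amp
        inputs_D = (
            fix_shape if (trial.fixation_enabled and t >= fix_on) else np.zeros(n)
        )
        exp_amp = 0.0
        if exp_shape is not None:
            exp_amp = expectation_amplitude(0.0, t, params)
            if exp_amp != 0.0:
                inputs_D = inputs_D + exp_shape * exp_amp
        return inputs_D, inputs_S, exp_amp

    t = t0
    if record:
        _, _, e0 = drives_at(t)
        times.append(t); trD.append(D.copy()); trS.append(S.copy())
        trH.append(H.copy()); traD.append(a_D.copy()); traS.append(a_S.copy())
        trExp.append(e0)

    clamped = False
    for _ in range(n_steps):
        inputs_D, inputs_S, exp_amp = drives_at(t)
        lat = lateral_interaction(a_D, kernel, params.boundary)
        D = D + dt * ((-D + params.h_D + lat + params.w_SD * a_S + inputs_D) / tau_D_ms)
        S = S + dt * ((-S + params.h_S + inputs_S) / tau_S_ms)
        H = H + dt * ((-H + params.h_H + params.k_H * a_S * (1.0 - H)) / tau_H_ms)
        t += dt

        if not (np.all(np.isfinite(D)) and np.all(np.isfinite(S)) and np.all(np.isfinite(H))):
            raise FloatingPointError(f"non-finite field state at t={t} ms")
        if np.any(H < 0.0) or np.any(H > 1.0):
            if not clamped:
                logger.warning("habituation left [0, 1] at t=%s ms; clamping", t)
                clamped = True
            H = np.clip(H, 0.0, 1.0)

        a_D = decision_rate(D, params)
        a_S = sensory_rate(S, H, params)

        if record:
            _, _, e = drives_at(t)
            times.append(t); trD.append(D.copy()); trS.append(S.copy())
            trH.append(H.copy()); traD.append(a_D.copy()); traS.append(a_S.copy())
            trExp.append(e)

        if trial.target_enabled and t >= target_onset:
            if a_S[target_idx] > peak_target_rate:
                peak_target_rate = float(a_S[target_idx])

        if not responded and np.max(a_D) >= params.threshold:
            responded = True
            crossing_time = t
            crossing_node = int(np.argmax(a_D)) + 1
            if trial.terminate_on_threshold:
                break

    rt = None
    if responded:
        rt = crossing_time - target_onset + params.delay_motor

    traces = None
    if record:
        traces = {
            "t": np.asarray(times),
            "D": np.asarray(trD),
            "S": np.asarray(trS),
            "H": np.asarray(trH),
            "a_D": np.asarray(traD),
            "a_S": np.asarray(traS),
            "expectation_amplitude": np.asarray(trExp),
        }

    return TrialResult(
        responded=responded,
        rt=rt,
        crossing_time=crossing_time,
        crossing_node=crossing_node,
        peak_target_rate=peak_target_rate,
        traces=traces,
        spec=trial,
    )
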