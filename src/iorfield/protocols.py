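"""Experiment protocols: CTOA sweeps, habituation curve, component traces.

Three standard protocols are provided.  ``ior_sweep`` runs cued and uncued
trials over a list of cue-target onset asynchronies and assembles the
inhibition statistic RT_cued - RT_uncued (negative values are facilitation,
positive values inhibition of return).  ``habituation_sweep`` measures the
sensory depression directly: for a dense CTOA grid it records the peak
target-induced sensory rate at the target locus, with a 50 ms cue and a
500 ms target both at exogenous strength 60 and no threshold termination.
``trace_report`` extracts the six per-locus component time series (D, S,
expectation strength, a_D, a_S, H) that summarize the model's functioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .simulate import TrialSpec, TrialResult, run_trial

__all__ = [
    "IORCurve",
    "HabituationCurve",
    "ior_sweep",
    "habituation_sweep",
    "trace_report",
    "DEFAULT_CTOAS",
    "CUE_NODE",
    "UNCUED_TARGET_NODE",
]

#: the six cue-target onset asynchronies of the reference experiment (ms)
DEFAULT_CTOAS = (0.0, 50.0, 100.0, 200.0, 300.0, 500.0)
CUE_NODE = 25
UNCUED_TARGET_NODE = 75


@dataclass
class IORCurve:
    """Per-CTOA cued/uncued reaction times and the inhibition statistic."""

    ctoas: np.ndarray
    rt_cued: np.ndarray
    rt_uncued: np.ndarray
    no_response: np.ndarray  # flags CTOAs where either trial failed to cross

    def __post_init__(self) -> None:
        self.ctoas = np.asarray(self.ctoas, dtype=float)
        self.rt_cued = np.asarray(self.rt_cued, dtype=float)
        self.rt_uncued = np.asarray(self.rt_uncued, dtype=float)
        self.no_response = np.asarray(self.no_response, dtype=bool)
        if not (
            len(self.ctoas) == len(self.rt_cued) == len(self.rt_uncued)
            == len(self.no_response)
        ):
            raise ValueError("curve columns must share one length")

    @property
    def inhibition(self) -> np.ndarray:
        """RT_cued - RT_uncued per CTOA (ms); NaN where a trial timed out."""
        return self.rt_cued - self.rt_uncued

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: ctoa, condition, rt, inhibition."""
        rows = []
        for i, ctoa in enumerate(self.ctoas):
            for cond, rt in (("cued", self.rt_cued[i]), ("uncued", self.rt_uncued[i])):
                rows.append(
                    {
                        "ctoa": ctoa,
                        "condition": cond,
                        "rt": rt,
                        "inhibition": self.inhibition[i],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class HabituationCurve:
    """Peak target-induced sensory rate at the target locus, per CTOA."""

    ctoas: np.ndarray
    peak_rate: np.ndarray

    def __post_init__(self) -> None:
        self.ctoas = np.asarray(self.ctoas, dtype=float)
        self.peak_rate = np.asarray(self.peak_rate, dtype=float)
        if len(self.ctoas) != len(self.peak_rate):
            raise ValueError("curve columns must share one length")
        if np.any(self.peak_rate < 0) or np.any(self.peak_rate > 1):
            raise ValueError("peak rates must lie in [0, 1]")

    @property
    def minimum_ctoa(self) -> float:
        """CTOA at which the target-induced peak rate is smallest."""
        return float(self.ctoas[int(np.argmin(self.peak_rate))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ctoa": self.ctoas, "peak_rate": self.peak_rate})


def _trial(ctoa: float, cued: bool, expectation: bool, **kw) -> TrialSpec:
    target = CUE_NODE if cued else UNCUED_TARGET_NODE
    return TrialSpec(
        cue_node=CUE_NODE,
        target_node=target,
        ctoa=ctoa,
        expectation_enabled=expectation,
        **kw,
    )


def ior_sweep(
    ctoas=DEFAULT_CTOAS,
    params: ModelParams | None = None,
    expectation_enabled: bool = True,
) -> IORCurve:
    """Run cued and uncued trials for each CTOA and assemble the IOR curve.

    Cued trials place cue and target at the same peripheral node, uncued
    trials at opposite peripheral nodes; the catch-trial location (the
    fixation node) is never used as a target.  Trials that fail to cross the
    threshold before the horizon are flagged and yield NaN reaction times.
    """
    ctoas = list(ctoas)
    if len(ctoas) == 0:
        raise ValueError("ctoas must be nonempty")
    params = params or ModelParams()
    rt_c, rt_u, flags = [], [], []
    for ctoa in ctoas:
        rc = run_trial(_trial(ctoa, True, expectation_enabled), params)
        ru = run_trial(_trial(ctoa, False, expectation_enabled), params)
        rt_c.append(np.nan if rc.rt is None else rc.rt)
        rt_u.append(np.nan if ru.rt is None else ru.rt)
        flags.append(rc.rt is None or ru.rt is None)
    return IORCurve(np.asarray(ctoas, float), rt_c, rt_u, flags)


def habituation_sweep(
    params: ModelParams | None = None,
    ctoas=None,
    stim_I_max: float = 60.0,
    cue_duration: float = 50.0,
    target_duration: float = 500.0,
) -> HabituationCurve:
    """Sensory-depression protocol: peak a_S at the target locus per CTOA.

    Cued trials with a ``cue_duration`` cue and a ``target_duration`` target,
    both at exogenous strength ``stim_I_max``; threshold termination is
    suppressed so the target always runs its full course.  The default grid
    spans 0-4000 ms in 10 ms increments (401 points).
    """
    params = params or ModelParams()
    if ctoas is None:
        ctoas = np.arange(0.0, 4000.0 + 1e-9, 10.0)
    ctoas = np.asarray(ctoas, dtype=float)
    peaks = np.empty(len(ctoas))
    horizon = params.delay_exo + target_duration + 200.0
    for i, ctoa in enumerate(ctoas):
        spec = _trial(
            ctoa,
            cued=True,
            expectation=True,
            cue_I_max=stim_I_max,
            target_I_max=stim_I_max,
            cue_duration=cue_duration,
            target_duration=target_duration,
            terminate_on_threshold=False,
            max_time=horizon,
        )
        peaks[i] = run_trial(spec, params).peak_target_rate
    return HabituationCurve(ctoas, peaks)


def trace_report(
    trial: TrialSpec,
    params: ModelParams | None = None,
    loci: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Per-locus component time series for one trial.

    Returns a tidy frame with columns t, node, D, S, H, a_D, a_S and the
    scalar expectation strength; by default the traced locus is the target
    node x0.
    """
    params = params or ModelParams()
    if loci is None:
        loci = (trial.target_node,)
    for locus in loci:
        if not 1 <= locus <= params.n_nodes:
            raise ValueError(f"locus {locus} off the 1..{params.n_nodes} grid")
    result = run_trial(trial, params, record=True)
    tr = result.traces
    frames = []
    for locus in loci:
        i = locus - 1
        frames.append(
            pd.DataFrame(
                {
                    "t": tr["t"],
                    "node": locus,
                    "D": tr["D"][:, i],
                    "S": tr["S"][:, i],
                    "H": tr["H"][:, i],
                    "a_D": tr["a_D"][:, i],
                    "a_S": tr["a_S"][:, i],
                    "expectation_strength": tr["expectation_amplitude"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def component_overview(
    params: ModelParams | None = None,
    ctoas=(25.0, 75.0, 500.0),
) -> pd.DataFrame:
    """Cued and uncued component traces at representative CTOAs.

    Mirrors the standard component-by-component overview: for each CTOA the
    six series are extracted at the target locus for both conditions.
    """
    params = params or ModelParams()
    frames = []
    for ctoa in ctoas:
        for cued in (True, False):
            spec = _trial(ctoa, cued, expectation=True, terminate_on_threshold=False,
                          max_time=1200.0)
            df = trace_report(spec, params, loci=(spec.target_node,))
            df["ctoa"] = ctoa
            df["condition"] = "cued" if cued else "uncued"
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
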