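"""Model parameters and their (de)serialization.

All named constants of the field dynamics, the rate transforms, the lateral
interaction kernel, the stimulus encodings, the expectation ramp, the
numerical grid and the perceptual/motor delays live here.  Time constants
``tau_D``, ``tau_S`` and ``tau_H`` are stored in seconds; the integrator and
all onsets/delays work in milliseconds, so the ``tau_*_ms`` properties carry
the single documented unit conversion.  ``beta_stim`` is a per-millisecond
exponential decay rate of exogenous stimulus amplitude, and ``m`` is the
expectation-ramp slope in amplitude units per second.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ModelParams", "load_params", "save_params", "default_params_path"]

_MS_PER_S = 1000.0


@dataclass
class ModelParams:
    # field time constants (seconds)
    tau_D: float = 0.328
    tau_S: float = 0.048
    tau_H: float = 1.620
    # resting levels
    h_D: float = -30.0
    h_S: float = -1.0
    h_H: float = 0.0
    # rate-transform sigmoids
    beta_D: float = 1.4
    beta_S: float = 6.0
    D0: float = 0.0
    S0: float = 0.0
    # habituation asymmetry (fast build-up vs slow decay)
    k_H: float = 7.0
    # Mexican-hat kernel: a*exp(-d^2/2sa^2) - b*exp(-d^2/2sb^2) - c
    a: float = 11.0
    b: float = 4.5
    c: float = 1.0
    sigma_a: float = 4.0
    sigma_b: float = 7.0
    # sensory -> decision 1-to-1 projection gain
    w_SD: float = 95.0
    # exogenous amplitude decay rate (per ms)
    beta_stim: float = 0.07
    # expectation ramp: amplitude = I0 + m * t_seconds
    m: float = 50.0
    I0: float = 18.0
    # numerical grid
    n_nodes: int = 100
    dt: float = 5.0  # ms
    # decision criterion on the external decision activation
    threshold: float = 0.8
    # perceptual and motor delays (ms)
    delay_exo: float = 70.0
    delay_endo: float = 120.0
    delay_motor: float = 80.0
    # convolution boundary rule: "zero" (bounded retinotopic strip) or
    # "circular" (sensitivity checks only)
    boundary: str = "zero"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("tau_D", "tau_S", "tau_H"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if not (self.sigma_a > 0 and self.sigma_b > 0):
            raise ValueError("kernel widths sigma_a, sigma_b must be > 0")
        if self.boundary not in ("zero", "circular"):
            raise ValueError(f"unknown boundary rule {self.boundary!r}")

    # -- unit conversions -------------------------------------------------
    @property
    def tau_D_ms(self) -> float:
        return self.tau_D * _MS_PER_S

    @property
    def tau_S_ms(self) -> float:
        return self.tau_S * _MS_PER_S

    @property
    def tau_H_ms(self) -> float:
        return self.tau_H * _MS_PER_S

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        conv = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if f.type in ("float", float):
                v = float(v)
            elif f.type in ("int", int):
                v = int(v)
            conv[f.name] = v
        return cls(**conv)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a flat key-value YAML file.

    Numeric values are written as decimal strings so the file round-trips
    bit-exactly (YAML float re-parsing can otherwise drift).
    """
    out = {}
    for k, v in params.to_dict().items():
        out[k] = repr(v) if isinstance(v, float) else v
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def load_params(path: str | Path) -> ModelParams:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must hold a mapping")
    return ModelParams.from_dict(raw)


def default_params_path() -> Path:
    """Path of the shipped default-parameter file."""
    return Path(__file__).parent / "data" / "default_params.yaml"
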