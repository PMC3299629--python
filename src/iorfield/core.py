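"""Field dynamics: rate transforms, lateral interaction, and derivatives.

Three coupled activation fields are defined over a 1-D grid of ``n_nodes``
equidistant nodes (labelled 1..n): a decision field ``D`` (superior-colliculus
intermediate-layer-like accumulator), a sensory field ``S`` (earlier sensory
processing), and a habituation field ``H`` that gates the sensory rate.  The
dynamics are

    tau_D dD/dt = -D + h_D + [W * a_D](x) + w_SD * a_S(x) + I_endo(x, t)
    tau_S dS/dt = -S + h_S + I_exo(x, t)
    tau_H dH/dt = -H + h_H + k_H * a_S(x) * (1 - H)

with rate transforms

    a_D = 1 / (1 + exp(-beta_D (D - D0)))
    a_S = (1 - H) / (1 + exp(-beta_S (S - S0)))

and a Mexican-hat kernel W(d) = a e^{-d^2/2 sigma_a^2} - b e^{-d^2/2 sigma_b^2} - c.

The habituation drive k_H * a_S * (1 - H) gives a build-up time constant of
tau_H / (1 + k_H) while the field is spiking, against the full tau_H for
decay, and keeps H inside [0, 1] without clamping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "FieldState",
    "decision_rate",
    "sensory_rate",
    "mexican_hat_weights",
    "lateral_interaction",
    "field_derivatives",
]


@dataclass
class FieldState:
    """Internal activations of the three fields at one instant.

    ``t`` is simulation time in ms; ``D``, ``S``, ``H`` are profiles of equal
    length over the node grid.
    """

    t: float
    D: np.ndarray
    S: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if not (self.D.shape == self.S.shape == self.H.shape):
            raise ValueError("D, S, H profiles must share one length")

    @classmethod
    def resting(cls, params: ModelParams, t: float = 0.0) -> "FieldState":
        n = params.n_nodes
        return cls(
            t=t,
            D=np.full(n, params.h_D),
            S=np.full(n, params.h_S),
            H=np.full(n, params.h_H),
        )

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.D.copy(), self.S.copy(), self.H.copy())


def _check_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def decision_rate(D_profile: np.ndarray, params: ModelParams) -> np.ndarray:
    """External activation (spike rate) of the decision field, in (0, 1)."""
    D = _check_finite(D_profile, "decision profile")
    # logistic written via exp of the negative argument; overflow-safe form
    z = params.beta_D * (D - params.D0)
    return _stable_logistic(z)


def sensory_rate(
    S_profile: np.ndarray, H_profile: np.ndarray, params: ModelParams
) -> np.ndarray:
    """External activation of the sensory field, gated by habituation.

    With H = 0 the achievable maximum is 1; as H approaches 1 the maximum
    achievable rate falls toward 0.
    """
    S = _check_finite(S_profile, "sensory profile")
    H = np.asarray(H_profile, dtype=float)
    if np.any(H < 0) or np.any(H > 1):
        raise ValueError("habituation profile outside [0, 1]")
    z = params.beta_S * (S - params.S0)
    return (1.0 - H) * _stable_logistic(z)


def _stable_logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def mexican_hat_weights(params: ModelParams) -> np.ndarray:
    """Lateral-interaction kernel over signed node distances -(n-1)..(n-1).

    Double-Gaussian Mexican hat minus a constant global-inhibition term:
    excitatory near d = 0, inhibitory at large distance.
    """
    for name in ("a", "b", "c", "sigma_a", "sigma_b"):
        if not np.isfinite(getattr(params, name)):
            raise ValueError(f"kernel constant {name} must be finite")
    if params.sigma_a <= 0 or params.sigma_b <= 0:
        raise ValueError("kernel widths must be strictly positive")
    n = params.n_nodes
    d = np.arange(-(n - 1), n, dtype=float)
    return (
        params.a * np.exp(-(d**2) / (2.0 * params.sigma_a**2))
        - params.b * np.exp(-(d**2) / (2.0 * params.sigma_b**2))
        - params.c
    )


def lateral_interaction(
    rate_profile: np.ndarray, kernel: np.ndarray, boundary: str = "zero"
) -> np.ndarray:
    """Convolve a rate profile with the lateral kernel.

    ``kernel`` must cover distances -(n-1)..(n-1) for an n-node profile.
    The default boundary rule is zero padding (the field is a bounded strip);
    ``circular`` wraps the grid for sensitivity checks.
    """
    r = np.asarray(rate_profile, dtype=float)
    n = r.shape[0]
    if kernel.shape[0] != 2 * n - 1:
        raise ValueError(
            f"kernel length {kernel.shape[0]} does not match profile length {n}"
        )
    if boundary == "zero":
        return np.convolve(r, kernel, mode="full")[n - 1 : 2 * n - 1]
    if boundary == "circular":
        full = np.convolve(np.tile(r, 3), kernel, mode="full")
        return full[2 * n - 1 : 3 * n - 1]
    raise ValueError(f"unknown boundary rule {boundary!r}")


def field_derivatives(
    state: FieldState,
    inputs_D: np.ndarray,
    inputs_S: np.ndarray,
    params: ModelParams,
    kernel: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (per ms) of the three fields.

    ``inputs_D`` is the summed endogenous drive to the decision field
    (fixation + expectation); ``inputs_S`` is the summed exogenous drive to
    the sensory field (cue + target).
    """
    n = state.D.shape[0]
    inputs_D = np.asarray(inputs_D, dtype=float)
    inputs_S = np.asarray(inputs_S, dtype=float)
    if inputs_D.shape[0] != n or inputs_S.shape[0] != n:
        raise ValueError("input profiles must match the field length")
    if kernel is None:
        kernel = mexican_hat_weights(params)

    a_D = decision_rate(state.D, params)
    a_S = sensory_rate(state.S, state.H, params)
    lat = lateral_interaction(a_D, kernel, params.boundary)

    dD = (-state.D + params.h_D + lat + params.w_SD * a_S + inputs_D) / params.tau_D_ms
    dS = (-state.S + params.h_S + inputs_S) / params.tau_S_ms
    dH = (-state.H + params.h_H + params.k_H * a_S * (1.0 - state.H)) / params.tau_H_ms
    return dD, dS, dH
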