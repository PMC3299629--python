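import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iorfield import (
    FieldState,
    ModelParams,
    decision_rate,
    field_derivatives,
    lateral_interaction,
    mexican_hat_weights,
    sensory_rate,
)


class TestDecisionRate:
    def test_saturates_at_extremes(self, params):
        rate = decision_rate(np.array([-1e3, 1e3]), params)
        assert rate[0] == pytest.approx(0.0, abs=1e-12)
        assert rate[1] == pytest.approx(1.0, abs=1e-12)

    def test_midpoint_at_offset(self, params):
        assert decision_rate(np.array([params.D0]), params)[0] == pytest.approx(0.5)

    def test_strictly_inside_unit_interval_and_monotone(self, params):
        D = np.linspace(-20, 20, 201)
        rate = decision_rate(D, params)
        assert np.all(rate > 0) and np.all(rate < 1)
        assert np.all(np.diff(rate) >= 0)

    def test_rejects_non_finite(self, params):
        with pytest.raises(ValueError, match="non-finite"):
            decision_rate(np.array([0.0, np.nan]), params)


class TestSensoryRate:
    def test_maximum_is_one_without_habituation(self, params):
        rate = sensory_rate(np.array([1e3]), np.array([0.0]), params)
        assert rate[0] == pytest.approx(1.0, abs=1e-12)

    def test_scalar_oracle(self, params):
        # direct evaluation of the rate formula at S=2, H=0.5
        expected = (1.0 - 0.5) / (1.0 + math.exp(-params.beta_S * 2.0))
        got = sensory_rate(np.array([2.0]), np.array([0.5]), params)[0]
        assert got == pytest.approx(expected, rel=1e-12)

    @given(
        s=st.floats(-20, 20),
        h1=st.floats(0, 1),
        h2=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_habituation(self, s, h1, h2):
        params = ModelParams()
        lo, hi = sorted([h1, h2])
        r_lo = sensory_rate(np.array([s]), np.array([lo]), params)[0]
        r_hi = sensory_rate(np.array([s]), np.array([hi]), params)[0]
        assert r_lo >= r_hi

    def test_monotone_increasing_in_activation(self, params):
        S = np.linspace(-10, 10, 101)
        H = np.full_like(S, 0.3)
        rate = sensory_rate(S, H, params)
        assert np.all(np.diff(rate) >= 0)

    def test_rejects_habituation_outside_unit_interval(self, params):
        with pytest.raises(ValueError, match="habituation"):
            sensory_rate(np.array([0.0]), np.array([1.5]), params)


class TestMexicanHat:
    def test_symmetric_in_distance(self, params):
        w = mexican_hat_weights(params)
        assert np.allclose(w, w[::-1])

    def test_center_value(self, params):
        # a - b - c with the published constants
        w = mexican_hat_weights(params)
        center = w[params.n_nodes - 1]
        assert center == pytest.approx(params.a - params.b - params.c)
        assert center == pytest.approx(5.5)

    def test_excitatory_near_inhibitory_far(self, params):
        w = mexican_hat_weights(params)
        d = np.arange(-(params.n_nodes - 1), params.n_nodes)
        assert w[d == 0][0] > 0
        far = np.abs(d) > 5 * params.sigma_b
        # both Gaussians have vanished: only the constant inhibition remains
        assert np.allclose(w[far], -params.c, atol=1e-8)

    def test_rejects_nonpositive_widths(self, params):
        bad = params.to_dict()
        bad["sigma_b"] = 0.0
        with pytest.raises(ValueError):
            ModelParams.from_dict(bad)


class TestLateralInteraction:
    def test_zero_rates_give_zero_output(self, params):
        kernel = mexican_hat_weights(params)
        out = lateral_interaction(np.zeros(params.n_nodes), kernel)
        assert np.all(out == 0)

    def test_impulse_reproduces_kernel(self, params):
        n = params.n_nodes
        kernel = mexican_hat_weights(params)
        r = np.zeros(n)
        j = 30
        r[j] = 1.0
        out = lateral_interaction(r, kernel)
        # zero-padded convolution: output x = W(x - j)
        d = np.arange(n) - j
        assert np.allclose(out, kernel[d + n - 1])

    def test_matches_direct_double_sum(self, params):
        n = params.n_nodes
        kernel = mexican_hat_weights(params)
        rng = np.random.default_rng(7)
        for _ in range(20):
            r = rng.random(n)
            out = lateral_interaction(r, kernel)
            brute = np.zeros(n)
            for x in range(n):
                for xp in range(n):
                    brute[x] += kernel[(x - xp) + n - 1] * r[xp]
            assert np.allclose(out, brute, atol=1e-10)

    def test_circular_boundary_wraps(self, params):
        n = params.n_nodes
        kernel = mexican_hat_weights(params)
        r = np.zeros(n)
        r[0] = 1.0
        out = lateral_interaction(r, kernel, boundary="circular")
        # with wrap-around the last node interacts with the impulse along
        # both arcs of the ring: distance 1 and distance n - 1
        assert out[-1] == pytest.approx(kernel[n] + kernel[0], abs=1e-12)

    def test_rejects_length_mismatch(self, params):
        with pytest.raises(ValueError, match="kernel length"):
            lateral_interaction(np.zeros(10), mexican_hat_weights(params))


class TestFieldDerivatives:
    def test_near_fixed_point_at_nominal_rest(self, params):
        state = FieldState.resting(params)
        zeros = np.zeros(params.n_nodes)
        dD, dS, dH = field_derivatives(state, zeros, zeros, params)
        # the rate sigmoids never vanish exactly, so the nominal resting
        # levels are a fixed point only up to the residual resting rates
        assert np.abs(dD).max() < 1e-2
        assert np.abs(dS).max() < 1e-12
        assert np.abs(dH).max() < 1e-4

    def test_self_consistent_rest_is_fixed_point(self, params):
        # relax without input, then check the derivatives truly vanish
        state = FieldState.resting(params)
        zeros = np.zeros(params.n_nodes)
        kernel = mexican_hat_weights(params)
        for _ in range(int(30_000 / params.dt)):
            dD, dS, dH = field_derivatives(state, zeros, zeros, params, kernel)
            state = FieldState(
                state.t + params.dt,
                state.D + params.dt * dD,
                state.S + params.dt * dS,
                state.H + params.dt * dH,
            )
        dD, dS, dH = field_derivatives(state, zeros, zeros, params, kernel)
        for d in (dD, dS, dH):
            assert np.abs(d).max() < 1e-6
        # and the relaxed state sits close to the nominal resting levels
        assert np.abs(state.D - params.h_D).max() < 0.5
        assert np.abs(state.S - params.h_S).max() < 1e-6
        assert np.abs(state.H - params.h_H).max() < 0.05

    def test_habituation_decays_when_sensory_silent(self, params):
        n = params.n_nodes
        state = FieldState(0.0, np.full(n, params.h_D), np.full(n, -10.0), np.full(n, 0.5))
        _, _, dH = field_derivatives(state, np.zeros(n), np.zeros(n), params)
        assert np.all(dH < 0)

    def test_habituation_builds_faster_than_it_decays(self, params):
        n = params.n_nodes
        H = np.full(n, 0.5)
        spiking = FieldState(0.0, np.full(n, params.h_D), np.full(n, 50.0), H)
        silent = FieldState(0.0, np.full(n, params.h_D), np.full(n, -50.0), H)
        zeros = np.zeros(n)
        _, _, dH_up = field_derivatives(spiking, zeros, zeros, params)
        _, _, dH_down = field_derivatives(silent, zeros, zeros, params)
        assert np.all(dH_up > 0)
        assert np.all(np.abs(dH_up) > np.abs(dH_down))

    def test_rejects_length_mismatch(self, params):
        state = FieldState.resting(params)
        with pytest.raises(ValueError, match="length"):
            field_derivatives(state, np.zeros(3), np.zeros(params.n_nodes), params)


def test_pure_decay_matches_closed_form(params):
    """With inputs, lateral terms and projection removed, each field relaxes
    exponentially to its resting level within Euler truncation error."""
    p = params.replace(a=0.0, b=0.0, c=0.0, w_SD=0.0, k_H=0.0)
    n = p.n_nodes
    D0, S0, H0 = 10.0, 5.0, 0.8
    state = FieldState(0.0, np.full(n, D0), np.full(n, S0), np.full(n, H0))
    zeros = np.zeros(n)
    T = 1000.0
    steps = int(T / p.dt)
    for _ in range(steps):
        dD, dS, dH = field_derivatives(state, zeros, zeros, p)
        state = FieldState(
            state.t + p.dt,
            state.D + p.dt * dD,
            state.S + p.dt * dS,
            state.H + p.dt * dH,
        )
    for value, x0, h, tau in (
        (state.D[0], D0, p.h_D, p.tau_D_ms),
        (state.S[0], S0, p.h_S, p.tau_S_ms),
        (state.H[0], H0, p.h_H, p.tau_H_ms),
    ):
        analytic = h + (x0 - h) * math.exp(-T / tau)
        # first-order scheme: global error O(dt), about dt/(2 tau) relative
        tol = abs(x0 - h) * p.dt / tau
        assert value == pytest.approx(analytic, abs=max(tol, 1e-9))
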