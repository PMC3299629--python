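# Methods

## Model

The model couples three activation fields over a 1-D grid of 100 equidistant
nodes (labelled 1–100; distances and stimulus widths are in node units).
Each field obeys a first-order relaxation toward its resting level plus
input terms:

```
tau_D dD/dt = -D + h_D + [W * a_D](x) + w_SD a_S(x) + I_endo(x, t)
tau_S dS/dt = -S + h_S + I_exo(x, t)
tau_H dH/dt = -H + h_H + k_H a_S(x) (1 - H)
```

`a_D` and `a_S` are logistic rate transforms of `D` and `S`; the sensory
rate carries a multiplicative habituation gain `(1 - H)`, so no habituation
(`H = 0`) allows a maximal rate of 1 and the achievable rate falls as `H`
approaches 1.  The habituation drive `k_H a_S (1 - H)` gives an effective
build-up time constant `tau_H / (1 + k_H)` ≈ 0.20 s while the sensory field
spikes, against the full `tau_H` = 1.62 s for decay — the fast-build-up /
slow-decay asymmetry that carries inhibition of return — and confines `H`
to [0, 1] without clamping (an integrator guard still clips and logs if a
pathological parameter set overshoots).

The lateral interaction of the decision field is a convolution of its own
rate with a double-Gaussian Mexican hat minus a constant,
`W(d) = a e^{-d²/2σ_a²} - b e^{-d²/2σ_b²} - c`: excitation within a few
nodes, a surround of inhibition, and uniform global inhibition `-c Σ a_D`.
With the default constants the model operates in the input-driven regime:
an ignited decision bump collapses once its input is removed, and all
fields relax back to rest (verified in the test suite).  The convolution is
zero-padded — the grid represents a bounded retinotopic strip — with a
circular mode available for sensitivity checks.

## Stimulus encoding

All inputs are Gaussian *distributions* of excitation: a stimulus of
nominal strength `I_max` and width `σ` contributes a bump with peak
`I_max / (σ √(2π))`.  This normalization is a deliberate reading of the
stimulus equations; it is what makes the published constants mutually
consistent.  With raw peaks of 40–60 the sensory sigmoid (slope 6, resting
level −1) would saturate so deeply that a simultaneous cue adds nothing to a
target (no CTOA-0 facilitation) and the cue pulse alone would drive the
decision field over threshold.  With normalized peaks (cue ≈ 2.0, target
≈ 3.0) the sensory rate *tends toward* its maximum of 1 without pinning
there, the cue produces a clear peak in `D` but none in `a_D`, and the
expectation ramp primes the decision field by a few units without ever
triggering an anticipatory response — all properties the behavior of the
model is known to have.

Defaults: cue `I_max = 40, σ = 8`, 50 ms duration; target `I_max = 60,
σ = 8`, lasting until the response threshold; fixation `I_max = 10, σ = 4`
at Node 50, constant; expectation signals `σ = 8` at Nodes 25, 50 and 75
with common strength `I(t) = I0 + m t` (`I0 = 18`, `m = 50 /s`), the ramp
clock starting at cue onset.  Exogenous amplitudes decay as
`exp(-β_stim τ)` with `β_stim = .07 /s` and `τ` the time since the
(delayed) stimulus onset — a slow decay (≈14 s time constant) that barely
affects a 50 ms cue; the brevity of exogenous influence comes from the
stimulus durations and the fast sensory time constant (`tau_S` = 48 ms),
not from the decay term.  Delays are pure time shifts of drive onset:
70 ms (exogenous), 120 ms (endogenous), 80 ms (motor).

Units: the printed time constants `tau_D = .328`, `tau_S = .048`,
`tau_H = 1.620` multiply the temporal derivatives and are treated as
seconds (the package converts once, internally, to ms); `β_stim` and `m`
are per-second rates.

## Trials and protocols

A trial starts with a 500 ms fixation-only warm-up (so the decision field
reaches its fixation-driven steady state; configurable), cue onset at
t = 0, target onset at t = CTOA.  A response is triggered at the first
Euler step (dt = 5 ms; RTs are quantized to this grid, and halving dt moves
RTs by at most one bin) at which any node's `a_D` reaches the 0.8
threshold; RT references the physical target onset.  The crossing locus
coincides with the target-aligned locus in all standard trials.  Trials
that never cross report an explicit no-response result; the safety horizon
is 3000 ms after target onset.

* **CTOA sweep** — cued (cue = target = Node 25) and uncued (cue 25,
  target 75) trials at CTOAs {0, 50, 100, 200, 300, 500} ms; the catch
  location (Node 50) is never a target.  The model is mirror-symmetric, so
  left and right placements are interchangeable (asserted in tests rather
  than averaged).
* **Habituation protocol** — cued trials with a 50 ms cue and a 500 ms
  target, both at strength 60, CTOA 0–4000 ms in 10 ms steps, threshold
  termination suppressed; the readout is the post-target-onset maximum of
  `a_S` at the target locus.  The peak is measured from physical target
  onset; at CTOAs below ≈ 100 ms the cue-driven and target-driven sensory
  responses overlap, which is why the curve only drops sharply once the cue
  response has separated from the target response.
* **No-expectation variant** — identical sweeps with the expectation input
  removed.  Inhibition at long CTOAs survives; the decrease of RT with
  CTOA (the foreperiod effect) disappears.  The foreperiod effect is read
  from uncued trials, where it is not masked by the build-up of inhibition
  at the cued location.

## Fitting

Predicted inhibition `PI_i = RT_cued − RT_uncued` per CTOA is scored
against observed increments `OI_i` by
`RMSE = sqrt(mean((PI_i − OI_i)²))` and mapped to a fitness
`F = 100 / (1 + RMSE_seconds)`: F = 100 exactly at RMSE = 0 and decreases
strictly with RMSE.  This rational normalization is the package's choice of
mapping; it reconciles a near-maximal fitness with a root-mean-squared
error of several milliseconds.

Six parameters are searched — `tau_D` (.01–1), `tau_S` (.01–1), `tau_H`
(.01–2.5), `w_SD` (0–100), `m` (1–100), `I0` (0–20) — by a seedable
(μ+λ) evolution strategy (μ = population/4, Gaussian mutation with σ = 15 %
of each range, clipped to bounds).  Any bounded population search would do:
the scientific content is the objective, not the optimizer.  Candidates
whose parameter vectors produce a no-response trial score the worst
possible fitness (0) and the search continues.  The default budget
(40 × 30) completes a fit in minutes on one core; the packaged observed
dataset is an *approximate digitization* of published cueing data (the
exact numbers were never printed) and is flagged as such — which is why the
goodness-of-fit test asserts only fitness > 90 rather than a point value.

## Numerical choices and degenerate inputs

* Threshold comparison uses ≥ at step boundaries; no sub-step
  interpolation.
* The rate sigmoids never vanish, so the exact resting levels
  `(h_D, h_S, h_H)` are a fixed point only up to residual resting rates
  (`a_S(h_S) ≈ 0.0025` shifts the true rest to `H* ≈ 0.017`,
  `D* ≈ h_D + 0.23`).  Tests assert derivative magnitudes < 1e-6 at the
  self-consistent rest and < 1e-2 at the nominal rest.
* Non-finite field values abort the integration with a diagnostic; H is
  clipped (with a logged warning) only as a guard.
* Empty expectation-location lists yield a zero drive with a warning;
  off-grid nodes and malformed parameter files are rejected with
  diagnostics.
* Parameter files store numeric values as decimal strings so provenance
  copies round-trip bit-exactly.

## What the simulations do and do not show

The protocols reproduce the within-trial dynamics of a double-cueing
experiment with deterministic dynamics: single prototypical trials stand in
for condition means, and there is no trial-to-trial noise, no learning
across trials, no spatially informative cueing, and no saccadic (as opposed
to manual) response pathway.  Passing tests therefore certify the model's
mechanism — habituation-mediated sensory depression plus decaying
cue-induced facilitation — not the variability structure of empirical RT
distributions.  Problem sizes used throughout (100 nodes, 5 ms steps,
six-CTOA sweeps, 401-point habituation grid) match the reference protocol;
unit tests use coarser grids of the same protocols where a full sweep adds
nothing.
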