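# Methods

## The model

The controlled variable is the real part of tissue impedance (Ω) during
radiofrequency ablation; the manipulated variable is the RMS electrode
voltage (V). The package treats the relationship as a black-box linear
time-invariant system identified from data, on the grounds that the
procedure operates around a trajectory (slow impedance decline followed by
the roll-off surge) rather than a fixed operating point, and that the goal
is regulation, not biophysical simulation. No Pennes/Arrhenius
electro-thermal modelling is attempted; perfusion and metabolic heating are
outside the model class by construction.

Identification is ARX: A(z⁻¹)y(k) = B(z⁻¹)u(k) + ξ(k), estimated by
ordinary least squares on the one-step regression. The regression row for
sample k is [−y(k−1)…−y(k−na), u(k−1)…u(k−nb)], rows k = p…N with
p = 1 + max(na, nb), giving an (N−p+1)×(na+nb) matrix. The headline fit is
one-step-ahead (measured past outputs feed the predictor); a free-run
simulation is provided separately as a diagnostic, because for a
marginally-excited record the two can differ dramatically and the one-step
metric is the one the FIT/R² values refer to.

Fit indices: FIT = 100·(1 − ‖y−ŷ‖₂/‖y−ȳ‖₂) (the NRMSE convention) and
R² = 1 − Σξ²/Σ(y−ȳ)². These satisfy R² = 1 − (1 − FIT/100)² exactly, which
the tests assert. A plain ratio variant of FIT is exposed behind a flag for
comparison but is not used anywhere: it is inconsistent with the NRMSE name
and with the reported magnitudes of well-fitting models.

The canonical plant — the 9-pole/8-zero continuous transfer function
identified from the ex-vivo estimation record — is shipped as a JSON
fixture in two variants. `as_printed` carries the coefficients at commonly
quoted precision; `routh_refined` replaces the denominator with the extra
digits recoverable from the first two rows of its published Routh array
(those rows are exactly the polynomial coefficients at alternating powers).
The refinement matters mostly through the constant term (0.5032 vs 0.5),
which sets the DC gain 0.81/0.5032 = 1.610. The discrete 1 Hz companion
model is likewise a fixture. Whether the continuous model was obtained by
converting the discrete one or estimated directly is not recoverable — a
zero-order-hold inverse of a 1 Hz model cannot produce 0.036 s rise-time
dynamics — so the printed continuous model is treated as canonical and
`d2c_convert` is provided as an independent, round-trip-tested utility
(zoh via the principal matrix logarithm, Tustin as exact polynomial
substitution).

## Step simulation and metrics

Step responses are computed by exact zero-order-hold discretization
(matrix exponential) of the state-space realization, propagated in blocks;
there is no integration truncation error, which matters for the stiff
9th/10th-order polynomials involved (their z-domain pole clusters near 1
also rule out direct-form filtering — it is numerically explosive at
dt = 1 ms, which is why the state recursion is used).

Metrics follow the MATLAB `stepinfo` definitions, because the workflow
being reproduced was built in that environment and its printed numbers are
only mutually consistent under those definitions:

* **rise time** — 10%→90% traversal of the span from the initial response
  value y(0) to the steady-state value (linear interpolation at the
  crossings);
* **overshoot** — 100·(peak − final)/|final|, clipped at zero;
* **settling time** — last instant |y − y_final| exceeds 2% of the
  *maximum* of |y − y_final| over the horizon.

For a response that starts at zero and overshoots by less than 100% these
reduce to the textbook "2% of final value" conventions. They diverge in the
two cases this package cares about: the open-loop plant (maximum deviation
is the 33.6 peak, 20× the final value, so the settling band is 2% of the
peak error — the textbook band would report ~50 s instead of ~15 s), and
the PID closed loop, which is biproper (see below) and starts at
y(0) = 0.94, so the rise-time span is 0.94→1.0.

## The closed loop

K(s) = Kp + Ki/s + Kd·s is kept with an ideal (unfiltered) derivative in
the transfer-function algebra. The plant has relative degree 1, so
KP and T = KP/(1+KP) remain proper (biproper), and the closed-loop
characteristic polynomial is s·den_P + (Kd s² + Kp s + Ki)·num_P, degree 10
with leading coefficient 1 + Kd·32.43. The physical reading of the
biproperness: the setpoint step differentiates into an impulse that passes
through the relative-degree-1 plant instantaneously, so the modelled output
jumps at t = 0⁺. The reconstructed time-domain control signal v(t) uses a
trapezoidal integral and a first-difference derivative on the simulation
grid, as a discrete Δu/Δt block would.

With Ki > 0 and a finite-DC-gain plant the closed-loop DC gain is exactly 1
in floating point (numerator and denominator share the constant term
Ki·num_P(0)); the tests assert equality, not approximation. Ki = 0 creates
an exact pole-zero cancellation at s = 0; the controller is then reduced
algebraically and a warning is emitted.

The tuning objective is OF = α·ISE + β·SysOvr + γ·ISTE with overshoot in
percent and defaults (α, β, γ) = (0.5, 0.6, 0.8), evaluated on a 10 s,
1 ms-grid unit-step simulation (the tuned loop settles by ~3 s; doubling
the horizon changes the integrals by <0.1%, and halving dt changes OF by
<10⁻⁵ relative, both verified in tests). ISE and ISTE are trapezoidal
integrals of e² and t·e². Candidates whose characteristic polynomial fails
the Routh test are assigned a finite penalty (10⁶) so swarm arithmetic
stays well defined; hard instability never propagates NaNs into the search.

A landscape note: under this objective the published gain set
(5.0594, 10.0, 0.4959) is *not* a minimizer — its 0.6% overshoot
contributes 0.36 to the OF, while gain sets with saturated Kd produce
overshoot-free loops with OF ~10⁻⁴, and the swarm reliably finds them. The
package reports what the objective actually scores; the published gains
remain the canonical operating point for the reproduction targets because
their step metrics are what the study documents.

## Routh–Hurwitz

The array is built by the standard cross-multiplication recurrence; the
number of sign changes in the first column equals the number of open
right-half-plane roots (property-tested against eigenvalue root-finding on
500 random polynomials). Two degeneracies are handled for library
robustness, although the canonical polynomials never hit them: an isolated
zero pivot is ε-substituted (ε treated as +0⁺ when counting signs), and an
all-zero row is replaced by the derivative of the auxiliary polynomial of
the row above. A table containing either degeneracy is never reported
asymptotically stable.

## Particle swarm

Global-best PSO, velocities v ← ω v + c₁r₁(pbest − x) + c₂r₂(gbest − x)
with per-dimension uniform draws (the standard choice where the draw
granularity is ambiguous), positions x ← x + v. Canonical configuration:
S = 30 particles, N = 3 dimensions, 10 iterations, bounds [0.01, 10] per
gain, c₁ = c₂ = 2.05, inertia linearly decaying 0.9 → 0.1. The velocity cap
is v_max = 2·(x_max − x_min) with initial velocities uniform in ±v_max/3;
positions are hard-clipped to the box, which represents exactly the
observed saturation of the integral gain at the upper bound 10. Early
stopping (gbest improvement below a threshold) exists but is off by
default so that repeated-run statistics come from a fixed budget.
Seeding: one root seed spawns per-run child generators through NumPy's
`SeedSequence`, so a multi-run experiment is reproducible from a single
integer; every result carries its seed.

## Synthetic data

`generate_rolloff_series` emulates the *shape* of the ex-vivo recordings:
impedance = baseline·(1 − f·s₁(t)) + (plateau − baseline)·σ(κ(t − t_r)),
with s₁ a saturating ramp (time constant t_r/3) for the early
conductivity-driven decline and σ a logistic for the dehydration surge.
Defaults: baseline 80 Ω, decline fraction 0.15, t_r = 318 s in a 330 s
record, plateau 1000 Ω, sharpness κ = 0.5 s⁻¹ (surge essentially complete
within ~10 s, leaving the terminal value within 2% of the plateau),
impedance noise 1.5 Ω. The voltage channel settles at 26 V after an 8 V
start-up transient with a 10 s time constant (mirroring the initial ~34 W
power transient) plus 0.3 V noise so that the identification regressors on
the input side are not collinear. Timestamps are a nominal 1 s grid with
0.15 s Gaussian jitter — a stand-in for the acquisition hardware's
irregular export cadence, whose true pattern is unknown.

What passing tests on this generator do show: the resampling, regression,
estimation, stability and tuning machinery is correct on data with the
right magnitudes, curvature and sampling pathology. What they do not show:
performance on real tissue records, whose noise is neither white nor
Gaussian, whose input is far less exciting (nearly constant voltage), and
whose roll-off shape varies between samples. The FIT values achievable on
synthetic records are therefore not comparable to those on the ex-vivo
recordings.

`simulate_arx_series` (exact ARX recursion with Gaussian equation noise and
an overflow guard) is the ground-truth source for parameter-recovery tests:
estimation error vanishes as noise → 0 and matches a pseudo-inverse oracle.
`generate_plant_response` drives any stable continuous plant with a sampled
input under zero-order hold.

## Numerical choices

* Step grids: dt = 1 ms; horizons 20 s (open loop) and 10 s (closed loop).
  The open-loop settling computation needs ≥ 16 s of horizon; metrics raise
  an explicit "unsettled" error rather than extrapolate. The pipeline
  retries with 8× and 64× horizons before reporting a loop unsettled.
* Steiglitz–McBride iteration: equation-error fit, then re-fit on signals
  prefiltered by 1/Â(z⁻¹) until the coefficient vector moves < 10⁻⁸
  (∞-norm) or 50 iterations; non-convergence warns and returns the last
  iterate. Relative degree is fixed at n_poles − n_zeros, so numerators
  start at the matching delay.
* Resampling to a uniform grid uses linear interpolation (the only
  defensible choice without a sensor model), grid anchored at the first
  timestamp.
* Root finding uses companion-matrix eigenvalues (`numpy.roots`) with
  post-hoc conjugate symmetrization; Routh zero tolerance is 10⁻¹² relative
  to the largest coefficient.
* The multi-run experiment (19 runs × 30 particles × 11 evaluation sweeps,
  each a 10 s / 1 ms simulation) runs in well under a minute on one core;
  these are the problem sizes used throughout the tests and the
  reproduction script.

## Known limitations

* The plant is a local, linear description of a strongly nonlinear,
  time-varying process; the closed-loop predictions hold for the modelled
  trajectory, not arbitrary operating points.
* The ideal-derivative loop is an idealization; any hardware deployment
  needs a filtered derivative (and anti-windup, saturation handling —
  all out of scope here), which will soften the t = 0⁺ jump and shift the
  rise-time metric.
* One-step-ahead FIT at high ARX orders is an optimistic measure on
  slowly-varying records; it is reported because it is the study's metric,
  with the free-run simulator available for a harsher view.
* The objective-function landscape admits many near-equivalent minima with
  saturated gains; reported tuned gains are therefore seed-dependent even
  though each run is individually reproducible.
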