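"""Synthetic data generators emulating the ex-vivo ablation recordings.

Three generators cover the pipeline's input needs without the original
laboratory spreadsheets:

* :func:`simulate_arx_series` drives a known ARX model forward with noise —
  the ground-truth source for parameter-recovery tests;
* :func:`generate_rolloff_series` produces a phenomenological impedance
  roll-off trace (slow early decline from a baseline of tens of ohms, then
  a logistic surge toward ~1000 Ω around the roll-off time) paired with a
  voltage channel that settles near 26 V after an initial transient, on
  jittered (non-uniform) timestamps, as the acquisition hardware records;
* :func:`generate_plant_response` runs an arbitrary input profile through a
  continuous plant and adds measurement noise.

The roll-off curve is deliberately phenomenological — a logistic rise, not
an electro-thermal tissue model: the modelling target of the package is the
black-box identified dynamics, not the biophysics that produce them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .lti import RationalTF, poles_zeros
from .sysid import ARXModel, TimeSeries

__all__ = [
    "RollOffParams",
    "DivergenceError",
    "simulate_arx_series",
    "generate_rolloff_series",
    "generate_plant_response",
]


class DivergenceError(RuntimeError):
    """The simulated recursion left the overflow guard."""


@dataclass(frozen=True)
class RollOffParams:
    """Parameters of the phenomenological roll-off generator.

    Defaults mimic the published estimation recording: ~80 Ω baseline with a
    slow early decline, roll-off centred at 318 s within a 330 s record,
    plateau near 1000 Ω, voltage settling at 26 V after an initial ~8 V
    transient (the ~34 W start-up), nominal 1 Hz sampling with Gaussian
    timestamp jitter.
    """

    baseline_impedance: float = 80.0  # Ω
    early_decline_fraction: float = 0.15
    rolloff_time: float = 318.0  # s
    rolloff_sharpness: float = 0.5  # 1/s, logistic steepness (surge over ~10 s)
    plateau_impedance: float = 1000.0  # Ω
    voltage_level: float = 26.0  # V RMS, settled
    voltage_transient_amplitude: float = 8.0  # V above the settled level at t=0
    voltage_transient_tau: float = 10.0  # s
    voltage_noise_sd: float = 0.3  # V
    noise_sd: float = 1.5  # Ω
    sampling_jitter_sd: float = 0.15  # s
    duration: float = 330.0  # s
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.plateau_impedance <= self.baseline_impedance:
            raise ValueError("plateau impedance must exceed the baseline")
        if not 0.0 < self.rolloff_time < self.duration:
            raise ValueError("roll-off time must fall inside the record")
        if self.noise_sd < 0 or self.sampling_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")


def simulate_arx_series(
    model: ARXModel,
    input_u: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float = 1.0,
    overflow_guard: float = 1e12,
) -> TimeSeries:
    """Forward ARX recursion y(k) = −Σaᵢy(k−i) + Σbⱼu(k−j) + ξ(k).

    Initial conditions are zero; ξ ~ N(0, noise_sd²).  The recursion is
    monitored and a :class:`DivergenceError` is raised if the output leaves
    the overflow guard (unstable model).
    """
    u = np.asarray(input_u, dtype=float)
    rng = np.random.default_rng(seed)
    n = u.size
    y = np.zeros(n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    for k in range(n):
        acc = noise[k]
        for i in range(1, model.na + 1):
            if k - i >= 0:
                acc -= model.a_coeffs[i - 1] * y[k - i]
        for j in range(1, model.nb + 1):
            if k - j >= 0:
                acc += model.b_coeffs[j - 1] * u[k - j]
        if not np.isfinite(acc) or abs(acc) > overflow_guard:
            raise DivergenceError(f"ARX recursion diverged at step {k}")
        y[k] = acc
    return TimeSeries(times=np.arange(n) * dt, input_u=u, output_y=y)


def generate_rolloff_series(p: RollOffParams) -> TimeSeries:
    """Phenomenological voltage/impedance record with non-uniform timestamps.

    Impedance: baseline·(1 − f·s₁(t)) + (plateau − baseline)·σ(κ·(t − t_r))
    where s₁ is a saturating ramp (time constant t_r/3) modelling the early
    conductivity-driven decline and σ a logistic modelling the dehydration
    surge.  Voltage: settled level plus an exponentially decaying start-up
    transient.  Timestamps are a nominal 1 s grid plus Gaussian jitter,
    sorted and de-duplicated to stay strictly increasing.
    """
    rng = np.random.default_rng(p.seed)
    n = int(np.floor(p.duration)) + 1
    t = np.arange(n, dtype=float)
    if p.sampling_jitter_sd > 0:
        t = t + rng.normal(0.0, p.sampling_jitter_sd, size=n)
        t[0] = max(t[0], 0.0)
        t = np.sort(t)
        # enforce strict monotonicity after sorting
        eps = 1e-6
        for k in range(1, n):
            if t[k] <= t[k - 1]:
                t[k] = t[k - 1] + eps

    ramp = 1.0 - np.exp(-3.0 * t / p.rolloff_time)
    logistic = 1.0 / (1.0 + np.exp(-p.rolloff_sharpness * (t - p.rolloff_time)))
    z = (
        p.baseline_impedance * (1.0 - p.early_decline_fraction * ramp)
        + (p.plateau_impedance - p.baseline_impedance) * logistic
    )
    if p.noise_sd > 0:
        z = z + rng.normal(0.0, p.noise_sd, size=n)
    z = np.maximum(z, 1.0)  # impedance stays physical

    v = p.voltage_level + p.voltage_transient_amplitude * np.exp(
        -t / p.voltage_transient_tau
    )
    if p.voltage_noise_sd > 0:
        v = v + rng.normal(0.0, p.voltage_noise_sd, size=n)
    return TimeSeries(times=t, input_u=v, output_y=z)


def _simulate_lti(tf: RationalTF, input_u: np.ndarray, dt: float) -> np.ndarray:
    """Zero-order-hold simulation of a continuous TF for a sampled input."""
    A, B, C, D = _signal.tf2ss(tf.num, tf.den)
    Ad, Bd, Cd, Dd, _ = _signal.cont2discrete((A, B, C, D), dt, method="zoh")
    b, c, d = Bd[:, 0], Cd[0], float(np.atleast_2d(Dd)[0, 0])
    x = np.zeros(Ad.shape[0])
    y = np.empty(input_u.size)
    for k, uk in enumerate(input_u):
        y[k] = c @ x + d * uk
        x = Ad @ x + b * uk
    return y


def generate_plant_response(
    tf: RationalTF,
    input_profile: tuple[np.ndarray, np.ndarray],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TimeSeries:
    """Response of a stable continuous plant to a sampled input, plus noise.

    ``input_profile`` is ``(times, u)`` on a uniform grid; the input is held
    between samples (zero-order hold).  Unstable plants are rejected.
    """
    t, u = (np.asarray(a, dtype=float) for a in input_profile)
    if t.size != u.size or t.size < 2:
        raise ValueError("input profile needs matching times and values")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-9, atol=1e-12):
        raise ValueError("input profile must be uniformly sampled")
    if np.any(poles_zeros(tf).poles.real >= 1e-12):
        raise ValueError("unstable plant rejected")
    y = _simulate_lti(tf, u, dt)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return TimeSeries(times=t, input_u=u, output_y=y)
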