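"""PID control of the ablation plant: closed loops, simulation and costs.

The controller K(s) = Kp + Ki/s + Kd·s modulates the electrode voltage from
the impedance error in a unity-negative-feedback loop around the identified
plant P(s).  The loop transfer T = KP/(1 + KP) is formed by exact polynomial
arithmetic (the characteristic polynomial is s·den_P + (Kd·s² + Kp·s + Ki)·num_P,
degree 10 for the canonical 9th-order plant).  The derivative term is kept
unfiltered in the algebra — valid because the plant has relative degree 1,
so T stays (bi)proper — while the reconstructed time-domain control signal
uses a first-difference derivative as a discrete Δu/Δt block would.

The tuning objective combines the integral of squared error (ISE), its
time-weighted variant (ISTE) and the percent overshoot:
OF = α·ISE + β·SysOvr + γ·ISTE, with canonical weights (0.5, 0.6, 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .lti import (
    RationalTF,
    dc_gain,
    routh_table,
    step_metrics,
    step_response,
)

__all__ = [
    "PIDGains",
    "ClosedLoopSim",
    "CostBreakdown",
    "CostWeights",
    "SimSettings",
    "REFERENCE_GAINS",
    "controller_tf",
    "closed_loop_tf",
    "simulate_closed_loop_step",
    "ise",
    "iste",
    "objective_function",
    "evaluate_candidate",
]


@dataclass(frozen=True)
class PIDGains:
    kp: float
    ki: float
    kd: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.kp, self.ki, self.kd])):
            raise ValueError("PID gains must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.kp, self.ki, self.kd])


#: The study's headline PSO-tuned gains.
REFERENCE_GAINS = PIDGains(kp=5.0594, ki=10.0, kd=0.4959)


@dataclass(frozen=True)
class CostWeights:
    """Weights (α, β, γ) on ISE, percent overshoot and ISTE."""

    alpha: float = 0.5
    beta: float = 0.6
    gamma: float = 0.8

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("cost weights must be non-negative")


@dataclass(frozen=True)
class SimSettings:
    """Closed-loop step-simulation settings used by the tuner."""

    horizon_s: float = 10.0
    dt_s: float = 1e-3
    penalty: float = 1e6


@dataclass
class ClosedLoopSim:
    """Unit-step closed-loop trajectory: output y, error e = 1−y, control v."""

    t: np.ndarray
    y: np.ndarray
    e: np.ndarray
    v: np.ndarray
    stable: bool


@dataclass
class CostBreakdown:
    ise: float
    iste: float
    overshoot_pct: float
    of_value: float


def controller_tf(g: PIDGains) -> RationalTF:
    """K(s) = Kp + Ki/s + Kd·s as the rational (Kd·s² + Kp·s + Ki)/s.

    With Ki = 0 the exact pole-zero cancellation at s = 0 is removed (the
    controller reduces to Kd·s + Kp) and a warning is emitted, since the
    loop then loses its integral action.
    """
    if g.ki == 0.0:
        warnings.warn(
            "ki = 0: cancelling the controller pole at s=0 (no integral action)",
            stacklevel=2,
        )
        return RationalTF([g.kd, g.kp], [1.0], domain="s")
    return RationalTF([g.kd, g.kp, g.ki], [1.0, 0.0], domain="s")


def closed_loop_tf(plant: RationalTF, g: PIDGains) -> RationalTF:
    """Unity-negative-feedback loop T = KP/(1 + KP), by polynomial arithmetic."""
    if plant.domain != "s":
        raise ValueError("closed_loop_tf expects a continuous plant")
    K = controller_tf(g)
    ol_num = np.polymul(K.num, plant.num)
    ol_den = np.polymul(K.den, plant.den)
    return RationalTF(ol_num, np.polyadd(ol_den, ol_num), domain="s")


def simulate_closed_loop_step(
    plant: RationalTF,
    g: PIDGains,
    horizon: float = 10.0,
    dt: float = 1e-3,
) -> ClosedLoopSim:
    """Closed-loop unit-step response with reconstructed control signal.

    y comes from the exact step response of T = KP/(1+KP); e = 1 − y; the
    voltage v applies the PID law to e on the grid, with a trapezoidal
    integral and a first-difference derivative.  An unstable loop (by the
    Routh criterion on the characteristic polynomial) is still simulated
    but flagged.
    """
    T = closed_loop_tf(plant, g)
    stable = routh_table(T.den).stable
    resp = step_response(T, horizon=horizon, dt=dt)
    e = 1.0 - resp.y
    e_int = integrate.cumulative_trapezoid(e, resp.t, initial=0.0)
    e_diff = np.empty_like(e)
    e_diff[0] = 0.0
    e_diff[1:] = np.diff(e) / dt
    v = g.kp * e + g.ki * e_int + g.kd * e_diff
    return ClosedLoopSim(t=resp.t, y=resp.y, e=e, v=v, stable=stable)


def ise(e_series: np.ndarray, dt: float) -> float:
    """Integral of squared error over the simulated horizon (trapezoidal)."""
    e = np.asarray(e_series, dtype=float)
    if e.size == 0:
        raise ValueError("empty error series")
    return float(np.trapezoid(e**2, dx=dt))


def iste(e_series: np.ndarray, dt: float) -> float:
    """Time-weighted integral of squared error, ∫ t·e²(t) dt (trapezoidal)."""
    e = np.asarray(e_series, dtype=float)
    if e.size == 0:
        raise ValueError("empty error series")
    t = np.arange(e.size) * dt
    return float(np.trapezoid(t * e**2, dx=dt))


def objective_function(
    ise_value: float,
    overshoot_pct: float,
    iste_value: float,
    w: CostWeights = CostWeights(),
) -> float:
    """OF = α·ISE + β·SysOvr + γ·ISTE (overshoot in percent)."""
    return w.alpha * ise_value + w.beta * overshoot_pct + w.gamma * iste_value


def evaluate_candidate(
    plant: RationalTF,
    g: PIDGains,
    w: CostWeights = CostWeights(),
    settings: SimSettings = SimSettings(),
) -> CostBreakdown:
    """Cost of one gain candidate: simulate the loop and combine the indices.

    A Routh-unstable closed loop short-circuits to the configured penalty
    so the swarm arithmetic stays finite.
    """
    T = closed_loop_tf(plant, g)
    if not routh_table(T.den).stable:
        return CostBreakdown(
            ise=np.nan, iste=np.nan, overshoot_pct=np.nan, of_value=settings.penalty
        )
    resp = step_response(T, horizon=settings.horizon_s, dt=settings.dt_s)
    yf = dc_gain(T)
    e = 1.0 - resp.y
    i1 = ise(e, settings.dt_s)
    i2 = iste(e, settings.dt_s)
    ovr = max(0.0, 100.0 * (resp.y.max() - yf) / abs(yf)) if yf != 0 else 0.0
    return CostBreakdown(
        ise=i1,
        iste=i2,
        overshoot_pct=ovr,
        of_value=objective_function(i1, ovr, i2, w),
    )


def closed_loop_metrics(
    plant: RationalTF,
    g: PIDGains,
    horizon: float = 10.0,
    dt: float = 1e-3,
):
    """Convenience: stepinfo-style metrics of the closed unit-step response."""
    T = closed_loop_tf(plant, g)
    resp = step_response(T, horizon=horizon, dt=dt)
    return step_metrics(resp, final_value=dc_gain(T))
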