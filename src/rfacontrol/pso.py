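"""Particle swarm optimization of PID gains with linearly decaying inertia.

Standard global-best PSO over the 3-dimensional gain box [x_min, x_max]³:

    v ← ω(k)·v + c₁r₁(pbest − x) + c₂r₂(gbest − x),   x ← x + v,

with per-dimension uniform draws r₁, r₂, velocities clamped to ±v_max and
positions hard-clipped to the box (the integral gain of the ablation tuning
problem saturates at the upper bound, which hard clipping represents
exactly).  The inertia weight decays linearly from ω₀ to ω_f over the run.

The canonical configuration mirrors the study: 30 particles, 10 iterations,
bounds [0.01, 10], c₁ = c₂ = 2.05, ω from 0.9 to 0.1, v_max = 2·(x_max − x_min)
with initial velocities uniform in ±v_max/3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .lti import RationalTF
from .pid import CostWeights, PIDGains, SimSettings, evaluate_candidate

__all__ = [
    "PSOConfig",
    "Particle",
    "PSOResult",
    "RunStatistics",
    "PSOPIDTuner",
    "init_swarm",
    "inertia_at",
    "update_velocity",
    "update_position",
    "optimize",
    "make_pid_evaluator",
    "multi_run_statistics",
]

Evaluator = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 30
    n_dims: int = 3
    x_min: float = 0.01
    x_max: float = 10.0
    c1: float = 2.05
    c2: float = 2.05
    omega_start: float = 0.9
    omega_end: float = 0.1
    max_iter: int = 10
    v_max: float | None = None  # defaults to 2·(x_max − x_min)
    v_init_scale: float = 1.0 / 3.0  # initial velocities uniform in ±v_init_scale·v_max
    early_stop_tol: float | None = None  # OF improvement threshold; None = run out
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.swarm_size < 1 or self.max_iter < 1 or self.n_dims < 1:
            raise ValueError("swarm_size, n_dims and max_iter must be >= 1")
        if not self.x_min < self.x_max:
            raise ValueError("need x_min < x_max")
        if not 0.0 <= self.omega_end <= self.omega_start:
            raise ValueError("need 0 <= omega_end <= omega_start")
        if self.v_max is None:
            object.__setattr__(self, "v_max", 2.0 * (self.x_max - self.x_min))


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_cost: float = np.inf


@dataclass
class PSOResult:
    gbest: PIDGains
    gbest_cost: float
    convergence: list[float]
    iterations_run: int
    seed: int | None


@dataclass
class RunStatistics:
    """Per-gain sample statistics across repeated independent runs."""

    n_runs: int
    mean: dict[str, float]
    variance: dict[str, float]
    std: dict[str, float]
    gains: np.ndarray  # (n_runs, 3) array of (kp, ki, kd)
    costs: np.ndarray
    seeds: list[int]


def init_swarm(cfg: PSOConfig, rng: np.random.Generator) -> list[Particle]:
    """Positions uniform on the box; velocities uniform in ±v_init_scale·v_max."""
    swarm = []
    for _ in range(cfg.swarm_size):
        x = rng.uniform(cfg.x_min, cfg.x_max, size=cfg.n_dims)
        vspan = cfg.v_init_scale * cfg.v_max
        v = rng.uniform(-vspan, vspan, size=cfg.n_dims) if vspan > 0 else np.zeros(cfg.n_dims)
        swarm.append(Particle(position=x, velocity=v, pbest_position=x.copy()))
    return swarm


def inertia_at(cfg: PSOConfig, k: int) -> float:
    """Linearly decaying inertia: ω(k) = ω₀ + k·(ω_f − ω₀)/max_iter."""
    if not 0 <= k <= cfg.max_iter:
        raise ValueError(f"iteration index {k} outside [0, {cfg.max_iter}]")
    return cfg.omega_start + k * (cfg.omega_end - cfg.omega_start) / cfg.max_iter


def update_velocity(
    particle: Particle,
    gbest: np.ndarray,
    omega: float,
    cfg: PSOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inertia + cognitive + social velocity update, clamped to ±v_max."""
    r1 = rng.uniform(size=cfg.n_dims)
    r2 = rng.uniform(size=cfg.n_dims)
    v = (
        omega * particle.velocity
        + cfg.c1 * r1 * (particle.pbest_position - particle.position)
        + cfg.c2 * r2 * (gbest - particle.position)
    )
    return np.clip(v, -cfg.v_max, cfg.v_max)


def update_position(particle: Particle, cfg: PSOConfig) -> np.ndarray:
    """x ← x + v, hard-clipped to the search box (velocity left unchanged)."""
    return np.clip(particle.position + particle.velocity, cfg.x_min, cfg.x_max)


def optimize(cfg: PSOConfig, evaluator: Evaluator) -> PSOResult:
    """Run the swarm; the convergence history records gbest after each sweep.

    The evaluator maps a gain vector to a finite cost (candidates that
    destabilize the loop must already carry their penalty).  Early stopping,
    when ``cfg.early_stop_tol`` is set, triggers once the improvement of
    gbest over an iteration falls below the threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    swarm = init_swarm(cfg, rng)

    gbest_x = None
    gbest_cost = np.inf
    for p in swarm:
        cost = float(evaluator(p.position))
        p.pbest_cost = cost
        if cost < gbest_cost:
            gbest_cost, gbest_x = cost, p.position.copy()
    convergence = [gbest_cost]

    iterations = 0
    for k in range(1, cfg.max_iter + 1):
        omega = inertia_at(cfg, k - 1)
        previous = gbest_cost
        for p in swarm:
            p.velocity = update_velocity(p, gbest_x, omega, cfg, rng)
            p.position = update_position(p, cfg)
            cost = float(evaluator(p.position))
            if cost < p.pbest_cost:
                p.pbest_cost = cost
                p.pbest_position = p.position.copy()
            if cost < gbest_cost:
                gbest_cost, gbest_x = cost, p.position.copy()
        convergence.append(gbest_cost)
        iterations = k
        if (
            cfg.early_stop_tol is not None
            and previous - gbest_cost < cfg.early_stop_tol
        ):
            break

    return PSOResult(
        gbest=PIDGains(*gbest_x),
        gbest_cost=gbest_cost,
        convergence=convergence,
        iterations_run=iterations,
        seed=cfg.seed,
    )


def make_pid_evaluator(
    plant: RationalTF,
    weights: CostWeights = CostWeights(),
    settings: SimSettings = SimSettings(),
) -> Evaluator:
    """Evaluator closure: gain vector → weighted ISE/overshoot/ISTE cost."""

    def _eval(x: np.ndarray) -> float:
        return evaluate_candidate(
            plant, PIDGains(*x), w=weights, settings=settings
        ).of_value

    return _eval


def multi_run_statistics(
    cfg: PSOConfig,
    evaluator: Evaluator,
    n_runs: int = 19,
    base_seed: int = 0,
) -> RunStatistics:
    """Repeat the tuning with independent seeds; sample statistics per gain.

    Child seeds are drawn deterministically from ``base_seed`` via NumPy's
    SeedSequence spawning, so the whole experiment is reproducible from a
    single integer.
    """
    if n_runs < 2:
        raise ValueError("need at least two runs for sample statistics")
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(base_seed).spawn(n_runs)
    ]
    gains = np.empty((n_runs, 3))
    costs = np.empty(n_runs)
    for i, seed in enumerate(child_seeds):
        res = optimize(replace(cfg, seed=seed), evaluator)
        gains[i] = res.gbest.as_array()
        costs[i] = res.gbest_cost
    names = ("kp", "ki", "kd")
    return RunStatistics(
        n_runs=n_runs,
        mean={n: float(gains[:, j].mean()) for j, n in enumerate(names)},
        variance={n: float(gains[:, j].var(ddof=1)) for j, n in enumerate(names)},
        std={n: float(gains[:, j].std(ddof=1)) for j, n in enumerate(names)},
        gains=gains,
        costs=costs,
        seeds=child_seeds,
    )


class PSOPIDTuner(BaseEstimator):
    """PSO-based PID tuning as a scikit-learn style estimator.

    ``fit(plant)`` runs the swarm against closed-loop step simulations of
    the given plant and exposes the tuned gains.

    Attributes
    ----------
    gains_ : PIDGains
    cost_ : float
    convergence_ : list of float
    result_ : PSOResult
    """

    def __init__(
        self,
        swarm_size: int = 30,
        max_iter: int = 10,
        x_min: float = 0.01,
        x_max: float = 10.0,
        c1: float = 2.05,
        c2: float = 2.05,
        omega_start: float = 0.9,
        omega_end: float = 0.1,
        alpha: float = 0.5,
        beta: float = 0.6,
        gamma: float = 0.8,
        horizon_s: float = 10.0,
        dt_s: float = 1e-3,
        penalty: float = 1e6,
        early_stop_tol: float | None = None,
        random_state: int | None = None,
    ):
        self.swarm_size = swarm_size
        self.max_iter = max_iter
        self.x_min = x_min
        self.x_max = x_max
        self.c1 = c1
        self.c2 = c2
        self.omega_start = omega_start
        self.omega_end = omega_end
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.horizon_s = horizon_s
        self.dt_s = dt_s
        self.penalty = penalty
        self.early_stop_tol = early_stop_tol
        self.random_state = random_state

    def _config(self) -> PSOConfig:
        return PSOConfig(
            swarm_size=self.swarm_size,
            x_min=self.x_min,
            x_max=self.x_max,
            c1=self.c1,
            c2=self.c2,
            omega_start=self.omega_start,
            omega_end=self.omega_end,
            max_iter=self.max_iter,
            early_stop_tol=self.early_stop_tol,
            seed=self.random_state,
        )

    def fit(self, plant: RationalTF, y=None) -> "PSOPIDTuner":
        evaluator = make_pid_evaluator(
            plant,
            weights=CostWeights(self.alpha, self.beta, self.gamma),
            settings=SimSettings(self.horizon_s, self.dt_s, self.penalty),
        )
        self.result_ = optimize(self._config(), evaluator)
        self.gains_ = self.result_.gbest
        self.cost_ = self.result_.gbest_cost
        self.convergence_ = self.result_.convergence
        return self
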