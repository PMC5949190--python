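"""Particle swarm optimizer with pluggable inertia-weight schedules.

Velocity and position follow the canonical update

    v <- w*v + c1*r1*(p_i - x) + c2*r2*(p_g - x)
    x <- x + v

with r1, r2 fresh uniforms per particle *and* dimension, velocities
clamped to [-vmax, vmax], and positions clamped to the search box (a
clamped component has its velocity zeroed).  The inertia weight w is
either constant or decays over generations under one of five dynamic
schedules (two linear, three nonlinear); large w early favors global
exploration, small w late favors local refinement.

Schedules (k = generation, T = maxgen, ws = omega_start, we = omega_end):

    constant    w = 1
    lin_a       ws - (ws - we) * k/T          (linearly decreasing inertia
    lin_b       we + (ws - we) * (T - k)/T     weight; the two forms are
                                               algebraically identical and
                                               both ids are kept because
                                               they are reported as separate
                                               experimental arms)
    quad_late   ws - (ws - we) * (k/T)**2      (slow early decay)
    quad_early  ws - (ws - we) * (2k/T - (k/T)**2)  (fast early decay)
    exp_ratio   we * (ws/we) ** (1 / (1 + c*k/T))   (never reaches we)

The fitness is maximized.  The per-generation trace records V_best, the
running maximum of every fitness evaluated so far (monotone by
construction), and V_ave, the mean fitness of the current swarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCHEDULES",
    "SwarmConfig",
    "SwarmState",
    "FitnessTrace",
    "inertia_weight",
    "update_velocity",
    "update_position",
    "pso_optimize",
]

SCHEDULES = ("constant", "lin_a", "lin_b", "quad_late", "quad_early", "exp_ratio")

# default search box over (C, g, m): brackets reported optima with headroom
DEFAULT_BOUNDS = ((0.1, 100.0), (0.01, 50.0), (0.01, 0.99))


@dataclass
class SwarmConfig:
    """Swarm size, schedule and box for one PSO run.

    ``vmax`` defaults to 0.2 * (upper - lower) per dimension.  ``c_exp``
    is the shape constant of the ``exp_ratio`` schedule.
    """

    n: int = 20
    dim: int = 3
    maxgen: int = 200
    c1: float = 1.49445
    c2: float = 1.49445
    omega_start: float = 0.9
    omega_end: float = 0.4
    schedule: str = "constant"
    c_exp: float = 10.0
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS
    vmax: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"particle count must be >= 2, got {self.n}")
        if self.maxgen < 1:
            raise ValueError(f"maxgen must be >= 1, got {self.maxgen}")
        if self.schedule not in SCHEDULES:
            raise ValueError(
                f"unknown schedule {self.schedule!r}; choose from {SCHEDULES}"
            )
        bounds = np.asarray(self.bounds, dtype=float)
        if bounds.shape != (self.dim, 2):
            raise ValueError(
                f"bounds must be {self.dim} (lower, upper) pairs, got shape {bounds.shape}"
            )
        if np.any(bounds[:, 0] >= bounds[:, 1]):
            raise ValueError("each lower bound must be strictly below its upper bound")
        self.bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
        if self.vmax is None:
            self.vmax = tuple(0.2 * (hi - lo) for lo, hi in self.bounds)
        else:
            vmax = np.asarray(self.vmax, dtype=float).ravel()
            if vmax.shape[0] != self.dim or np.any(vmax <= 0):
                raise ValueError("vmax must give a positive cap per dimension")
            self.vmax = tuple(float(v) for v in vmax)

    @property
    def lower(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([hi for _, hi in self.bounds])

    @property
    def vmax_arr(self) -> np.ndarray:
        return np.asarray(self.vmax, dtype=float)


@dataclass
class SwarmState:
    """Positions/velocities plus personal and global bests at generation k."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    generation: int = 0


@dataclass
class FitnessTrace:
    """Per-generation V_best (running max), V_ave (swarm mean) and omega."""

    v_best: np.ndarray
    v_ave: np.ndarray
    omega: np.ndarray | None = None

    def __post_init__(self):
        self.v_best = np.asarray(self.v_best, dtype=float).ravel()
        self.v_ave = np.asarray(self.v_ave, dtype=float).ravel()
        if self.v_best.shape != self.v_ave.shape:
            raise ValueError("V_best and V_ave must have the same length")
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=float).ravel()

    def __len__(self) -> int:
        return self.v_best.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "generation": np.arange(1, len(self) + 1),
                "v_best": self.v_best,
                "v_ave": self.v_ave,
            }
        )
        if self.omega is not None:
            df["omega"] = self.omega
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FitnessTrace":
        df = pd.read_csv(path)
        omega = df["omega"].to_numpy() if "omega" in df.columns else None
        return cls(df["v_best"].to_numpy(), df["v_ave"].to_numpy(), omega)


def inertia_weight(schedule: str, k: int, cfg: SwarmConfig) -> float:
    """Inertia weight at generation k (0 <= k <= maxgen) under ``schedule``."""
    if schedule not in SCHEDULES:
        raise ValueError(f"unknown schedule {schedule!r}; choose from {SCHEDULES}")
    if not 0 <= k <= cfg.maxgen:
        raise ValueError(f"generation {k} outside [0, {cfg.maxgen}]")
    ws, we, T = cfg.omega_start, cfg.omega_end, cfg.maxgen
    t = k / T
    if schedule == "constant":
        return 1.0
    if schedule in ("lin_a", "lin_b"):
        return ws - (ws - we) * t
    if schedule == "quad_late":
        return ws - (ws - we) * t**2
    if schedule == "quad_early":
        return ws - (ws - we) * (2.0 * t - t**2)
    # exp_ratio
    return we * (ws / we) ** (1.0 / (1.0 + cfg.c_exp * t))


def update_velocity(
    state: SwarmState, omega: float, cfg: SwarmConfig, rng: np.random.Generator
) -> np.ndarray:
    """Inertia + cognitive + social update, clamped to [-vmax, vmax]."""
    n, d = state.positions.shape
    r1 = rng.random((n, d))
    r2 = rng.random((n, d))
    v = (
        omega * state.velocities
        + cfg.c1 * r1 * (state.pbest_positions - state.positions)
        + cfg.c2 * r2 * (state.gbest_position[None, :] - state.positions)
    )
    np.clip(v, -cfg.vmax_arr, cfg.vmax_arr, out=v)
    state.velocities = v
    return v


def update_position(state: SwarmState, cfg: SwarmConfig) -> np.ndarray:
    """x <- x + v, clamped to the box; clamped components get zero velocity."""
    x = state.positions + state.velocities
    lo, hi = cfg.lower, cfg.upper
    clamped = (x < lo) | (x > hi)
    np.clip(x, lo, hi, out=x)
    state.velocities = np.where(clamped, 0.0, state.velocities)
    state.positions = x
    return x


def _evaluate(fitness_fn, X: np.ndarray, generation: int) -> np.ndarray:
    fits = np.empty(X.shape[0])
    for i, x in enumerate(X):
        try:
            fits[i] = fitness_fn(x)
        except Exception as err:
            raise RuntimeError(
                f"fitness evaluation failed at generation {generation}, "
                f"particle {i}, position {x}"
            ) from err
    return fits


def pso_optimize(
    fitness_fn: Callable[[np.ndarray], float], cfg: SwarmConfig
) -> tuple[np.ndarray, float, FitnessTrace]:
    """Maximize ``fitness_fn`` over the configured box.

    Runs ``maxgen`` generations from a seeded uniform initialization and
    returns ``(best_position, best_fitness, trace)``.  The trace has one
    row per generation; V_best is the running maximum of all evaluations
    (initial swarm included), V_ave the mean of the current swarm's
    fitnesses.  Personal/global best ties keep the first achiever.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi, vmax = cfg.lower, cfg.upper, cfg.vmax_arr
    X = rng.uniform(lo, hi, size=(cfg.n, cfg.dim))
    V = rng.uniform(-vmax, vmax, size=(cfg.n, cfg.dim))
    fits = _evaluate(fitness_fn, X, generation=0)
    best = int(np.argmax(fits))
    state = SwarmState(
        positions=X,
        velocities=V,
        pbest_positions=X.copy(),
        pbest_fitness=fits.copy(),
        gbest_position=X[best].copy(),
        gbest_fitness=float(fits[best]),
    )

    v_best = np.empty(cfg.maxgen)
    v_ave = np.empty(cfg.maxgen)
    omegas = np.empty(cfg.maxgen)
    for k in range(1, cfg.maxgen + 1):
        omega = inertia_weight(cfg.schedule, k, cfg)
        update_velocity(state, omega, cfg, rng)
        update_position(state, cfg)
        fits = _evaluate(fitness_fn, state.positions, generation=k)
        improved = fits > state.pbest_fitness  # strict: ties keep first achiever
        state.pbest_fitness[improved] = fits[improved]
        state.pbest_positions[improved] = state.positions[improved]
        best = int(np.argmax(state.pbest_fitness))
        if state.pbest_fitness[best] > state.gbest_fitness:
            state.gbest_fitness = float(state.pbest_fitness[best])
            state.gbest_position = state.pbest_positions[best].copy()
        state.generation = k
        v_best[k - 1] = state.gbest_fitness
        v_ave[k - 1] = fits.mean()
        omegas[k - 1] = omega

    trace = FitnessTrace(v_best, v_ave, omegas)
    return state.gbest_position.copy(), state.gbest_fitness, trace
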