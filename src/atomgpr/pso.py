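"""Particle swarm optimization of the kernel hyperparameters.

The marginal likelihood surface over theta is multimodal, so the scales
are fit by a plain global PSO with inertia/cognitive/social rates
(defaults 0.729 / 1.490 / 1.490), box bounds [0, 3] per dimension, and a
relative-difference stall rule: the swarm stops once the global best has
moved by less than ``sigma_thresh`` (relative) for ``n_stall`` consecutive
iterations.

Positions *and* velocities are initialized uniformly on
``[theta_min, theta_max]``; positions are clamped to the box with the
velocity zeroed on any clamped dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .gpr import IllConditionedModelError

__all__ = ["SwarmConfig", "SwarmState", "optimize", "converged", "step",
           "update_velocity"]


@dataclass
class SwarmConfig:
    omega: float = 0.729
    phi_p: float = 1.490
    phi_g: float = 1.490
    theta_min: float = 0.0
    theta_max: float = 3.0
    sigma_thresh: float = 1e-7
    n_stall: int = 20
    n_particles: int | None = None  # default: max(4*ndim, 50)
    max_iter: int = 1000
    seed: int = 0

    def particles(self, ndim: int) -> int:
        return self.n_particles if self.n_particles else max(4 * ndim, 50)


@dataclass
class SwarmState:
    positions: np.ndarray       # (nparticles, ndim)
    velocities: np.ndarray
    p_best: np.ndarray          # per-particle best positions
    p_best_val: np.ndarray
    g_best: np.ndarray
    g_best_val: float
    best_history: list[float] = field(default_factory=list)


def update_velocity(state: SwarmState, config: SwarmConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """v <- omega*v + phi_p*r1*(p - x) + phi_g*r2*(g - x).

    r1, r2 are uniform(0,1) draws per particle *per dimension*.
    """
    shape = state.positions.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    return (config.omega * state.velocities
            + config.phi_p * r1 * (state.p_best - state.positions)
            + config.phi_g * r2 * (state.g_best - state.positions))


def _evaluate(objective: Callable[[np.ndarray], float],
              positions: np.ndarray) -> np.ndarray:
    vals = np.empty(len(positions))
    for i, x in enumerate(positions):
        try:
            vals[i] = objective(x)
        except IllConditionedModelError:
            vals[i] = -np.inf
    return vals


def step(state: SwarmState, config: SwarmConfig,
         objective: Callable[[np.ndarray], float],
         rng: np.random.Generator) -> SwarmState:
    """One swarm cycle: move, clamp, evaluate, update bests once."""
    v = update_velocity(state, config, rng)
    x = state.positions + v
    low = x < config.theta_min
    high = x > config.theta_max
    x = np.clip(x, config.theta_min, config.theta_max)
    v = np.where(low | high, 0.0, v)

    vals = _evaluate(objective, x)
    improved = vals > state.p_best_val
    state.p_best = np.where(improved[:, None], x, state.p_best)
    state.p_best_val = np.where(improved, vals, state.p_best_val)
    best = int(np.argmax(state.p_best_val))
    if state.p_best_val[best] > state.g_best_val:
        state.g_best = state.p_best[best].copy()
        state.g_best_val = float(state.p_best_val[best])
    state.positions, state.velocities = x, v
    state.best_history.append(state.g_best_val)
    return state


def converged(best_history: list[float], config: SwarmConfig) -> bool:
    """True iff the last ``n_stall`` steps each moved the global best by a
    relative amount below ``sigma_thresh`` (absolute when the reference
    value is zero)."""
    if len(best_history) < config.n_stall + 1:
        return False
    tail = best_history[-(config.n_stall + 1):]
    for prev, cur in zip(tail, tail[1:]):
        diff = abs(cur - prev)
        rel = diff if prev == 0 else diff / abs(prev)
        if not rel < config.sigma_thresh:
            return False
    return True


def optimize(objective: Callable[[np.ndarray], float], ndim: int,
             config: SwarmConfig | None = None,
             rng: np.random.Generator | None = None
             ) -> tuple[np.ndarray, float, dict]:
    """Maximize ``objective`` over the theta box.

    Returns ``(theta_best, value_best, diagnostics)`` where diagnostics
    holds the per-iteration global-best trace and a convergence flag.
    """
    if ndim < 1:
        raise ValueError("ndim must be >= 1")
    config = config or SwarmConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    npart = config.particles(ndim)
    positions = rng.uniform(config.theta_min, config.theta_max, (npart, ndim))
    velocities = rng.uniform(config.theta_min, config.theta_max, (npart, ndim))
    vals = _evaluate(objective, positions)
    best = int(np.argmax(vals))
    state = SwarmState(
        positions=positions, velocities=velocities,
        p_best=positions.copy(), p_best_val=vals,
        g_best=positions[best].copy(), g_best_val=float(vals[best]),
        best_history=[float(vals[best])],
    )
    flag = False
    for _ in range(config.max_iter):
        step(state, config, objective, rng)
        if converged(state.best_history, config):
            flag = True
            break
    diagnostics = {"best_history": list(state.best_history),
                   "converged": flag,
                   "n_iterations": len(state.best_history) - 1}
    return state.g_best.copy(), state.g_best_val, diagnostics
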