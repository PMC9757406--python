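"""Moth-flame optimization (MFO).

A population metaheuristic: candidate solutions (moths) spiral toward an
elite archive of the best positions found so far (flames).  Each moth i
moves toward flame j = min(i, n_flames−1) along a logarithmic helix,

    new_k = L_k · exp(b·t_k) · cos(2π·t_k) + flame_k,

where L_k = |flame_k − moth_k| is the per-dimension distance, b the helix
shape constant and t a path coefficient drawn uniformly from [r, 1] with r
shrinking linearly from −1 to −2 over the run (so late moves hug the
flame).  The flame archive is the best-N merge of the previous flames and
the current moths, sorted by fitness, and the number of flames decays
linearly from N to 1 — progressively concentrating the search on the best
solution.  Objectives are minimized.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MFOConfig",
    "OptimizationResult",
    "spiral_step",
    "flame_count",
    "clip",
    "optimize",
]


@dataclass
class MFOConfig:
    """Optimizer settings.

    Bounds may be scalars or per-dimension vectors; ``spiral_constant`` is
    the logarithmic-helix shape constant b.
    """

    n_agents: int = 50
    dimension: int = 30
    lower_bound: float | np.ndarray = -100.0
    upper_bound: float | np.ndarray = 100.0
    max_iterations: int = 1000
    spiral_constant: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        self.lower_bound = np.broadcast_to(
            np.asarray(self.lower_bound, dtype=float), (self.dimension,)
        ).copy()
        self.upper_bound = np.broadcast_to(
            np.asarray(self.upper_bound, dtype=float), (self.dimension,)
        ).copy()
        if not np.all(self.lower_bound < self.upper_bound):
            raise ValueError("lower_bound must be < upper_bound element-wise")


@dataclass
class OptimizationResult:
    """Best position/fitness, best-so-far trace and evaluation count."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    evaluations: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.trace) > 0):
            raise ValueError("best-so-far trace must be non-increasing")
        if self.trace.size and self.best_fitness != self.trace[-1]:
            raise ValueError("best_fitness must equal the last trace entry")

    def write_trace(self, path: str | Path) -> None:
        """Export the convergence trace as CSV (iteration, best_fitness)."""
        with open(path, "w") as fh:
            fh.write("iteration,best_fitness\n")
            for i, v in enumerate(self.trace, start=1):
                fh.write(f"{i},{v!r}\n")


def spiral_step(
    moth: np.ndarray, flame: np.ndarray, b: float, t: np.ndarray
) -> np.ndarray:
    """One logarithmic-helix move of a moth toward a flame.

    Per dimension k: L = |flame_k − moth_k|; new_k = L·e^{b·t_k}·cos(2π·t_k)
    + flame_k.  A moth sitting on its flame stays there exactly (L = 0).
    """
    moth = np.asarray(moth, dtype=float)
    flame = np.asarray(flame, dtype=float)
    t = np.asarray(t, dtype=float)
    L = np.abs(flame - moth)
    return L * np.exp(b * t) * np.cos(2 * np.pi * t) + flame


def flame_count(iteration: int, max_iterations: int, n_agents: int) -> int:
    """Linearly decaying flame count: N at the start, 1 at the last iteration."""
    n = round(n_agents - iteration * (n_agents - 1) / max_iterations)
    return max(1, int(n))


def clip(position: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Component-wise clamp into the [lb, ub] box."""
    return np.clip(position, lb, ub)


def optimize(
    objective: Callable[[np.ndarray], float],
    config: MFOConfig,
    initial_positions: Sequence[np.ndarray] | None = None,
    callback: Callable[[int, float], None] | None = None,
) -> OptimizationResult:
    """Minimize ``objective`` over the configured box.

    Parameters
    ----------
    objective : callable
        Maps a position (1-D array of length ``dimension``) to a finite
        scalar; smaller is better.
    initial_positions : sequence of arrays, optional
        Positions that overwrite the first moths of the random initial
        population (e.g. a known-good incumbent, guaranteeing the result
        is at least as good by elitism).
    callback : callable, optional
        Called as ``callback(iteration, best_so_far)`` once per iteration.

    Raises
    ------
    RuntimeError
        If the objective returns a non-finite value; the message names
        the offending position.
    """
    lb, ub = config.lower_bound, config.upper_bound
    N, D, T = config.n_agents, config.dimension, config.max_iterations
    rng = np.random.default_rng(config.seed)
    moths = lb + rng.random((N, D)) * (ub - lb)
    if initial_positions is not None:
        if len(initial_positions) > N:
            raise ValueError("more initial positions than agents")
        for i, pos in enumerate(initial_positions):
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (D,):
                raise ValueError(f"initial position {i} has shape {pos.shape}")
            moths[i] = pos

    def evaluate(batch: np.ndarray) -> np.ndarray:
        out = np.empty(len(batch))
        for i, pos in enumerate(batch):
            val = float(objective(pos))
            if not np.isfinite(val):
                raise RuntimeError(
                    f"objective returned non-finite value {val!r} at position {pos}"
                )
            out[i] = val
        return out

    flame_pos: np.ndarray | None = None
    flame_fit: np.ndarray | None = None
    trace = np.empty(T)
    evaluations = 0
    for l in range(1, T + 1):
        moths = clip(moths, lb, ub)
        fitness = evaluate(moths)
        evaluations += N
        if flame_pos is None:
            order = np.argsort(fitness, kind="stable")
            flame_pos = moths[order].copy()
            flame_fit = fitness[order].copy()
        else:
            pool_pos = np.vstack([flame_pos, moths])
            pool_fit = np.concatenate([flame_fit, fitness])
            order = np.argsort(pool_fit, kind="stable")[:N]
            flame_pos = pool_pos[order].copy()
            flame_fit = pool_fit[order].copy()
        trace[l - 1] = flame_fit[0]
        if callback is not None:
            callback(l, float(flame_fit[0]))
        n_flames = flame_count(l, T, N)
        r = -1.0 - l / T  # shrinks from ~−1 to −2
        t = rng.uniform(r, 1.0, size=(N, D))
        for i in range(N):
            j = min(i, n_flames - 1)
            moths[i] = spiral_step(moths[i], flame_pos[j], config.spiral_constant, t[i])
    return OptimizationResult(
        best_position=flame_pos[0].copy(),
        best_fitness=float(flame_fit[0]),
        trace=trace,
        evaluations=evaluations,
    )
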