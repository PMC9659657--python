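"""Baseline whale optimization primitives.

The whale optimization algorithm (WOA) moves a population of candidate
solutions with three behaviors: encircling the current leader
(``X* - A |C X* - X|``), a logarithmic spiral around the leader
(``D' e^{bl} cos(2 pi l) + X*``), and exploration around a random member
(``X_rand - A |C X_rand - X|``). The control parameter ``a1`` decays
linearly from 2 to 0 over the evaluation budget and ``a2`` from -1 to -2;
``A = 2 a1 r - a1`` and ``C = 2 r`` with ``r ~ U[0,1]`` drawn per
dimension, the branch probability ``p`` and spiral shape ``l`` drawn once
per individual per generation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["schedule", "clip_to_bounds", "woa_move", "woa_update",
           "woa_population_step"]

SPIRAL_B = 1.0


def schedule(fes: int, max_fes: int) -> tuple[float, float]:
    """Linear control-parameter schedules (a1, a2) at evaluation count fes."""
    if not 0 <= fes <= max_fes:
        raise ValueError(f"fes must be in [0, {max_fes}], got {fes}")
    frac = fes / max_fes
    return 2.0 - 2.0 * frac, -1.0 - frac


def clip_to_bounds(x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    return np.clip(x, lb, ub)


def woa_move(x, leader, x_rand, A, C, p, l, b: float = SPIRAL_B):
    """One position update with all random draws supplied explicitly.

    ``A`` and ``C`` are per-dimension vectors; the encircle/explore branch
    is resolved per dimension on |A| < 1, the spiral branch on p >= 0.5.
    Exposed separately from :func:`woa_update` so tests can force branches.
    """
    x = np.asarray(x, float)
    leader = np.asarray(leader, float)
    x_rand = np.asarray(x_rand, float)
    A = np.asarray(A, float)
    C = np.asarray(C, float)
    if p >= 0.5:
        d_prime = np.abs(leader - x)
        return d_prime * np.exp(b * l) * np.cos(2.0 * np.pi * l) + leader
    encircle = leader - A * np.abs(C * leader - x)
    explore = x_rand - A * np.abs(C * x_rand - x)
    return np.where(np.abs(A) < 1.0, encircle, explore)


def woa_update(x, leader, x_rand, a1: float, a2: float, rng) -> np.ndarray:
    """One position update drawing p, l per individual and r per dimension."""
    dim = len(np.asarray(x))
    p = rng.random()
    r1 = rng.random(dim)
    r2 = rng.random(dim)
    A = 2.0 * a1 * r1 - a1
    C = 2.0 * r2
    l = (a2 - 1.0) * rng.random() + 1.0
    return woa_move(x, leader, x_rand, A, C, p, l)


def woa_population_step(X, leader_pos, a1: float, a2: float, rng):
    """Vectorized position update of the whole population.

    Each individual's exploration partner is drawn uniformly from the
    population excluding itself. Returns the new position matrix; the
    caller is responsible for boundary repair and re-evaluation.
    """
    X = np.asarray(X, float)
    n, dim = X.shape
    p = rng.random(n)
    r1 = rng.random((n, dim))
    r2 = rng.random((n, dim))
    A = 2.0 * a1 * r1 - a1
    C = 2.0 * r2
    l = (a2 - 1.0) * rng.random((n, 1)) + 1.0
    idx = rng.integers(0, n - 1, size=n)
    idx[idx >= np.arange(n)] += 1  # exclude self
    Xr = X[idx]

    encircle = leader_pos - A * np.abs(C * leader_pos - X)
    explore = Xr - A * np.abs(C * Xr - X)
    contract = np.where(np.abs(A) < 1.0, encircle, explore)
    d_prime = np.abs(leader_pos - X)
    spiral = d_prime * np.exp(SPIRAL_B * l) * np.cos(2.0 * np.pi * l) + leader_pos
    return np.where((p < 0.5)[:, None], contract, spiral)
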