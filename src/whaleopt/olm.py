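"""Orthogonal learning mechanism (OLM).

A Taguchi-style refinement step: dimensions are randomly partitioned into
F factors; for each factor, Q levels interpolate between a whale's current
position (level 1) and a guide exemplar (level Q); a strength-2 orthogonal
array prescribes M = Q^2 trial combinations; factor analysis of the trial
fitnesses predicts a best combination, and the best of the M+1 evaluated
vectors is returned. The guide exemplar is located from three random
population members as ``X_k1 + rand(1,dim) .* (X_k2 - X_k3)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["OrthogonalPlan", "build_oa", "partition_factors", "locate_leader",
           "level_value", "olm_refine", "make_plan"]


def _is_prime(q: int) -> bool:
    if q < 2:
        return False
    return all(q % p for p in range(2, int(math.isqrt(q)) + 1))


def build_oa(Q: int, F: int) -> np.ndarray:
    """Strength-2 orthogonal array with Q^J rows over F factors at Q levels.

    Standard linear construction over GF(Q) for prime Q: rows are the
    J-tuples over GF(Q), columns the nonzero direction vectors with leading
    coefficient 1, entries ``row . col mod Q`` mapped to levels 1..Q. For
    (Q, F) = (3, 4) this is the L9(3^4) array.
    """
    if Q < 2 or not _is_prime(Q):
        raise ValueError(f"Q must be a prime >= 2, got {Q}")
    if F < 1:
        raise ValueError(f"F must be >= 1, got {F}")
    J = 2
    while (Q ** J - 1) // (Q - 1) < F:
        J += 1
        if Q ** J > 10 ** 6:
            raise ValueError(f"(Q={Q}, F={F}) is not supported")
    rows = np.array(np.meshgrid(*[range(Q)] * J, indexing="ij")).reshape(J, -1).T
    cols = []
    for v in np.array(np.meshgrid(*[range(Q)] * J, indexing="ij")).reshape(J, -1).T:
        nz = np.nonzero(v)[0]
        if len(nz) and v[nz[0]] == 1:
            cols.append(v)
        if len(cols) == F:
            break
    cols = np.array(cols)
    return (rows @ cols.T) % Q + 1


def partition_factors(dim: int, F: int, rng) -> np.ndarray:
    """Random balanced assignment of each dimension to one of F factors."""
    if dim < F:
        raise ValueError(f"dim ({dim}) must be >= F ({F})")
    base, rem = divmod(dim, F)
    counts = [base + 1] * rem + [base] * (F - rem)
    labels = np.repeat(np.arange(F), counts)
    return labels[rng.permutation(dim)]


@dataclass
class OrthogonalPlan:
    Q: int
    F: int
    oa: np.ndarray
    factor_of_dim: np.ndarray

    @property
    def M(self) -> int:
        return self.oa.shape[0]


def make_plan(dim: int, rng, Q: int = 3, F: int = 4) -> OrthogonalPlan:
    return OrthogonalPlan(Q=Q, F=F, oa=build_oa(Q, F),
                          factor_of_dim=partition_factors(dim, F, rng))


def locate_leader(X, rng, lb=None, ub=None) -> np.ndarray:
    """Guide exemplar from three distinct random population members."""
    X = np.asarray(X, dtype=float)
    n, dim = X.shape
    if n < 3:
        raise ValueError(f"need >= 3 individuals, got {n}")
    k1, k2, k3 = rng.choice(n, size=3, replace=False)
    leader = X[k1] + rng.random(dim) * (X[k2] - X[k3])
    if lb is not None:
        leader = np.clip(leader, lb, ub)
    return leader


def level_value(xi: float, xj: float, q: int, Q: int) -> float:
    """Level-q interpolant between xi (level 1) and xj (level Q)."""
    if Q < 2:
        raise ValueError(f"Q must be >= 2, got {Q}")
    if not 1 <= q <= Q:
        raise ValueError(f"q must be in [1, {Q}], got {q}")
    return xi + (q - 1) / (Q - 1) * (xj - xi)


def olm_refine(x, leader, plan: OrthogonalPlan, objective, fes_budget: int):
    """Orthogonal-array trial refinement of one individual.

    Returns ``(candidate, fitness, fes_used)``. If the budget cannot cover
    the M trials plus the predicted combination, the step is skipped and
    ``(x, inf, 0)`` is returned. Delta ties are broken toward the lowest
    level index, and the candidate is always the best evaluated vector
    (never worse than the best trial).
    """
    x = np.asarray(x, dtype=float)
    leader = np.asarray(leader, dtype=float)
    M, Q, F = plan.M, plan.Q, plan.F
    if fes_budget < M + 1:
        return x.copy(), float("inf"), 0

    span = leader - x
    levels = plan.oa[:, plan.factor_of_dim]          # (M, dim), entries 1..Q
    trials = x + (levels - 1) / (Q - 1) * span
    fits = np.array([objective(t) for t in trials])

    # factor analysis: average trial fitness per (factor, level)
    delta = np.empty((F, Q))
    for f in range(F):
        for q in range(Q):
            delta[f, q] = (Q / M) * fits[plan.oa[:, f] == q + 1].sum()
    best_levels = delta.argmin(axis=1) + 1           # ties -> lowest level
    pred_levels = best_levels[plan.factor_of_dim]
    predicted = x + (pred_levels - 1) / (Q - 1) * span
    pred_fit = objective(predicted)

    i_best = int(np.argmin(fits))
    if fits[i_best] <= pred_fit:
        return trials[i_best].copy(), float(fits[i_best]), M + 1
    return predicted, float(pred_fit), M + 1
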