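"""Optimizer engines: WOA, CMWOA, OWOA, COWOA and a standalone CMS loop.

COWOA spends the first half of its evaluation budget on WOA position
updates assisted by the orthogonal learning mechanism (OLM) and the second
half on the covariance matrix strategy (CMS), seeded from the population
present at the handover. CMWOA and OWOA are the single-mechanism
ablations; with both mechanisms disabled the engine reproduces baseline
WOA exactly.

All runners share the signature ``(problem, n, max_fes, seed) ->
OptResult`` and exact function-evaluation accounting: the problem's
evaluation counter advance equals ``fes_used``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .cms import cms_init, cms_sample, cms_update
from .olm import locate_leader, make_plan, olm_refine
from .problems import Problem
from .woa import clip_to_bounds, schedule, woa_population_step

__all__ = ["OptResult", "run_woa", "run_cmwoa", "run_owoa", "run_cowoa",
           "run_cms", "RUNNERS"]


@dataclass
class OptResult:
    best_pos: np.ndarray
    best_fit: float
    curve: list  # (fes, best-so-far) pairs, sampled once per generation
    fes_used: int
    seed: int
    phase_switch_fes: Optional[int] = None

    def to_json(self) -> str:
        d = asdict(self)
        d["best_pos"] = np.asarray(self.best_pos).tolist()
        d["curve"] = [[int(f), float(v)] for f, v in self.curve]
        return json.dumps(d)


def _run(problem: Problem, n: int, max_fes: int, seed: int, *,
         use_olm: bool, use_cms: bool, olm_every: str = "generation",
         paper_literal_eq25: bool = False, cms_mean: str = "best",
         early_stop: bool = False) -> OptResult:
    if n < 4:
        raise ValueError(f"population size must be >= 4, got {n}")
    if max_fes < n:
        raise ValueError(f"max_fes ({max_fes}) must be >= population size ({n})")
    if olm_every not in ("generation", "whale"):
        raise ValueError(f"olm_every must be 'generation' or 'whale', got {olm_every!r}")

    rng = np.random.default_rng(seed)
    dim = problem.dim
    lb, ub = problem.lower_bound, problem.upper_bound
    X = lb + rng.random((n, dim)) * (ub - lb)
    fitness = np.full(n, np.inf)
    prev_fitness = None
    leader_pos = X[0].copy()
    leader_score = np.inf
    curve: list[tuple[int, float]] = []
    fes = 0
    phase_switch = max_fes // 2 if use_cms else None
    plan = make_plan(dim, rng) if use_olm else None
    cms_state = None
    cms_active = False
    start_counter = problem.eval_counter

    def note_best(pos_block, fit_block):
        nonlocal leader_pos, leader_score
        i = int(np.argmin(fit_block))
        if fit_block[i] < leader_score:
            leader_score = float(fit_block[i])
            leader_pos = pos_block[i].copy()

    def olm_objective(v):
        return problem.evaluate(clip_to_bounds(v, lb, ub))

    def hit_optimum():
        return (early_stop and problem.f_star is not None
                and leader_score <= problem.f_star + 1e-12)

    while fes < max_fes and not hit_optimum():
        if cms_active:
            m = min(n, max_fes - fes)
            Xs = clip_to_bounds(cms_sample(cms_state, m, rng), lb, ub)
            f = problem.evaluate_many(Xs)
            fes += m
            note_best(Xs, f)
            curve.append((fes, leader_score))
            if m == n:
                cms_state = cms_update(cms_state, Xs, f,
                                       paper_literal_eq25=paper_literal_eq25)
            continue

        # --- evaluation phase (first-half / plain WOA path) ---
        m = min(n, max_fes - fes)
        X[:m] = clip_to_bounds(X[:m], lb, ub)
        f = problem.evaluate_many(X[:m])
        fes += m
        note_best(X[:m], f)
        curve.append((fes, leader_score))
        improvement = None
        if prev_fitness is not None and m == n:
            improvement = prev_fitness - f
        fitness[:m] = f
        if fes >= max_fes:
            break

        if use_cms and fes >= phase_switch:
            cms_active = True
            cms_state = cms_init(X, fitness, lb, ub, mean_on=cms_mean, rng=rng)
            continue

        # --- position-update phase ---
        a1, a2 = schedule(fes, max_fes)
        prev_fitness = fitness.copy()
        X = woa_population_step(X, leader_pos, a1, a2, rng)

        if use_olm:
            if olm_every == "whale":
                targets = list(range(n))
            elif improvement is None:
                targets = [int(np.argmax(fitness))]       # first generation
            else:
                targets = [int(np.argmin(improvement))]   # least-improved whale
            for t in targets:
                if max_fes - fes < plan.M + 1:
                    break
                g_leader = locate_leader(X, rng, lb, ub)
                cand, cf, used = olm_refine(
                    clip_to_bounds(X[t], lb, ub), g_leader, plan,
                    olm_objective, max_fes - fes)
                fes += used
                if used == 0:
                    break
                if cf < leader_score:
                    leader_score = float(cf)
                    leader_pos = cand.copy()
                if cf < fitness[t]:
                    X[t] = cand
                    fitness[t] = cf
                    prev_fitness[t] = cf

    assert problem.eval_counter - start_counter == fes
    return OptResult(best_pos=leader_pos, best_fit=leader_score, curve=curve,
                     fes_used=fes, seed=seed, phase_switch_fes=phase_switch)


def run_woa(problem, n, max_fes, seed, **kw) -> OptResult:
    """Baseline whale optimization."""
    return _run(problem, n, max_fes, seed, use_olm=False, use_cms=False, **kw)


def run_cmwoa(problem, n, max_fes, seed, **kw) -> OptResult:
    """WOA first half, covariance matrix strategy second half (no OLM)."""
    return _run(problem, n, max_fes, seed, use_olm=False, use_cms=True, **kw)


def run_owoa(problem, n, max_fes, seed, **kw) -> OptResult:
    """WOA with orthogonal learning throughout (no CMS)."""
    return _run(problem, n, max_fes, seed, use_olm=True, use_cms=False, **kw)


def run_cowoa(problem, n, max_fes, seed, **kw) -> OptResult:
    """Full dual-mechanism engine: WOA+OLM first half, CMS second half."""
    return _run(problem, n, max_fes, seed, use_olm=True, use_cms=True, **kw)


def run_cms(problem, n, max_fes, seed,
            paper_literal_eq25: bool = False) -> OptResult:
    """Standalone CMS loop from a random initial population."""
    if n < 4:
        raise ValueError(f"population size must be >= 4, got {n}")
    if max_fes < 2 * n:
        raise ValueError(f"max_fes ({max_fes}) must be >= 2n ({2 * n})")
    rng = np.random.default_rng(seed)
    lb, ub = problem.lower_bound, problem.upper_bound
    X = lb + rng.random((n, problem.dim)) * (ub - lb)
    f = problem.evaluate_many(X)
    fes = n
    i = int(np.argmin(f))
    leader_pos, leader_score = X[i].copy(), float(f[i])
    curve = [(fes, leader_score)]
    state = cms_init(X, f, lb, ub)
    while fes < max_fes:
        m = min(n, max_fes - fes)
        Xs = clip_to_bounds(cms_sample(state, m, rng), lb, ub)
        fs = problem.evaluate_many(Xs)
        fes += m
        i = int(np.argmin(fs))
        if fs[i] < leader_score:
            leader_score = float(fs[i])
            leader_pos = Xs[i].copy()
        curve.append((fes, leader_score))
        if m == n:
            state = cms_update(state, Xs, fs,
                               paper_literal_eq25=paper_literal_eq25)
    return OptResult(best_pos=leader_pos, best_fit=leader_score, curve=curve,
                     fes_used=fes, seed=seed, phase_switch_fes=None)


RUNNERS = {
    "woa": run_woa,
    "cmwoa": run_cmwoa,
    "owoa": run_owoa,
    "cowoa": run_cowoa,
    "cms": run_cms,
}
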