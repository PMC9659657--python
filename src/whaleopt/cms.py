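"""Covariance matrix strategy (CMS).

A CMA-ES-style Gaussian search engine: candidates are sampled as
``m + sigma * N(0, C)``, the mean is recombined from the mu best samples
with log-decreasing weights, the covariance receives rank-1 (evolution
path ``Pc``) and rank-mu updates, and the step size ``sigma`` adapts from
the conjugate path ``Psigma`` against the expected norm of a standard
Gaussian vector (chiN).

Learning rates follow the construction used here: ``c1 = 2/D^2``,
``c_mu = min(mu_eff/D^2, 1 - c1)``, ``cc = 4/(D+4)``,
``c_sigma = (mu_eff+2)/(D+mu_eff+3)`` and the usual damping ``d_sigma``.
The decay factor of ``Pc`` is (1 - c1); by default ``Psigma`` decays with
(1 - c_sigma) (the normalization-consistent choice), with
``paper_literal_eq25=True`` switching the decay to (1 - cc).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["CMSState", "cms_init", "cms_sample", "cms_update",
           "repair_covariance"]

EIG_FLOOR = 1e-12


@dataclass
class CMSState:
    m: np.ndarray
    sigma: float
    C: np.ndarray
    Pc: np.ndarray
    Psigma: np.ndarray
    mu: int
    weights: np.ndarray
    mu_eff: float
    c1: float
    c_mu: float
    cc: float
    c_sigma: float
    d_sigma: float
    chiN: float

    @property
    def dim(self) -> int:
        return len(self.m)

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items()}
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "CMSState":
        d = json.loads(s)
        for k in ("m", "C", "Pc", "Psigma", "weights"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def repair_covariance(C: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Symmetrize and clip eigenvalues to keep C a valid covariance."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"covariance must be square, got shape {C.shape}")
    S = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(S)
    if w.min() >= floor:
        return S
    w = np.maximum(w, floor)
    out = (V * w) @ V.T
    return 0.5 * (out + out.T)


def _default_weights(mu: int) -> np.ndarray:
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    return w / w.sum()


def cms_init(X, fitness, lb, ub, mean_on: str = "best", rng=None) -> CMSState:
    """Initialize the CMS from an evaluated population.

    The distribution mean starts at the population's best individual
    (``mean_on="random"`` picks a random individual instead). The initial
    step size is the ratio S_best/S, where S_best is the mean squared
    per-dimension deviation of the best individual from the population
    mean position and S sums that quantity over all individuals; a
    degenerate population falls back to 0.3 times the mean bound width.
    """
    X = np.asarray(X, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    n, dim = X.shape
    if n < 2:
        raise ValueError(f"population must have >= 2 members, got {n}")
    mean_pos = X.mean(axis=0)
    best = int(np.argmin(fitness))
    dev = X - mean_pos
    S_best = float((dev[best] ** 2).mean())
    S = float((dev ** 2).mean(axis=1).sum())
    sigma = S_best / S if S > 0 else 0.0
    if sigma <= 0:
        sigma = 0.3 * float(np.mean(np.asarray(ub, float) - np.asarray(lb, float)))
    if mean_on == "random":
        if rng is None:
            raise ValueError("mean_on='random' requires an rng")
        m = X[int(rng.integers(n))].copy()
    else:
        m = X[best].copy()

    mu = n // 2
    weights = _default_weights(mu)
    mu_eff = 1.0 / float((weights ** 2).sum())
    c1 = 2.0 / dim ** 2
    c_mu = min(mu_eff / dim ** 2, 1.0 - c1)
    cc = 4.0 / (dim + 4.0)
    c_sigma = (mu_eff + 2.0) / (dim + mu_eff + 3.0)
    d_sigma = 1.0 + 2.0 * max(0.0, np.sqrt((mu_eff - 1.0) / (dim + 1.0)) - 1.0) + c_sigma
    chiN = np.sqrt(dim) * (1.0 - 1.0 / (4.0 * dim) + 1.0 / (21.0 * dim ** 2))
    return CMSState(
        m=m, sigma=float(sigma), C=np.eye(dim),
        Pc=np.zeros(dim), Psigma=np.zeros(dim),
        mu=mu, weights=weights, mu_eff=mu_eff,
        c1=c1, c_mu=c_mu, cc=cc, c_sigma=c_sigma, d_sigma=d_sigma,
        chiN=float(chiN),
    )


def _eig_sqrt(C: np.ndarray):
    w, V = np.linalg.eigh(C)
    w = np.maximum(w, EIG_FLOOR)
    return w, V


def cms_sample(state: CMSState, n: int, rng) -> np.ndarray:
    """Draw n candidates from m + sigma * N(0, C)."""
    w, V = _eig_sqrt(state.C)
    Z = rng.standard_normal((n, state.dim))
    return state.m + state.sigma * (Z @ (V * np.sqrt(w)).T)


def cms_update(state: CMSState, samples, fitness,
               paper_literal_eq25: bool = False) -> CMSState:
    """One generation of mean/path/covariance/step-size adaptation."""
    samples = np.asarray(samples, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    if not np.all(np.isfinite(fitness)):
        raise ValueError("non-finite fitness values in CMS update")
    if samples.shape[0] < state.mu:
        raise ValueError(
            f"need at least mu={state.mu} samples, got {samples.shape[0]}")
    order = np.argsort(fitness, kind="stable")
    Xmu = samples[order[: state.mu]]
    w = state.weights
    m_new = w @ Xmu
    delta = (m_new - state.m) / state.sigma

    # conjugate step-size path
    ew, V = _eig_sqrt(state.C)
    C_inv_half = (V / np.sqrt(ew)) @ V.T
    decay = (1.0 - state.cc) if paper_literal_eq25 else (1.0 - state.c_sigma)
    Psigma = decay * state.Psigma + np.sqrt(
        state.c_sigma * (2.0 - state.c_sigma) * state.mu_eff) * (C_inv_half @ delta)
    sigma = state.sigma * np.exp(
        (state.c_sigma / state.d_sigma)
        * (np.linalg.norm(Psigma) / state.chiN - 1.0))

    # covariance evolution path and rank-1 / rank-mu updates
    Pc = (1.0 - state.c1) * state.Pc + np.sqrt(
        state.cc * (2.0 - state.cc) * state.mu_eff) * delta
    Y = (Xmu - state.m) / state.sigma
    rank_mu = (Y.T * w) @ Y
    C = ((1.0 - state.c1 - state.c_mu) * state.C
         + state.c1 * np.outer(Pc, Pc)
         + state.c_mu * rank_mu)
    C = repair_covariance(C)

    return CMSState(
        m=m_new, sigma=float(sigma), C=C, Pc=Pc, Psigma=Psigma,
        mu=state.mu, weights=state.weights, mu_eff=state.mu_eff,
        c1=state.c1, c_mu=state.c_mu, cc=state.cc,
        c_sigma=state.c_sigma, d_sigma=state.d_sigma, chiN=state.chiN,
    )
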