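"""Shifted/rotated continuous benchmark problems.

The suite wraps fourteen classic base functions (elliptic, cigar, discus,
Rosenbrock, Ackley, Weierstrass, Griewank, Rastrigin, modified Schwefel,
Katsuura, HappyCat, HGBat, expanded Schaffer F6, sphere) in a seeded random
shift and rotation, mirroring the construction of the standard CEC-style
test suites: ``f(x) = f_base(M (x - o)) + bias`` on the box [-100, 100]^D,
with the shift ``o`` drawn uniformly in [-80, 80]^D so that the optimum is
interior. Every base function evaluates to exactly 0 at the origin, so the
known optimum value of each problem is its bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["Problem", "FAMILIES", "random_orthogonal_matrix", "make_problem"]


def random_orthogonal_matrix(dim: int, seed: int) -> np.ndarray:
    """Seeded random orthogonal matrix (QR of a Gaussian, sign-fixed).

    Multiplying by the sign of R's diagonal makes the factorization unique,
    which both fixes determinism and yields the Haar distribution.
    """
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((dim, dim))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))


# ---------------------------------------------------------------------------
# Base functions. Each takes Z of shape (m, D) and returns shape (m,).
# All satisfy f(0) = 0 exactly in floating point.

def _sphere(Z):
    return (Z ** 2).sum(axis=1)


def _elliptic(Z):
    D = Z.shape[1]
    if D == 1:
        w = np.ones(1)
    else:
        w = 10.0 ** (6.0 * np.arange(D) / (D - 1))
    return (Z ** 2) @ w


def _bent_cigar(Z):
    return Z[:, 0] ** 2 + 1e6 * (Z[:, 1:] ** 2).sum(axis=1)


def _discus(Z):
    return 1e6 * Z[:, 0] ** 2 + (Z[:, 1:] ** 2).sum(axis=1)


def _rosenbrock(Z):
    # CEC-style input scaling places the optimum at the origin.
    Y = Z * (2.048 / 100.0) + 1.0
    if Z.shape[1] == 1:
        return 100.0 * (Y[:, 0] - Y[:, 0] ** 2) ** 2 + (Y[:, 0] - 1.0) ** 2
    a = Y[:, :-1]
    b = Y[:, 1:]
    return (100.0 * (b - a ** 2) ** 2 + (a - 1.0) ** 2).sum(axis=1)


def _ackley(Z):
    D = Z.shape[1]
    s1 = np.sqrt((Z ** 2).mean(axis=1))
    s2 = np.cos(2.0 * np.pi * Z).mean(axis=1)
    return -20.0 * np.exp(-0.2 * s1) - np.exp(s2) + 20.0 + np.exp(1.0)


_W_A, _W_B, _W_KMAX = 0.5, 3.0, 20


def _weierstrass(Z):
    D = Z.shape[1]
    k = np.arange(_W_KMAX + 1)
    ak = _W_A ** k
    bk = _W_B ** k
    total = np.zeros(Z.shape[0])
    for aki, bki in zip(ak, bk):
        total += aki * np.cos(2.0 * np.pi * bki * (Z + 0.5)).sum(axis=1)
    const = D * float((ak * np.cos(np.pi * bk)).sum())
    return total - const


def _griewank(Z):
    D = Z.shape[1]
    s = (Z ** 2).sum(axis=1) / 4000.0
    p = np.cos(Z / np.sqrt(np.arange(1, D + 1))).prod(axis=1)
    return s - p + 1.0


def _rastrigin(Z):
    return (Z ** 2 - 10.0 * np.cos(2.0 * np.pi * Z) + 10.0).sum(axis=1)


_SCHWEFEL_Z0 = 4.209687462275036e2


def _schwefel(Z):
    # Modified (bounded) Schwefel; offset computed from the same g so the
    # value at the origin cancels exactly.
    D = Z.shape[1]
    z = Z * 10.0 + _SCHWEFEL_Z0

    def g(zi):
        out = np.empty_like(zi)
        inside = np.abs(zi) <= 500.0
        out[inside] = zi[inside] * np.sin(np.sqrt(np.abs(zi[inside])))
        hi = zi > 500.0
        if hi.any():
            t = 500.0 - np.mod(zi[hi], 500.0)
            out[hi] = t * np.sin(np.sqrt(np.abs(t))) - (zi[hi] - 500.0) ** 2 / (10000.0 * D)
        lo = zi < -500.0
        if lo.any():
            t = np.mod(np.abs(zi[lo]), 500.0) - 500.0
            out[lo] = t * np.sin(np.sqrt(np.abs(t))) - (zi[lo] + 500.0) ** 2 / (10000.0 * D)
        return out

    g0 = _SCHWEFEL_Z0 * np.sin(np.sqrt(_SCHWEFEL_Z0))
    return (g0 - g(z)).sum(axis=1)


def _katsuura(Z):
    D = Z.shape[1]
    z = Z * (5.0 / 100.0)
    j = 2.0 ** np.arange(1, 33)
    t = z[:, :, None] * j
    s = (np.abs(t - np.round(t)) / j).sum(axis=2)  # (m, D)
    expo = 10.0 / D ** 1.2
    prod = ((1.0 + np.arange(1, D + 1) * s) ** expo).prod(axis=1)
    return (10.0 / D ** 2) * (prod - 1.0)


def _happycat(Z):
    D = Z.shape[1]
    z = Z * (5.0 / 100.0) - 1.0
    r2 = (z ** 2).sum(axis=1)
    s = z.sum(axis=1)
    return np.abs(r2 - D) ** 0.25 + (0.5 * r2 + s) / D + 0.5


def _hgbat(Z):
    D = Z.shape[1]
    z = Z * (5.0 / 100.0) - 1.0
    r2 = (z ** 2).sum(axis=1)
    s = z.sum(axis=1)
    return np.sqrt(np.abs(r2 ** 2 - s ** 2)) + (0.5 * r2 + s) / D + 0.5


def _schaffer_pair(x, y):
    r2 = x ** 2 + y ** 2
    return 0.5 + (np.sin(np.sqrt(r2)) ** 2 - 0.5) / (1.0 + 0.001 * r2) ** 2


def _scaffer_f6(Z):
    Y = np.roll(Z, -1, axis=1)
    return _schaffer_pair(Z, Y).sum(axis=1)


FAMILIES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "elliptic": _elliptic,
    "bent_cigar": _bent_cigar,
    "discus": _discus,
    "rosenbrock": _rosenbrock,
    "ackley": _ackley,
    "weierstrass": _weierstrass,
    "griewank": _griewank,
    "rastrigin": _rastrigin,
    "schwefel": _schwefel,
    "katsuura": _katsuura,
    "happycat": _happycat,
    "hgbat": _hgbat,
    "scaffer_f6": _scaffer_f6,
    "sphere": _sphere,
}


@dataclass
class Problem:
    """A continuous minimization problem with evaluation accounting.

    ``eval_counter`` increments by one per point evaluated, whether points
    are submitted singly or as a batch.
    """

    dim: int
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    func: Callable[[np.ndarray], np.ndarray]
    f_star: Optional[float] = None
    name: str = "problem"
    shift: Optional[np.ndarray] = None
    rotation: Optional[np.ndarray] = None
    eval_counter: int = field(default=0)

    def evaluate(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ValueError(f"expected shape ({self.dim},), got {x.shape}")
        self.eval_counter += 1
        return float(self.func(x[None, :])[0])

    def evaluate_many(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.dim:
            raise ValueError(f"expected shape (m, {self.dim}), got {X.shape}")
        self.eval_counter += X.shape[0]
        return np.asarray(self.func(X), dtype=float)


def make_problem(family: str, dim: int, seed: int, bias: float = 0.0) -> Problem:
    """Build a shifted/rotated problem instance.

    The shift is drawn uniformly in [-80, 80]^dim and the rotation is a
    seeded random orthogonal matrix; evaluation is
    ``f_base(M (x - shift)) + bias`` on bounds [-100, 100]^dim.
    """
    if family not in FAMILIES:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-80.0, 80.0, size=dim)
    M = random_orthogonal_matrix(dim, seed=int(rng.integers(2 ** 31)))
    base = FAMILIES[family]

    def func(X: np.ndarray) -> np.ndarray:
        return base((X - shift) @ M.T) + bias

    return Problem(
        dim=dim,
        lower_bound=np.full(dim, -100.0),
        upper_bound=np.full(dim, 100.0),
        func=func,
        f_star=float(bias),
        name=f"{family}_d{dim}_s{seed}",
        shift=shift,
        rotation=M,
    )
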