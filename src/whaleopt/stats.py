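"""Multi-run benchmark harness and statistical comparison.

Runs a list of optimizers over a list of problems with matched seeds per
(problem, run) pair, and summarizes the final best-fitness samples as
AVG/STD tables, per-problem Wilcoxon signed-rank tests against a
reference algorithm (two-sided, zero differences dropped), and Friedman
mean ranks (per-problem ranks of the per-algorithm averages, ties
averaged, lower is better under minimization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonTable", "wilcoxon_signed_rank", "friedman_mean_ranks",
           "run_trials"]


def wilcoxon_signed_rank(a, b) -> tuple[float, str]:
    """Two-sided Wilcoxon signed-rank p-value and a better/worse sign.

    The sign is "+" when p < 0.05 and median(a) < median(b) (a is better
    under minimization), "-" when p < 0.05 and median(a) > median(b), and
    "=" otherwise. All-tied samples give p = 1 and "=".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D vectors")
    if len(a) < 5:
        raise ValueError(f"need >= 5 pairs, got {len(a)}")
    d = a - b
    if np.all(d == 0):
        return 1.0, "="
    p = float(sps.wilcoxon(a, b, zero_method="wilcox",
                           alternative="two-sided").pvalue)
    if p < 0.05:
        ma, mb = np.median(a), np.median(b)
        if ma < mb:
            return p, "+"
        if ma > mb:
            return p, "-"
    return p, "="


def friedman_mean_ranks(values) -> np.ndarray:
    """Mean rank per algorithm from a (problems x algorithms) value matrix.

    Within each problem the algorithms are ranked 1 = lowest value, ties
    receive average ranks; ranks are then averaged over problems.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a (>=2 problems) x (>=2 algorithms) matrix")
    if np.isnan(values).any():
        raise ValueError("NaN in results matrix")
    ranks = np.apply_along_axis(sps.rankdata, 1, values)
    return ranks.mean(axis=0)


@dataclass
class ComparisonTable:
    algorithms: list
    functions: list
    avg: np.ndarray            # (algorithms x functions)
    std: np.ndarray
    pvalues: np.ndarray        # vs algorithms[0]
    signs: np.ndarray          # entries in {+, =, -}, for algorithms[0] vs each
    friedman_mean_rank: np.ndarray
    finals: dict = field(default_factory=dict)  # (alg, func) -> per-run finals

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": 1,
            "algorithms": list(self.algorithms),
            "functions": list(self.functions),
            "avg": self.avg.tolist(),
            "std": self.std.tolist(),
            "pvalues": self.pvalues.tolist(),
            "signs": self.signs.tolist(),
            "friedman_mean_rank": self.friedman_mean_rank.tolist(),
            "finals": {f"{a}::{f}": np.asarray(v).tolist()
                       for (a, f), v in self.finals.items()},
        })

    def to_csv(self) -> str:
        lines = ["algorithm,function,avg,std,pvalue_vs_ref,sign"]
        for i, a in enumerate(self.algorithms):
            for j, f in enumerate(self.functions):
                lines.append(f"{a},{f},{self.avg[i, j]!r},{self.std[i, j]!r},"
                             f"{self.pvalues[i, j]!r},{self.signs[i, j]}")
        return "\n".join(lines) + "\n"


def _pair_seed(base_seed: int, prob_idx: int, run: int) -> int:
    return int((base_seed * 1_000_003 + prob_idx * 10_007 + run * 101) % (2 ** 31))


def run_trials(algorithms, problems, n_runs: int, max_fes: int,
               base_seed: int, n_pop: int = 30) -> ComparisonTable:
    """Run every algorithm on every problem with matched per-run seeds.

    ``algorithms`` is a list of (name, runner) pairs with the shared runner
    contract ``runner(problem, n, max_fes, seed) -> OptResult``. Signs in
    the table compare the first (reference) algorithm against each other
    algorithm; "+" means the reference is significantly better.
    """
    algorithms = list(algorithms)
    problems = list(problems)
    if not algorithms or not problems:
        raise ValueError("need at least one algorithm and one problem")
    if n_runs < 2:
        raise ValueError(f"n_runs must be >= 2, got {n_runs}")
    names = [a[0] for a in algorithms]
    fnames = [p.name for p in problems]
    A, F = len(algorithms), len(problems)
    finals = {}
    for j, prob in enumerate(problems):
        for name, runner in algorithms:
            vals = np.empty(n_runs)
            for r in range(n_runs):
                before = prob.eval_counter
                res = runner(prob, n_pop, max_fes, _pair_seed(base_seed, j, r))
                used = prob.eval_counter - before
                if used > max_fes:
                    raise RuntimeError(
                        f"{name} spent {used} evaluations (> {max_fes})")
                vals[r] = res.best_fit
            finals[(name, prob.name)] = vals

    avg = np.empty((A, F))
    std = np.empty((A, F))
    pvalues = np.ones((A, F))
    signs = np.full((A, F), "=", dtype=object)
    for i, name in enumerate(names):
        for j, fn in enumerate(fnames):
            v = finals[(name, fn)]
            avg[i, j] = v.mean()
            std[i, j] = v.std(ddof=1)
            if i > 0 and n_runs >= 5:
                p, s = wilcoxon_signed_rank(finals[(names[0], fn)], v)
                pvalues[i, j] = p
                signs[i, j] = s
    ranks = friedman_mean_ranks(avg.T)
    return ComparisonTable(algorithms=names, functions=fnames, avg=avg,
                           std=std, pvalues=pvalues, signs=signs,
                           friedman_mean_rank=ranks, finals=finals)
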