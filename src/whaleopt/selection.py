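"""Binary wrapper feature selection with a KELM inner evaluator.

Continuous whale-engine positions in [0, 1]^D are mapped to feature masks
through the gentle S-shaped transfer ``sigmoid(x) = 1/(1 + e^{-x/3})``
with stochastic thresholding (bit d set iff sigmoid(x_d) >= r_d,
r_d ~ U[0,1]); all-zero masks are repaired by setting one random bit. A
mask is scored as ``fitness = alpha * error + beta * |R|/|D|`` with
alpha = 0.99, beta = 0.01, where the error is the KELM misclassification
rate on a seed-fixed stratified 80/20 holdout of the training partition.

The outer protocol is repeated stratified k-fold cross-validation: the
optimizer and the final KELM see only the training partition of each
fold; accuracy, specificity, precision and F-measure are computed on the
held-out fold, and per-feature selection counts are accumulated across
repeats and folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_X_y, check_is_fitted

from .cms import cms_init, cms_sample, cms_update
from .kelm import DEFAULT_REG_C, KELMClassifier
from .olm import locate_leader, make_plan, olm_refine
from .woa import schedule, woa_population_step

__all__ = ["sigmoid_transfer", "binarize", "fitness", "confusion_metrics",
           "HoldoutMaskEvaluator", "evaluate_mask", "run_binary_optimizer",
           "exhaustive_best_mask", "kfold_protocol", "FSResult",
           "WhaleFeatureSelector"]

ALPHA = 0.99
BETA = 0.01


def sigmoid_transfer(x):
    """S-shaped transfer 1/(1 + e^{-x/3}), elementwise."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float) / 3.0))


def binarize(x_cont, rng) -> np.ndarray:
    """Stochastic threshold of a continuous position into a feature mask."""
    x_cont = np.asarray(x_cont, dtype=float)
    bits = sigmoid_transfer(x_cont) >= rng.random(len(x_cont))
    if not bits.any():
        bits[rng.integers(len(bits))] = True
    return bits


def fitness(error: float, n_selected: int, D: int,
            alpha: float = ALPHA, beta: float = BETA) -> float:
    """Wrapper objective: alpha * error + beta * n_selected / D."""
    if D < 1:
        raise ValueError(f"D must be >= 1, got {D}")
    if not 0 <= n_selected <= D:
        raise ValueError(f"n_selected must be in [0, {D}], got {n_selected}")
    if not 0.0 <= error <= 1.0:
        raise ValueError(f"error must be in [0, 1], got {error}")
    return alpha * error + beta * n_selected / D


def confusion_metrics(y_true, y_pred, positive_label=1) -> dict:
    """Accuracy, specificity, precision, recall and F-measure (harmonic).

    Ratios with zero denominators are reported as 0 and flagged in the
    returned ``degenerate`` list (with a warning).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or len(y_true) < 1:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            warnings.warn(f"{name} undefined (zero denominator); reported as 0")
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f_den = precision + recall
    if f_den == 0:
        degenerate.append("f_measure")
        f_measure = 0.0
    else:
        f_measure = 2.0 * precision * recall / f_den
    return {
        "accuracy": (tp + tn) / len(y_true),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure,
        "degenerate": degenerate,
    }


class HoldoutMaskEvaluator:
    """Memoized KELM holdout error for feature masks.

    Splits the supplied training partition once (stratified 80/20, seeded),
    z-scores features with inner-train statistics, and evaluates each mask
    by assembling the masked RBF kernel from the selected columns directly
    (a single GEMM), solving the regularized kernel system in single
    precision, and scoring the held-out split. Identical masks return
    cached errors, keeping wrapper runs deterministic and fast.

    ``max_train`` optionally caps the inner-train side by stratified
    subsampling for very large datasets (off by default).
    """

    def __init__(self, X, y, seed: int, test_size: float = 0.2,
                 max_train: int | None = None,
                 gamma: float | None = None, reg_C: float = DEFAULT_REG_C):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.n_features = X.shape[1]
        self.gamma = gamma
        self.reg_C = reg_C
        classes, counts = np.unique(y, return_counts=True)
        self._degenerate = len(classes) < 2 or counts.min() < 2
        if self._degenerate:
            return
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=seed % (2 ** 31))
        if max_train is not None and len(X_tr) > max_train:
            X_tr, _, y_tr, _ = train_test_split(
                X_tr, y_tr, train_size=max_train, stratify=y_tr,
                random_state=(seed + 1) % (2 ** 31))
        mean = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z_tr = (X_tr - mean) / sd
        Z_val = (X_val - mean) / sd
        self._Zb = np.vstack([Z_tr, Z_val]).astype(np.float32)
        self._sq = self._Zb ** 2
        cls, y_idx = np.unique(y_tr, return_inverse=True)
        self._T = np.zeros((len(y_tr), len(cls)), dtype=np.float32)
        self._T[np.arange(len(y_tr)), y_idx] = 1.0
        self._ridge = (np.eye(len(y_tr)) / reg_C).astype(np.float32)
        self._classes = cls
        self._y_val = y_val
        self._n_tr = len(y_tr)
        self._cache: dict[bytes, float] = {}

    def error(self, mask) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_features,):
            raise ValueError(f"mask must have length {self.n_features}")
        if not mask.any():
            raise ValueError("mask selects no features (repair it first)")
        if self._degenerate:
            return 1.0
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        k = int(mask.sum())
        gamma = self.gamma if self.gamma is not None else float(np.sqrt(k))
        g2 = gamma ** 2
        Zs = self._Zb[:, mask]
        sq = self._sq[:, mask].sum(axis=1)
        n_tr = self._n_tr
        # squared distances via GEMM on the selected columns only
        D2 = sq[:, None] + sq[None, :n_tr] - 2.0 * (Zs @ Zs[:n_tr].T)
        np.maximum(D2, 0.0, out=D2)
        K = np.exp(D2 / np.float32(-g2))
        K_tr, K_val = K[:n_tr], K[n_tr:]
        A = K_tr + self._ridge
        beta = cho_solve(cho_factor(A, lower=True, check_finite=False),
                         self._T, check_finite=False)
        pred = self._classes[np.argmax(K_val @ beta, axis=1)]
        err = float(np.mean(pred != self._y_val))
        self._cache[key] = err
        return err


def evaluate_mask(mask, X_train, y_train, kelm_params: dict | None = None,
                  seed: int = 0) -> float:
    """KELM holdout misclassification rate for one mask (deterministic)."""
    ev = HoldoutMaskEvaluator(X_train, y_train, seed=seed,
                              **(kelm_params or {}))
    return ev.error(mask)


def run_binary_optimizer(X, y, algorithm: str = "bcowoa", n_pop: int = 20,
                         n_iter: int = 100, seed: int = 0,
                         evaluator: HoldoutMaskEvaluator | None = None,
                         alpha: float = ALPHA, beta: float = BETA,
                         kelm_params: dict | None = None):
    """Binary whale-engine wrapper search over feature masks.

    ``algorithm`` is "bcowoa" (WOA+OLM for the first half of the iteration
    budget, CMS for the second half) or "bwoa" (plain WOA throughout).
    Returns ``(best_mask, best_fitness, curve)`` with a non-increasing
    best-fitness curve sampled once per iteration.
    """
    if algorithm not in ("bcowoa", "bwoa"):
        raise ValueError(f"algorithm must be 'bcowoa' or 'bwoa', got {algorithm!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0 or len(y) == 0:
        raise ValueError("empty dataset")
    D = X.shape[1]
    rng = np.random.default_rng(seed)
    if evaluator is None:
        evaluator = HoldoutMaskEvaluator(
            X, y, seed=int(rng.integers(2 ** 31)), **(kelm_params or {}))

    pos = rng.random((n_pop, D))
    best_mask, best_fit = None, np.inf
    leader_pos = pos[0].copy()
    curve = []
    phase_switch = n_iter // 2 if algorithm == "bcowoa" else n_iter
    plan = make_plan(D, rng) if algorithm == "bcowoa" else None
    cms_state = None
    prev_fits = None

    def score(x_cont) -> float:
        mask = binarize(np.clip(x_cont, 0.0, 1.0), rng)
        err = evaluator.error(mask)
        fit = alpha * err + beta * mask.sum() / D
        nonlocal best_mask, best_fit, leader_pos
        if fit < best_fit:
            best_fit = fit
            best_mask = mask
            leader_pos = np.clip(np.asarray(x_cont, float), 0.0, 1.0).copy()
        return fit

    for t in range(n_iter):
        fits = np.array([score(p) for p in pos])
        curve.append(best_fit)
        if t == n_iter - 1:
            break
        if t >= phase_switch:
            if cms_state is None:
                cms_state = cms_init(pos, fits, np.zeros(D), np.ones(D))
            else:
                cms_state = cms_update(cms_state, pos, fits)
            pos = np.clip(cms_sample(cms_state, n_pop, rng), 0.0, 1.0)
        else:
            a1, a2 = schedule(t, n_iter)
            improvement = prev_fits - fits if prev_fits is not None else None
            prev_fits = fits
            pos = np.clip(woa_population_step(pos, leader_pos, a1, a2, rng),
                          0.0, 1.0)
            if plan is not None:
                target = int(np.argmin(improvement)) if improvement is not None \
                    else int(np.argmax(fits))
                g_leader = locate_leader(pos, rng, 0.0, 1.0)
                cand, cf, used = olm_refine(pos[target], g_leader, plan,
                                            score, plan.M + 1)
                if used and cf < fits[target]:
                    pos[target] = np.clip(cand, 0.0, 1.0)
                    prev_fits[target] = cf
    return best_mask, float(best_fit), curve


def exhaustive_best_mask(evaluator: HoldoutMaskEvaluator, D: int,
                         alpha: float = ALPHA, beta: float = BETA):
    """Brute-force fitness minimum over all 2^D - 1 non-empty masks."""
    if D > 15:
        raise ValueError("exhaustive search is limited to D <= 15")
    best_mask, best_fit = None, np.inf
    for code in range(1, 2 ** D):
        mask = np.array([(code >> d) & 1 for d in range(D)], dtype=bool)
        fit = alpha * evaluator.error(mask) + beta * mask.sum() / D
        if fit < best_fit:
            best_fit, best_mask = fit, mask
    return best_mask, float(best_fit)


@dataclass
class FSResult:
    per_fold: list               # dicts: repeat, fold, mask, n_selected, metrics
    avg: dict
    std: dict
    selection_counts: np.ndarray
    n_runs: int

    def to_json(self) -> str:
        folds = [{**{k: v for k, v in rec.items() if k != "mask"},
                  "mask": np.asarray(rec["mask"]).astype(int).tolist()}
                 for rec in self.per_fold]
        return json.dumps({
            "schema_version": 1,
            "per_fold": folds,
            "avg": self.avg,
            "std": self.std,
            "selection_counts": self.selection_counts.tolist(),
            "n_runs": self.n_runs,
        })

    def to_csv(self) -> str:
        cols = ["accuracy", "specificity", "precision", "f_measure"]
        lines = ["fold,n_selected," + ",".join(cols)]
        for i, rec in enumerate(self.per_fold, start=1):
            lines.append(f"#{i},{rec['n_selected']}," +
                         ",".join(f"{rec[c]:.4f}" for c in cols))
        lines.append("AVG,," + ",".join(f"{self.avg[c]:.4f}" for c in cols))
        lines.append("STD,," + ",".join(f"{self.std[c]:.4f}" for c in cols))
        return "\n".join(lines) + "\n"


def kfold_protocol(X, y, algorithm: str = "bcowoa", k: int = 10,
                   repeats: int = 1, seed: int = 0, n_pop: int = 20,
                   n_iter: int = 100, gamma: float | None = None,
                   reg_C: float = DEFAULT_REG_C,
                   positive_label=1) -> FSResult:
    """Repeated stratified k-fold wrapper-selection protocol.

    Per repeat x fold: the optimizer searches masks on the training
    partition only, a KELM is fit on the masked training data, and the
    four confusion metrics are computed on the held-out fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    min_class = np.unique(y, return_counts=True)[1].min()
    if min_class < k:
        warnings.warn(f"smallest class has {min_class} members; reducing "
                      f"k from {k} to {min_class}")
        k = int(min_class)
    D = X.shape[1]
    selection_counts = np.zeros(D, dtype=int)
    per_fold = []
    run = 0
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=(seed + 7919 * rep) % (2 ** 31))
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            run_seed = (seed * 100003 + rep * 1009 + fold) % (2 ** 31)
            evaluator = HoldoutMaskEvaluator(
                X[tr], y[tr], seed=run_seed, gamma=gamma, reg_C=reg_C)
            mask, _, _ = run_binary_optimizer(
                X[tr], y[tr], algorithm=algorithm, n_pop=n_pop,
                n_iter=n_iter, seed=run_seed, evaluator=evaluator)
            model = KELMClassifier(gamma=gamma, reg_C=reg_C)
            model.fit(X[tr][:, mask], y[tr])
            pred = model.predict(X[te][:, mask])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = confusion_metrics(y[te], pred, positive_label=positive_label)
            selection_counts += mask.astype(int)
            per_fold.append({
                "repeat": rep, "fold": fold, "mask": mask,
                "n_selected": int(mask.sum()),
                "accuracy": m["accuracy"], "specificity": m["specificity"],
                "precision": m["precision"], "f_measure": m["f_measure"],
            })
            run += 1
    cols = ["accuracy", "specificity", "precision", "f_measure"]
    avg = {c: float(np.mean([r[c] for r in per_fold])) for c in cols}
    std = {c: float(np.std([r[c] for r in per_fold], ddof=1))
           if len(per_fold) > 1 else 0.0 for c in cols}
    return FSResult(per_fold=per_fold, avg=avg, std=std,
                    selection_counts=selection_counts, n_runs=run)


class WhaleFeatureSelector(SelectorMixin, BaseEstimator):
    """sklearn-compatible wrapper feature selector.

    Fits a binary whale-engine search (bCOWOA by default) scored by the
    KELM holdout error plus sparsity penalty, exposing the selected mask
    through the standard ``get_support`` / ``transform`` interface.
    """

    def __init__(self, algorithm: str = "bcowoa", n_pop: int = 20,
                 n_iter: int = 100, gamma: float | None = None,
                 reg_C: float = DEFAULT_REG_C, alpha: float = ALPHA,
                 beta: float = BETA, random_state: int = 0):
        self.algorithm = algorithm
        self.n_pop = n_pop
        self.n_iter = n_iter
        self.gamma = gamma
        self.reg_C = reg_C
        self.alpha = alpha
        self.beta = beta
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        mask, fit, curve = run_binary_optimizer(
            X, y, algorithm=self.algorithm, n_pop=self.n_pop,
            n_iter=self.n_iter, seed=self.random_state,
            alpha=self.alpha, beta=self.beta,
            kelm_params={"gamma": self.gamma, "reg_C": self.reg_C})
        self.support_ = mask
        self.best_fitness_ = fit
        self.fitness_curve_ = curve
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
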