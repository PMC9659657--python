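"""Synthetic tabular classification datasets with planted structure.

Two generators are provided. ``generate_classification`` plants
``k_informative`` class-separated Gaussian features among standard-normal
noise columns. ``generate_hd_like`` emulates a hemodialysis cohort for
intradialytic-hypotension (IDH) prediction: 1239 sessions, 36 numeric
clinical features, 649 non-IDH / 590 IDH, with eight planted informative
features (platelet-lymphocyte ratio, mean arterial pressure, white blood
cells, gender, ultrafiltration volume, dialysis vintage,
monocyte-lymphocyte and neutrophil-monocyte ratios) whose class-wise
marginals are matched to published medians and interquartile ranges.

The generators are deterministic per seed and are first-class tested code:
every downstream pipeline stage (KELM, wrapper selection, the k-fold
protocol) is exercised against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["Dataset", "generate_classification", "generate_hd_like",
           "planted_recovery_score", "HD_FEATURES", "HD_PLANTED_CODES"]

_IQR_Z = 2.0 * norm.ppf(0.75)  # ~1.349: IQR of a standard normal


@dataclass
class Dataset:
    X: np.ndarray
    y: np.ndarray
    feature_names: list
    planted: Optional[frozenset] = None  # informative feature indices
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def generate_classification(n: int, D: int, k_informative: int,
                            effect: float, class_balance: float = 0.5,
                            correlation: float = 0.0, seed: int = 0) -> Dataset:
    """Planted-feature binary classification data.

    Informative features are class-conditional Gaussians with mean
    separation ``effect`` (in SD units) and optional equicorrelation
    within the informative block; noise features are standard normal.
    Labels are Bernoulli(class_balance) for class 1.
    """
    if not 1 <= k_informative <= D:
        raise ValueError(f"k_informative must be in [1, {D}], got {k_informative}")
    if not 0 < class_balance < 1:
        raise ValueError(f"class_balance must be in (0, 1), got {class_balance}")
    if not 0 <= correlation < 1:
        raise ValueError(f"correlation must be in [0, 1), got {correlation}")
    if effect < 0:
        raise ValueError(f"effect must be >= 0, got {effect}")
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < class_balance).astype(int)
    if y.min() == y.max():  # force both classes present
        y[rng.integers(n)] = 1 - y[0]
    planted = np.sort(rng.choice(D, size=k_informative, replace=False))
    X = rng.standard_normal((n, D))
    Zinf = rng.standard_normal((n, k_informative))
    if correlation > 0:
        cov = np.full((k_informative, k_informative), correlation)
        np.fill_diagonal(cov, 1.0)
        Zinf = Zinf @ np.linalg.cholesky(cov).T
    X[:, planted] = Zinf + effect * y[:, None]
    names = [f"X{j + 1}" for j in range(D)]
    return Dataset(X=X, y=y, feature_names=names,
                   planted=frozenset(int(i) for i in planted), seed=seed)


# ---------------------------------------------------------------------------
# Hemodialysis-like cohort.
#
# Rows: (code, kind, non-IDH (median, IQR), IDH (median, IQR)).
# kind: "normal", "lognormal" (right-skewed clinical durations/volumes) or
# "bernoulli" (the (median, IQR) slots then hold the class rates).

HD_FEATURES = [
    ("F1_dialysis_vintage", "lognormal", (68.0, 74.0), (100.0, 124.0)),
    ("F2_diabetes", "bernoulli", (0.4, 0.0), (0.4, 0.0)),
    ("F3_ultrafiltration_volume", "lognormal", (2.0, 1.0), (2.2, 1.0)),
    ("F4_age", "normal", (66.0, 18.0), (66.0, 13.0)),
    ("F5_dry_weight", "normal", (56.1, 14.7), (54.0, 12.9)),
    ("F6_pre_dialysis_weight", "normal", (58.1, 14.5), (56.2, 13.9)),
    ("F7_interdialytic_weight_gain", "normal", (1.9, 1.0), (2.1, 1.0)),
    ("F8_pct_interdialytic_weight_gain", "normal", (3.46, 2.23), (3.87, 1.78)),
    ("F9_systolic_bp", "normal", (133.0, 29.0), (150.0, 30.0)),
    ("F10_diastolic_bp", "normal", (74.0, 15.0), (79.0, 17.0)),
    ("F11_mean_arterial_pressure", "normal", (93.0, 18.0), (103.0, 19.0)),
    ("F12_heart_rate", "normal", (76.0, 16.0), (77.0, 15.0)),
    ("F13_gender", "bernoulli", (0.59, 0.0), (0.55, 0.0)),
    ("F14_white_blood_cell", "normal", (5.39, 1.83), (5.25, 2.37)),
    ("F15_neutrophil_pct", "normal", (65.0, 8.9), (64.4, 13.2)),
    ("F16_eosinophil_pct", "normal", (3.3, 3.5), (3.1, 3.5)),
    ("F17_basophil_pct", "normal", (0.1, 0.2), (0.2, 0.3)),
    ("F18_monocyte_pct", "normal", (7.3, 3.2), (8.0, 3.5)),
    ("F19_lymphocyte_pct", "normal", (22.0, 9.7), (22.3, 10.0)),
    ("F20_neutrophil_lymphocyte_ratio", "normal", (3.03, 1.70), (2.90, 1.92)),
    ("F21_monocyte_lymphocyte_ratio", "normal", (0.33, 0.19), (0.37, 0.22)),
    ("F22_platelet_lymphocyte_ratio", "normal", (145.5, 91.3), (145.5, 82.9)),
    ("F23_neutrophil_monocyte_ratio", "normal", (8.76, 4.48), (8.76, 5.06)),
    ("F24_red_blood_cell", "normal", (3.64, 0.50), (3.57, 0.61)),
    ("F25_hemoglobin", "normal", (114.0, 13.0), (114.0, 16.0)),
    ("F26_hematocrit", "normal", (0.34, 0.04), (0.35, 0.06)),
    ("F27_mean_corpuscular_volume", "normal", (95.6, 5.3), (96.1, 6.1)),
    ("F28_mean_corpuscular_hemoglobin", "normal", (31.3, 2.1), (31.0, 2.1)),
    ("F29_mchc", "normal", (327.0, 10.0), (324.0, 12.0)),
    ("F30_rdw_cv", "normal", (13.8, 1.1), (14.3, 1.2)),
    ("F31_rdw_sd", "normal", (48.1, 4.3), (48.8, 6.2)),
    ("F32_platelet", "normal", (177.0, 86.0), (187.0, 80.0)),
    ("F33_thrombocytocrit", "normal", (0.19, 0.08), (0.19, 0.07)),
    ("F34_mean_platelet_volume", "normal", (10.4, 1.2), (10.4, 1.1)),
    ("F35_platelet_distribution_sd", "normal", (11.9, 2.4), (12.2, 2.5)),
    ("F36_platelet_large_cell_ratio", "normal", (27.8, 9.8), (27.7, 9.0)),
]

HD_PLANTED_CODES = ("F22", "F11", "F14", "F13", "F3", "F1", "F21", "F23")

HD_N_NON_IDH = 649
HD_N_IDH = 590

# Minimum standardized class separation imposed on planted *continuous*
# features. Several published per-class medians coincide (e.g. the
# platelet-lymphocyte and neutrophil-monocyte ratios), which would leave a
# "planted" feature carrying no location signal at all; a floor of 0.5
# pooled SDs keeps every planted feature genuinely informative while
# features already separated beyond the floor keep their published
# medians unchanged. Gender stays at its published Bernoulli rates.
HD_MIN_EFFECT_SD = 0.5


def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    # median = exp(mu); IQR = 2 exp(mu) sinh(z75 * s)
    mu = np.log(median)
    s = np.arcsinh(iqr / (2.0 * median)) / norm.ppf(0.75)
    return mu, s


def _sample_marginal(kind: str, median: float, iqr: float, size: int, rng):
    if kind == "bernoulli":
        return (rng.random(size) < median).astype(float)
    if kind == "lognormal":
        mu, s = _lognormal_params(median, iqr)
        return rng.lognormal(mean=mu, sigma=s, size=size)
    return rng.normal(loc=median, scale=iqr / _IQR_Z, size=size)


def generate_hd_like(seed: int = 0) -> Dataset:
    """Hemodialysis-like cohort with eight planted informative features."""
    rng = np.random.default_rng(seed)
    n = HD_N_NON_IDH + HD_N_IDH
    y = np.concatenate([np.zeros(HD_N_NON_IDH, int), np.ones(HD_N_IDH, int)])
    names = [row[0] for row in HD_FEATURES]
    planted_idx = [i for i, row in enumerate(HD_FEATURES)
                   if row[0].split("_")[0] in HD_PLANTED_CODES]
    X = np.empty((n, len(HD_FEATURES)))
    for j, (code, kind, (m0, q0), (m1, q1)) in enumerate(HD_FEATURES):
        if j in planted_idx:
            if kind != "bernoulli":
                sd = 0.5 * (q0 + q1) / _IQR_Z
                diff = m1 - m0
                if abs(diff) < HD_MIN_EFFECT_SD * sd:
                    sign = np.sign(diff) if diff != 0 else \
                        (np.sign(q1 - q0) if q1 != q0 else 1.0)
                    m1 = m0 + sign * HD_MIN_EFFECT_SD * sd
            col = np.empty(n)
            col[y == 0] = _sample_marginal(kind, m0, q0, HD_N_NON_IDH, rng)
            col[y == 1] = _sample_marginal(kind, m1, q1, HD_N_IDH, rng)
        else:
            # pooled, class-independent marginal
            mp, qp = 0.5 * (m0 + m1), 0.5 * (q0 + q1)
            col = _sample_marginal(kind, mp, qp, n, rng)
        X[:, j] = col
    perm = rng.permutation(n)
    return Dataset(X=X[perm], y=y[perm], feature_names=names,
                   planted=frozenset(planted_idx), seed=seed)


def planted_recovery_score(selected, planted) -> float:
    """Jaccard index between a selected and a planted feature-index set."""
    s, p = set(selected), set(planted)
    union = s | p
    if not union:
        return 0.0
    return len(s & p) / len(union)
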