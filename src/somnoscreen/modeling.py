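"""Bilinear (pairwise-interaction) models over feature combinations.

For a combination of k features (3 <= k <= 5) the predicted PSG parameter is
a degree-2 polynomial with all pairwise interaction terms:

    y_hat = sum_{i<j} a_ij x_i x_j  +  sum_i b_i x_i  +  c

(for k = 3 this is the classic seven-coefficient form a1 XY + a2 XZ + a3 YZ
+ a4 X + a5 Y + a6 Z + a7; no triple products — higher orders overfit small
cohorts).  Candidate combinations are enumerated exhaustively over the
selected features (seeded subsampling beyond a cap), each fit by least
squares on standardized design columns, scored by the Spearman correlation
between predicted and actual values and by the percentage of subjects whose
predictions fall inside the overlap interval of the two severity groups'
prediction ranges, and the 20 best (highest |CC|, then lowest overlap) are
kept for classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

TOP_MODELS = 20
COMBINATION_CAP = 20_000
COMBINATION_SIZES = (3, 4, 5)

#: Fit precondition: complete cases per coefficient.
MIN_ROWS_PER_COEF = 5


def n_coefficients(k: int) -> int:
    """C(k,2) pairwise + k linear + intercept."""
    return comb(k, 2) + k + 1


class BilinearRegression(BaseEstimator, RegressorMixin):
    """Least-squares bilinear model with all pairwise interactions.

    Design columns are standardized to zero mean / unit variance before the
    interaction terms are formed, so coefficient magnitudes are comparable
    across features with different units.  ``raw_coefficients_`` maps the
    fit back to the unstandardized a_ij / b_i / c parametrization.

    Attributes (after ``fit``)
    --------------------------
    coef_pairs_ : (C(k,2),) standardized interaction coefficients
    coef_linear_ : (k,) standardized linear coefficients
    intercept_ : float
    rank_ : numerical rank of the design matrix
    """

    def __init__(self):
        pass

    def _design(self, Z: np.ndarray) -> np.ndarray:
        k = Z.shape[1]
        pairs = [Z[:, i] * Z[:, j] for i, j in combinations(range(k), 2)]
        return np.column_stack(pairs + [Z[:, i] for i in range(k)] + [np.ones(Z.shape[0])])

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, k = X.shape
        p = n_coefficients(k)
        if n < MIN_ROWS_PER_COEF * p:
            raise ValueError(f"need n >= {MIN_ROWS_PER_COEF * p} complete cases for {p} coefficients, got {n}")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        D = self._design((X - self.mean_) / self.scale_)
        coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        self.rank_ = int(rank)
        self.is_rank_deficient_ = rank < p
        npairs = comb(k, 2)
        self.coef_pairs_ = coef[:npairs]
        self.coef_linear_ = coef[npairs : npairs + k]
        self.intercept_ = float(coef[-1])
        self.n_features_in_ = k
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_pairs_")
        X = np.asarray(X, float)
        D = self._design((X - self.mean_) / self.scale_)
        return D @ np.concatenate([self.coef_pairs_, self.coef_linear_, [self.intercept_]])

    @property
    def raw_coefficients_(self) -> dict[str, np.ndarray | float]:
        """Coefficients on the original (unstandardized) feature scale."""
        check_is_fitted(self, "coef_pairs_")
        k = self.n_features_in_
        m, s = self.mean_, self.scale_
        pair_idx = list(combinations(range(k), 2))
        a = np.zeros((k, k))
        for (i, j), b_ij in zip(pair_idx, self.coef_pairs_):
            a[i, j] = b_ij / (s[i] * s[j])
        lin = self.coef_linear_ / s
        c = self.intercept_ - float(np.sum(self.coef_linear_ * m / s))
        for (i, j), b_ij in zip(pair_idx, self.coef_pairs_):
            lin[i] -= b_ij * m[j] / (s[i] * s[j])
            lin[j] -= b_ij * m[i] / (s[i] * s[j])
            c += b_ij * m[i] * m[j] / (s[i] * s[j])
        return {"pairs": np.array([a[i, j] for i, j in pair_idx]), "linear": lin, "intercept": c}


def spearman_cc(pred: np.ndarray, actual: np.ndarray) -> tuple[float, bool]:
    """Spearman rank correlation (average ranks for ties).

    Returns ``(cc, flagged)``; a constant input makes the correlation
    undefined, reported as 0.0 with the flag set.
    """
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if pred.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(pred) == 0 or np.ptp(actual) == 0:
        return 0.0, True
    rho = stats.spearmanr(pred, actual).statistic
    return float(rho), False


def overlap_pct(pred: np.ndarray, above: np.ndarray) -> float:
    """Percentage of all subjects whose prediction lies inside the closed
    overlap interval of the two groups' prediction ranges (0 if disjoint)."""
    pred = np.asarray(pred, float)
    above = np.asarray(above, bool)
    a, b = pred[above], pred[~above]
    if a.size == 0 or b.size == 0:
        raise ValueError("both severity groups must be nonempty")
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    if lo > hi:
        return 0.0
    return 100.0 * float(np.mean((pred >= lo) & (pred <= hi)))


@dataclass
class BilinearModel:
    """A fitted feature combination with its ranking scores."""

    psg_name: str
    labels: tuple[str, ...]
    estimator: BilinearRegression
    spearman: float
    spearman_flagged: bool
    overlap: float
    n_fit: int
    fit_ids: list[str] = field(default_factory=list)

    def predict_frame(self, features: pd.DataFrame) -> pd.Series:
        """Predict for every subject with complete inputs; NaN otherwise."""
        sub = features[list(self.labels)]
        complete = sub.notna().all(axis=1)
        out = pd.Series(np.nan, index=features.index)
        if complete.any():
            out[complete] = self.estimator.predict(sub[complete].to_numpy(float))
        return out


def fit_bilinear(
    features: pd.DataFrame,
    psg: pd.Series,
    labels: Sequence[str],
    threshold: float,
    psg_name: str = "",
) -> BilinearModel | None:
    """Fit one feature combination on complete cases.

    Returns ``None`` (with a logged reason) when there are too few complete
    cases or the design is rank-deficient — a dropped combination, not an
    error.
    """
    labels = tuple(labels)
    sub = features[list(labels)]
    complete = sub.notna().all(axis=1) & psg.notna()
    n = int(complete.sum())
    p = n_coefficients(len(labels))
    if n < MIN_ROWS_PER_COEF * p:
        logger.debug("%s: %d complete cases < %d; combination dropped", labels, n, MIN_ROWS_PER_COEF * p)
        return None
    X = sub[complete].to_numpy(float)
    y = psg[complete].to_numpy(float)
    est = BilinearRegression().fit(X, y)
    if est.is_rank_deficient_:
        logger.debug("%s: rank-deficient design; combination dropped", labels)
        return None
    pred = est.predict(X)
    rho, flagged = spearman_cc(pred, y)
    ov = overlap_pct(pred, y >= threshold)
    return BilinearModel(
        psg_name=psg_name,
        labels=labels,
        estimator=est,
        spearman=rho,
        spearman_flagged=flagged,
        overlap=ov,
        n_fit=n,
        fit_ids=list(sub.index[complete]),
    )


def enumerate_combinations(
    labels: Sequence[str],
    sizes: Sequence[int] = COMBINATION_SIZES,
    cap: int = COMBINATION_CAP,
    seed: int = 0,
) -> list[tuple[str, ...]]:
    """All size-3/4/5 combinations of the labels, seeded-subsampled to ``cap``."""
    labels = sorted(labels)
    combos: list[tuple[str, ...]] = []
    for k in sizes:
        combos.extend(combinations(labels, k))
    if len(combos) > cap:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(combos), size=cap, replace=False))
        combos = [combos[i] for i in idx]
        logger.info("combination space capped: %d kept of %d", cap, len(idx))
    return combos


def rank_models(models: Sequence[BilinearModel], top: int = TOP_MODELS) -> list[BilinearModel]:
    """Sort by (|Spearman CC| descending, overlap ascending, labels) and
    keep the first ``top``."""
    ordered = sorted(models, key=lambda m: (-abs(m.spearman), m.overlap, m.labels))
    return list(ordered[:top])


def fit_and_rank(
    features: pd.DataFrame,
    psg: pd.Series,
    threshold: float,
    psg_name: str = "",
    sizes: Sequence[int] = COMBINATION_SIZES,
    cap: int = COMBINATION_CAP,
    seed: int = 0,
    top: int = TOP_MODELS,
) -> list[BilinearModel]:
    """Enumerate, fit, and rank bilinear models over selected features."""
    combos = enumerate_combinations(list(features.columns), sizes=sizes, cap=cap, seed=seed)
    models = []
    for labels in combos:
        m = fit_bilinear(features, psg, labels, threshold, psg_name=psg_name)
        if m is not None and not m.spearman_flagged:
            models.append(m)
    return rank_models(models, top=top)
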