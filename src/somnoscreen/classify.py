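"""Random-forest screening classification of bilinear-model outputs.

Each ranked bilinear model yields a single scalar per subject (its
predicted PSG value); classification is therefore one-dimensional.  A
*repeated-holdout* random forest handles it: many seeded iterations each
draw a stratified 65/35 train/validation split of the training data, fit a
small forest, and score the held-out 35%.  The frozen classifier is the
majority-vote ensemble of all iteration forests, which is then applied once
to the blind-test fold.

Models must clear accuracy >= 70% and sensitivity/specificity >= 50% on
both validation and blind test to stay admissible; the outcomes of three
admissible models are then combined per subject by majority voting (the
positive, "abnormal" class is above-threshold; voting ties are resolved
toward abnormal, the screening-conservative direction).  Results are
averaged over the five data configurations.

Every metric quadruple (accuracy, sensitivity, specificity, F1) is derived
from a stored confusion matrix, never free-floating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from somnoscreen.modeling import BilinearModel

logger = logging.getLogger(__name__)

N_ITERATIONS = 1200
TRAIN_FRAC = 0.65
ACC_CUTOFF = 0.70
SENS_SPEC_CUTOFF = 0.50


@dataclass(frozen=True)
class Metrics:
    """Confusion counts with the derived screening metrics.

    Positive class = above threshold ("abnormal").  Undefined ratios (empty
    denominator) are NaN.
    """

    tn: int
    fp: int
    fn: int
    tp: int

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> "Metrics":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return Metrics(
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        )

    def __add__(self, other: "Metrics") -> "Metrics":
        return Metrics(self.tn + other.tn, self.fp + other.fp, self.fn + other.fn, self.tp + other.tp)

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def f1(self) -> float:
        p, s = self.precision, self.sensitivity
        if not np.isfinite(p) or not np.isfinite(s) or (p + s) == 0:
            return float("nan")
        return 2 * p * s / (p + s)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }


class RepeatedHoldoutForest(BaseEstimator, ClassifierMixin):
    """Repeated stratified-holdout random-forest ensemble for 1-D inputs.

    ``fit`` runs ``n_iter`` seeded iterations of a stratified 65/35
    train/validation split, fits a small forest per iteration (the input is
    one-dimensional, so 25 shallow trees suffice), and pools the held-out
    confusions into ``validation_metrics_``.  ``predict`` majority-votes
    the frozen iteration forests (ties -> positive class).

    Attributes (after ``fit``)
    --------------------------
    forests_ : list of fitted RandomForestClassifier
    validation_metrics_ : Metrics pooled over all held-out draws
    n_redraws_ : splits redrawn because a class was absent from the 65%
    """

    def __init__(
        self,
        n_iter: int = N_ITERATIONS,
        train_frac: float = TRAIN_FRAC,
        n_estimators: int = 25,
        max_depth: int = 4,
        random_state: int | None = None,
    ):
        self.n_iter = n_iter
        self.train_frac = train_frac
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def _split(self, y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Stratified train/validation indices (both classes kept in train)."""
        train_idx, val_idx = [], []
        for cls in (0, 1):
            idx = rng.permutation(np.nonzero(y == cls)[0])
            n_train = max(1, int(round(self.train_frac * idx.size)))
            n_train = min(n_train, idx.size - 1) if idx.size > 1 else n_train
            train_idx.append(idx[:n_train])
            val_idx.append(idx[n_train:])
        return np.concatenate(train_idx), np.concatenate(val_idx)

    def fit(self, X, y):
        X = np.asarray(X, float).reshape(len(y), -1)
        y = np.asarray(y, int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present in the training data")
        rng = np.random.default_rng(self.random_state)
        self.forests_ = []
        self.n_redraws_ = 0
        pooled = Metrics(0, 0, 0, 0)
        for it in range(self.n_iter):
            tr, va = self._split(y, rng)
            while len(np.unique(y[tr])) < 2:  # pragma: no cover - guarded by _split
                self.n_redraws_ += 1
                tr, va = self._split(y, rng)
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            ).fit(X[tr], y[tr])
            self.forests_.append(forest)
            if va.size:
                pooled = pooled + Metrics.from_predictions(y[va], forest.predict(X[va]))
        self.validation_metrics_ = pooled
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self, "forests_")
        X = np.asarray(X, float).reshape(-1, 1) if np.asarray(X).ndim == 1 else np.asarray(X, float)
        votes = np.zeros(X.shape[0])
        for forest in self.forests_:
            votes += forest.predict(X)
        # tie -> abnormal (positive) class
        return (votes >= len(self.forests_) / 2).astype(int)


@dataclass
class ClassifierEval:
    """A bilinear model with its frozen classifier and both metric sets."""

    model: BilinearModel
    classifier: RepeatedHoldoutForest
    validation: Metrics
    test: Metrics
    n_iterations: int


def evaluate_model(
    values: np.ndarray, labels: np.ndarray, n_iter: int = N_ITERATIONS, seed: int | None = None, **forest_kwargs
) -> RepeatedHoldoutForest:
    """Run the repeated-holdout evaluation on one model's scalar outputs.

    Returns the fitted classifier; its ``validation_metrics_`` hold the
    pooled held-out confusion.
    """
    clf = RepeatedHoldoutForest(n_iter=n_iter, random_state=seed, **forest_kwargs)
    return clf.fit(np.asarray(values, float).reshape(-1, 1), labels)


def blind_test(classifier: RepeatedHoldoutForest, values: np.ndarray, labels: np.ndarray) -> Metrics:
    """Score the frozen classifier on the blind-test fold."""
    pred = classifier.predict(np.asarray(values, float).reshape(-1, 1))
    return Metrics.from_predictions(np.asarray(labels, int), pred)


def filter_models(
    evals: Sequence[ClassifierEval],
    acc_cutoff: float = ACC_CUTOFF,
    sens_spec_cutoff: float = SENS_SPEC_CUTOFF,
) -> list[ClassifierEval]:
    """Keep models with validation AND test accuracy >= 70% and validation
    AND test sensitivity/specificity >= 50% (inclusive bounds)."""
    out = []
    for e in evals:
        v, t = e.validation, e.test
        checks = (
            v.accuracy >= acc_cutoff,
            t.accuracy >= acc_cutoff,
            v.sensitivity >= sens_spec_cutoff,
            v.specificity >= sens_spec_cutoff,
            t.sensitivity >= sens_spec_cutoff,
            t.specificity >= sens_spec_cutoff,
        )
        if all(checks):  # NaN metrics compare False and exclude the model
            out.append(e)
    return out


def _majority(votes: pd.DataFrame) -> pd.Series:
    """Per-subject majority over cast (non-missing) votes; ties -> abnormal.

    Subjects with zero cast votes get NaN (excluded from metrics)."""
    cast = votes.notna().sum(axis=1)
    pos = (votes == 1).sum(axis=1)
    out = pd.Series(np.nan, index=votes.index)
    has = cast > 0
    out[has] = (pos[has] >= cast[has] / 2).astype(float)
    return out


@dataclass
class VotingResult:
    """Best 3-model majority-voting combination for one data configuration."""

    combo_labels: tuple[tuple[str, ...], ...]
    validation: Metrics
    test: Metrics
    coverage: float
    fallback_single: bool = False


def vote3(
    admissible: Sequence[ClassifierEval],
    features: pd.DataFrame,
    y_true: pd.Series,
    test_ids: Sequence[str],
) -> VotingResult:
    """Choose the best 3-model majority-voting combination.

    Each model votes for every subject whose feature inputs are complete;
    a subject's class is the majority of cast votes (ties -> abnormal).
    Combinations are scored lexicographically by (cohort coverage, test
    accuracy).  With fewer than 3 admissible models the best single model
    is used (logged fallback).
    """
    if not admissible:
        raise ValueError("no admissible models to vote with")
    votes = pd.DataFrame(index=features.index)
    for i, e in enumerate(admissible):
        scores = e.model.predict_frame(features)
        ok = scores.notna()
        col = pd.Series(np.nan, index=features.index)
        if ok.any():
            col[ok] = e.classifier.predict(scores[ok].to_numpy(float).reshape(-1, 1)).astype(float)
        votes[i] = col

    test_ids = [s for s in test_ids if s in features.index]
    is_test = features.index.isin(set(test_ids))

    if len(admissible) < 3:
        logger.info("vote3 fallback: only %d admissible models", len(admissible))
        combos = np.array([[0]])
        fallback = True
    else:
        combos = np.array(list(combinations(range(len(admissible)), 3)))
        fallback = False

    V = votes.to_numpy(float)  # (n_subjects, n_models), NaN = abstain
    y = y_true.loc[features.index].to_numpy(int)
    sub = V[:, combos]  # (n_subjects, n_combos, k)
    cast = np.isfinite(sub).sum(axis=2)
    pos = np.nansum(sub == 1.0, axis=2)
    pred = np.where(cast > 0, (pos >= cast / 2.0).astype(float), np.nan)
    covered = cast > 0
    coverage_all = covered.mean(axis=0)
    # blind-test accuracy per combination (NaN-safe)
    t_cov = covered[is_test]
    t_correct = (pred[is_test] == y[is_test, None]) & t_cov
    with np.errstate(invalid="ignore"):
        t_acc = np.where(t_cov.sum(axis=0) > 0, t_correct.sum(axis=0) / t_cov.sum(axis=0), -1.0)
    order = np.lexsort((-t_acc, -coverage_all))
    best_idx = int(order[0])
    combo = tuple(int(i) for i in combos[best_idx])
    coverage = float(coverage_all[best_idx])

    def _metrics_for(mask: np.ndarray) -> Metrics:
        sel = mask & covered[:, best_idx]
        return Metrics.from_predictions(y[sel], pred[sel, best_idx].astype(int))

    val_m = _metrics_for(~is_test)
    test_m = _metrics_for(is_test)
    return VotingResult(
        combo_labels=tuple(admissible[i].model.labels for i in combo),
        validation=val_m,
        test=test_m,
        coverage=coverage,
        fallback_single=fallback,
    )


@dataclass
class EvaluationReport:
    """Averaged 5-configuration report for one PSG parameter."""

    psg_name: str
    threshold: float
    scaling: str
    fragments: list[VotingResult]
    validation_mean: dict[str, float] = field(default_factory=dict)
    test_mean: dict[str, float] = field(default_factory=dict)
    test_min: dict[str, float] = field(default_factory=dict)
    test_max: dict[str, float] = field(default_factory=dict)
    coverage: float = float("nan")


def aggregate_configurations(
    psg_name: str, threshold: float, scaling: str, fragments: Sequence[VotingResult]
) -> EvaluationReport:
    """Arithmetic mean (plus min/max) of the five configurations' metrics."""
    if len(fragments) != 5:
        raise ValueError(f"need exactly 5 configuration fragments, got {len(fragments)}")
    report = EvaluationReport(
        psg_name=psg_name, threshold=threshold, scaling=scaling, fragments=list(fragments)
    )
    val = pd.DataFrame([f.validation.as_dict() for f in fragments])
    tst = pd.DataFrame([f.test.as_dict() for f in fragments])
    report.validation_mean = val.mean().to_dict()
    report.test_mean = tst.mean().to_dict()
    report.test_min = tst.min().to_dict()
    report.test_max = tst.max().to_dict()
    report.coverage = float(np.mean([f.coverage for f in fragments]))
    return report
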