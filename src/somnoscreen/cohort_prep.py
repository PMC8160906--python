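"""Per-PSG-parameter threshold determination, data configurations, and
feature selection.

Each PSG parameter is turned into a two-class problem by a data-driven
threshold: the parameter's values are first variance-stabilized (squared or
logged until |skewness| < 0.5), the observed range is cut into 20 equal
divisions giving 19 interior candidate thresholds, and each candidate is
scored by the *spectral gap* — the average distance between the
non-overlapping 95% confidence bands of the two groups' mean dB spectra,
averaged over the four breathing maneuvers.  The winning candidate must
leave at least 20 subjects on each side; a physiologically meaningful
override can replace the purely data-driven pick.

The cohort is then split into five *data configurations*: stratified
blind-test folds of 20% above + 20% below the threshold, with the remaining
80% used for training/validation — and for everything upstream of testing
(threshold scanning, feature selection, model fitting), so no test subject
ever influences those stages.

Feature selection runs three stages on training/validation data only:
correlation de-duplication (|Pearson CC| >= 0.95 keeps the member better
correlated with the PSG parameter), per-group Tukey-fence outlier removal,
and a Welch two-sample t-test gate at p <= 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from somnoscreen.spectral import ANALYSIS_BAND, PowerSpectrum, to_db

logger = logging.getLogger(__name__)

N_DIVISIONS = 20
MIN_GROUP = 20
SKEW_LIMIT = 0.5
DEDUP_CC = 0.95
P_CUTOFF = 0.05


# ---------------------------------------------------------------------------
# scaling and threshold candidates


def scale_for_skewness(values: np.ndarray) -> tuple[np.ndarray, str]:
    """Variance-stabilize PSG values until |skewness| < 0.5.

    Left-skewed samples (skewness <= -0.5) are squared; right-skewed samples
    (skewness >= 0.5) are log-transformed (shifted by +1 first if zeros are
    present).  Returns ``(scaled values, tag)`` with tag in
    {'none', 'square', 'log'}.
    """
    values = np.asarray(values, float)
    if values.size < 10:
        raise ValueError(f"need >= 10 values, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("constant PSG values: cannot scale or threshold")
    sk = float(stats.skew(values))
    if sk <= -SKEW_LIMIT:
        return values**2, "square"
    if sk >= SKEW_LIMIT:
        if values.min() < 0:
            raise ValueError("log scaling requires nonnegative values")
        if values.min() == 0:
            logger.info("zeros present; log-scaling with +1 shift")
            return np.log(values + 1.0), "log"
        return np.log(values), "log"
    return values, "none"


def candidate_thresholds(scaled: np.ndarray) -> np.ndarray:
    """The 19 interior cut points of 20 equal divisions of the range."""
    scaled = np.asarray(scaled, float)
    if np.unique(scaled).size < 2:
        raise ValueError("need at least 2 distinct values")
    lo, hi = float(scaled.min()), float(scaled.max())
    step = (hi - lo) / N_DIVISIONS
    return lo + step * np.arange(1, N_DIVISIONS)


# ---------------------------------------------------------------------------
# spectral gap


def _group_ci(db_spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = db_spectra.mean(axis=0)
    se = db_spectra.std(axis=0, ddof=1) / np.sqrt(db_spectra.shape[0])
    return mean, mean - 1.96 * se, mean + 1.96 * se


def spectral_gap(
    spectra: Mapping[str, Mapping[str, PowerSpectrum]],
    below_ids: Sequence[str],
    above_ids: Sequence[str],
    band: tuple[float, float] = ANALYSIS_BAND,
) -> float:
    """Average 95%-CI gap between two groups' mean dB spectra.

    ``spectra`` maps subject id -> maneuver -> per-subject spectrum.  Per
    maneuver, group mean dB spectra with pointwise 95% confidence bands
    (mean +/- 1.96 SE) are compared bin by bin; over the bins where the
    bands do not overlap, the mean distance between the nearer boundaries
    is the maneuver's gap (0 if the bands overlap everywhere).  The result
    averages over the maneuvers that have data for both groups.
    """
    maneuvers = sorted({m for per_subj in spectra.values() for m in per_subj})
    gaps = []
    for man in maneuvers:
        grp = []
        for ids in (below_ids, above_ids):
            rows = [spectra[s][man] for s in ids if man in spectra.get(s, {})]
            if len(rows) < 2:
                break
            idx = rows[0].band_indices(*band)
            grp.append(np.array([to_db(r.power)[idx] for r in rows]))
        if len(grp) < 2:
            continue
        _, lo_b, hi_b = _group_ci(grp[0])
        _, lo_a, hi_a = _group_ci(grp[1])
        # disjoint bands: one group's lower CI above the other's upper CI
        gap_bins = np.where(lo_a > hi_b, lo_a - hi_b, np.where(lo_b > hi_a, lo_b - hi_a, 0.0))
        nonzero = gap_bins > 0
        gaps.append(float(gap_bins[nonzero].mean()) if nonzero.any() else 0.0)
    if not gaps:
        raise ValueError("no maneuver had >= 2 subjects in both groups")
    return float(np.mean(gaps))


@dataclass
class ThresholdScan:
    """Gap scores and group sizes for all candidate thresholds of one
    PSG parameter (on its scaled values)."""

    psg_name: str
    scaling: str
    candidates: np.ndarray
    gap: np.ndarray
    group_sizes: list[tuple[int, int]]
    selected: float = float("nan")
    selection_reason: str = ""

    def eligible(self, min_group: int = MIN_GROUP) -> np.ndarray:
        return np.array([min(nb, na) >= min_group for nb, na in self.group_sizes])


def threshold_scan(
    psg_name: str,
    scaled_values: Mapping[str, float],
    scaling: str,
    spectra: Mapping[str, Mapping[str, PowerSpectrum]],
) -> ThresholdScan:
    """Score every candidate threshold of a PSG parameter by spectral gap."""
    ids = [s for s, v in scaled_values.items() if np.isfinite(v)]
    vals = np.array([scaled_values[s] for s in ids])
    cands = candidate_thresholds(vals)
    gaps = np.empty(cands.size)
    sizes: list[tuple[int, int]] = []
    for k, thr in enumerate(cands):
        below = [s for s, v in zip(ids, vals) if v < thr]
        above = [s for s, v in zip(ids, vals) if v >= thr]
        sizes.append((len(below), len(above)))
        try:
            gaps[k] = spectral_gap(spectra, below, above)
        except ValueError:
            gaps[k] = 0.0
    return ThresholdScan(psg_name=psg_name, scaling=scaling, candidates=cands, gap=gaps, group_sizes=sizes)


def select_threshold(
    scan: ThresholdScan, override: float | None = None, min_group: int = MIN_GROUP
) -> float:
    """Pick the threshold: max gap among balanced candidates, or the
    candidate nearest a physiological override.

    Candidates leaving fewer than ``min_group`` subjects on either side are
    ineligible.  Gap ties break toward the smaller threshold.
    """
    ok = scan.eligible(min_group)
    if not ok.any():
        raise ValueError(
            f"{scan.psg_name}: no candidate threshold leaves >= {min_group} subjects per group "
            "(cohort too small or imbalanced)"
        )
    cands = scan.candidates[ok]
    if override is not None:
        pick = cands[np.argmin(np.abs(cands - override))]
        scan.selected, scan.selection_reason = float(pick), "override_physiological"
        return scan.selected
    gaps = scan.gap[ok]
    best = gaps.max()
    pick = cands[np.nonzero(gaps == best)[0][0]]  # tie -> smaller threshold
    scan.selected, scan.selection_reason = float(pick), "max_gap"
    return scan.selected


# ---------------------------------------------------------------------------
# data configurations


@dataclass
class DataConfiguration:
    """One of the five stratified blind-test partitions."""

    fold_id: int
    test_ids: list[str]
    trainval_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.test_ids) & set(self.trainval_ids)
        if overlap:
            raise ValueError(f"fold {self.fold_id}: test/trainval overlap {sorted(overlap)}")


def make_configurations(
    below_ids: Sequence[str], above_ids: Sequence[str], seed: int, n_folds: int = 5
) -> list[DataConfiguration]:
    """Split each stratum into ``n_folds`` disjoint ~20% folds; fold k's test
    set is the union of the two strata's k-th folds."""
    rng = np.random.default_rng(seed)
    for name, ids in (("below", below_ids), ("above", above_ids)):
        if len(ids) < n_folds:
            raise ValueError(f"{name}-threshold stratum has {len(ids)} < {n_folds} subjects")
    folds_b = np.array_split(rng.permutation(np.asarray(below_ids, dtype=object)), n_folds)
    folds_a = np.array_split(rng.permutation(np.asarray(above_ids, dtype=object)), n_folds)
    cohort = set(below_ids) | set(above_ids)
    configs = []
    for k in range(n_folds):
        test = sorted(list(folds_b[k]) + list(folds_a[k]))
        configs.append(
            DataConfiguration(fold_id=k + 1, test_ids=test, trainval_ids=sorted(cohort - set(test)))
        )
    return configs


# ---------------------------------------------------------------------------
# feature selection


@dataclass
class SelectionReport:
    """Outcome of the three-stage feature selection."""

    selected: list[str]
    dropped_duplicate: dict[str, str] = field(default_factory=dict)  # dropped -> kept
    dropped_insignificant: dict[str, float] = field(default_factory=dict)  # label -> p
    dropped_too_few: list[str] = field(default_factory=list)
    n_outliers_removed: int = 0
    p_values: dict[str, float] = field(default_factory=dict)


def _tukey_mask(values: np.ndarray) -> np.ndarray:
    """True where a value is inside the Tukey 1.5 IQR fences."""
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        return np.isfinite(values)
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    return np.isfinite(values) & (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)


def select_features(
    features: pd.DataFrame,
    psg_scaled: pd.Series,
    threshold: float,
    p_cutoff: float = P_CUTOFF,
    dedup_cc: float = DEDUP_CC,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Three-stage per-PSG-parameter feature selection on training data.

    1. de-duplication: for each feature pair with |Pearson CC| >= 0.95, drop
       the member with the lower |CC| to the (scaled) PSG values;
    2. per severity group (below/above threshold), remove per-feature
       outliers outside the Tukey 1.5 IQR fences (those entries become
       missing for that feature only);
    3. keep features whose two groups differ with Welch t-test p <= 0.05.

    Returns the outlier-cleaned values of the selected features and a
    report.  Features with fewer than 3 non-missing values in either group
    are dropped with a logged reason.
    """
    features = features.loc[psg_scaled.index]
    report = SelectionReport(selected=[])

    # constant or all-missing columns carry no group information
    variable = features.columns[features.std(ddof=0).fillna(0.0) > 0]
    for label in features.columns.difference(variable):
        report.dropped_too_few.append(label)
        logger.info("feature %s dropped: constant or empty column", label)
    features = features[variable]

    # stage 1: correlation de-duplication
    corr = features.corr(method="pearson")
    target_cc = features.corrwith(psg_scaled).abs()
    labels = list(features.columns)
    dropped: set[str] = set()
    for i, a in enumerate(labels):
        if a in dropped:
            continue
        for b in labels[i + 1 :]:
            if b in dropped:
                continue
            cc = corr.loc[a, b]
            if np.isfinite(cc) and abs(cc) >= dedup_cc:
                loser, keeper = (a, b) if target_cc.get(a, 0) < target_cc.get(b, 0) else (b, a)
                dropped.add(loser)
                report.dropped_duplicate[loser] = keeper
                if loser == a:
                    break
    kept = [l for l in labels if l not in dropped]

    group_above = psg_scaled >= threshold
    cleaned = features[kept].copy()

    # stage 2: per-group Tukey-fence outlier removal
    for label in kept:
        col = cleaned[label].to_numpy(float)
        mask = np.zeros_like(col, dtype=bool)
        for sel in (group_above.to_numpy(), ~group_above.to_numpy()):
            sub_mask = np.zeros_like(col, dtype=bool)
            sub_mask[sel] = _tukey_mask(col[sel])
            mask |= sub_mask
        report.n_outliers_removed += int((np.isfinite(col) & ~mask).sum())
        cleaned.loc[~mask, label] = np.nan

    # stage 3: Welch t-test gate
    selected = []
    for label in kept:
        above = cleaned.loc[group_above, label].dropna()
        below = cleaned.loc[~group_above, label].dropna()
        if len(above) < 3 or len(below) < 3:
            report.dropped_too_few.append(label)
            logger.info("feature %s dropped: <3 non-missing per group", label)
            continue
        with warnings.catch_warnings():
            # near-constant discrete features trip scipy's precision warning;
            # their NaN/1.0 p-values are simply not selected
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(above, below, equal_var=False).pvalue)
        report.p_values[label] = p
        if p <= p_cutoff:
            selected.append(label)
        else:
            report.dropped_insignificant[label] = p
    report.selected = selected
    return cleaned[selected], report
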