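"""End-to-end orchestration: cohort -> per-PSG-parameter screening reports.

Per PSG parameter the pipeline runs, for each of five data configurations
built from its (variance-stabilized) values:

1. threshold scan on the configuration's training/validation 80% only;
2. three-stage feature selection on the same 80%;
3. exhaustive bilinear-model search, ranked, top 20 kept;
4. repeated-holdout random-forest evaluation per model, admissibility
   filtering, and 3-model majority voting;

and finally averages the five configurations.  A failure in one PSG
parameter is isolated: that parameter is reported as failed and the run
continues.

Because the severity threshold itself is learned per configuration, the
five blind-test folds are stratified on a provisional median split of the
scaled values; the learned thresholds then apply within each configuration.
The reported threshold is the modal selection across configurations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import somnoscreen
from somnoscreen import classify, cohort_prep, modeling
from somnoscreen.classify import ClassifierEval, EvaluationReport
from somnoscreen.cohort_prep import ThresholdScan
from somnoscreen.feature_catalog import REGISTRY, compute_feature_table
from somnoscreen.io_preprocess import group_by_subject, read_recording, read_tables
from somnoscreen.spectral import mean_spectrum
from somnoscreen.synthetic_data import Cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline settings; defaults are the method's standard constants."""

    seed: int = 0
    psg_params: tuple[str, ...] | None = None  # None -> every PSG column
    psg_overrides: dict[str, float] = field(default_factory=dict)  # physiological thresholds
    # estimator settings
    welch_kwargs: dict = field(default_factory=dict)
    bispec_kwargs: dict = field(default_factory=dict)
    # selection settings
    dedup_cc: float = cohort_prep.DEDUP_CC
    p_cutoff: float = cohort_prep.P_CUTOFF
    min_group: int = cohort_prep.MIN_GROUP
    # modeling settings
    combination_sizes: tuple[int, ...] = modeling.COMBINATION_SIZES
    top_models: int = modeling.TOP_MODELS
    combination_cap: int = modeling.COMBINATION_CAP
    # classification settings
    n_iterations: int = classify.N_ITERATIONS
    train_frac: float = classify.TRAIN_FRAC
    acc_cutoff: float = classify.ACC_CUTOFF
    sens_spec_cutoff: float = classify.SENS_SPEC_CUTOFF
    n_estimators: int = 25
    max_depth: int = 4
    n_folds: int = 5
    output_dir: str | None = None


@dataclass
class PipelineResult:
    """Reports and intermediates of one full run."""

    reports: dict[str, EvaluationReport]
    failures: dict[str, str]
    scans: dict[str, list[ThresholdScan]]
    features: pd.DataFrame
    manifest: dict


def load_cohort_dir(path: str | Path) -> tuple[dict, dict, dict]:
    """Load a directory of ``<id>.wav`` + ``<id>_annotations.csv`` pairs plus
    ``anthropometrics.csv`` and ``psg.csv`` into pipeline inputs."""
    path = Path(path)
    anthro, psg = read_tables(path / "anthropometrics.csv", path / "psg.csv")
    signals = {}
    for wav in sorted(path.glob("*.wav")):
        sid = wav.stem
        sigs = read_recording(wav, path / f"{sid}_annotations.csv")
        signals[sid] = group_by_subject(sigs).get(sid, {})
    return signals, anthro, psg


def _subject_spectra(signals: Mapping[str, Mapping[str, Sequence]], welch_kwargs: dict) -> dict:
    out: dict[str, dict] = {}
    for sid, by_man in signals.items():
        out[sid] = {man: mean_spectrum(sigs, **welch_kwargs) for man, sigs in by_man.items() if sigs}
    return out


def _seed_for(base: int, *path: int) -> int:
    return int(np.random.SeedSequence([base, *path]).generate_state(1)[0] % (2**31 - 1))


def _run_one_configuration(
    cfg: RunConfig,
    config: cohort_prep.DataConfiguration,
    psg_name: str,
    scaled: pd.Series,
    scaling: str,
    spectra: Mapping,
    features: pd.DataFrame,
    param_idx: int,
) -> tuple[ThresholdScan, "classify.VotingResult"]:
    trainval = [s for s in config.trainval_ids if np.isfinite(scaled.get(s, np.nan))]
    scan = cohort_prep.threshold_scan(
        psg_name, {s: float(scaled[s]) for s in trainval}, scaling, spectra
    )
    threshold = cohort_prep.select_threshold(
        scan, override=cfg.psg_overrides.get(psg_name), min_group=cfg.min_group
    )

    feats_tv = features.loc[trainval]
    selected, sel_report = cohort_prep.select_features(
        feats_tv, scaled.loc[trainval], threshold, p_cutoff=cfg.p_cutoff, dedup_cc=cfg.dedup_cc
    )
    if len(sel_report.selected) < min(cfg.combination_sizes):
        raise ValueError(
            f"{psg_name} fold {config.fold_id}: only {len(sel_report.selected)} features selected; "
            f"cannot form {min(cfg.combination_sizes)}-feature models"
        )

    models = modeling.fit_and_rank(
        selected,
        scaled.loc[trainval],
        threshold,
        psg_name=psg_name,
        sizes=cfg.combination_sizes,
        cap=cfg.combination_cap,
        seed=_seed_for(cfg.seed, param_idx, config.fold_id, 1),
        top=cfg.top_models,
    )
    if not models:
        raise ValueError(f"{psg_name} fold {config.fold_id}: no fittable model combination")

    y_all = (scaled >= threshold).astype(int)
    test_ids = [s for s in config.test_ids if np.isfinite(scaled.get(s, np.nan))]
    evals: list[ClassifierEval] = []
    for m_idx, model in enumerate(models):
        out_tv = model.predict_frame(features.loc[trainval]).dropna()
        if out_tv.empty or len(np.unique(y_all.loc[out_tv.index])) < 2:
            continue
        clf = classify.evaluate_model(
            out_tv.to_numpy(float),
            y_all.loc[out_tv.index].to_numpy(int),
            n_iter=cfg.n_iterations,
            seed=_seed_for(cfg.seed, param_idx, config.fold_id, 2, m_idx),
            train_frac=cfg.train_frac,
            n_estimators=cfg.n_estimators,
            max_depth=cfg.max_depth,
        )
        out_test = model.predict_frame(features.loc[test_ids]).dropna()
        if out_test.empty:
            continue
        test_m = classify.blind_test(clf, out_test.to_numpy(float), y_all.loc[out_test.index].to_numpy(int))
        evals.append(
            ClassifierEval(
                model=model,
                classifier=clf,
                validation=clf.validation_metrics_,
                test=test_m,
                n_iterations=cfg.n_iterations,
            )
        )

    admissible = classify.filter_models(evals, cfg.acc_cutoff, cfg.sens_spec_cutoff)
    if not admissible:
        # fall back to every evaluated model so a vote is still cast
        logger.warning("%s fold %d: no model met the admissibility filters", psg_name, config.fold_id)
        admissible = evals
    cohort_ids = trainval + test_ids
    fragment = classify.vote3(admissible, features.loc[cohort_ids], y_all.loc[cohort_ids], test_ids)
    return scan, fragment


def run_pipeline(
    cohort: Cohort | tuple,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full screening pipeline on a cohort.

    ``cohort`` is either a :class:`~somnoscreen.synthetic_data.Cohort` or a
    ``(signals, anthro, psg)`` triple as returned by :func:`load_cohort_dir`.
    """
    cfg = config or RunConfig()
    if isinstance(cohort, Cohort):
        signals, anthro, psg = cohort.signals, cohort.anthro, cohort.psg
    else:
        signals, anthro, psg = cohort

    logger.info("computing features for %d subjects", len(signals))
    features = compute_feature_table(
        signals, anthro, REGISTRY, welch_kwargs=cfg.welch_kwargs, bispec_kwargs=cfg.bispec_kwargs
    )
    spectra = _subject_spectra(signals, cfg.welch_kwargs)

    param_names = list(cfg.psg_params) if cfg.psg_params else sorted(
        {name for r in psg.values() for name in r.values}
    )

    reports: dict[str, EvaluationReport] = {}
    failures: dict[str, str] = {}
    scans: dict[str, list[ThresholdScan]] = {}
    for p_idx, name in enumerate(param_names):
        try:
            raw = pd.Series(
                {sid: r.values.get(name, np.nan) for sid, r in psg.items() if sid in features.index}
            ).dropna()
            scaled_vals, scaling = cohort_prep.scale_for_skewness(raw.to_numpy(float))
            scaled = pd.Series(scaled_vals, index=raw.index)

            median = float(np.median(scaled))
            below = sorted(scaled.index[scaled < median])
            above = sorted(scaled.index[scaled >= median])
            configurations = cohort_prep.make_configurations(
                below, above, seed=_seed_for(cfg.seed, p_idx, 0), n_folds=cfg.n_folds
            )

            param_scans, fragments, thresholds = [], [], []
            for dc in configurations:
                scan, fragment = _run_one_configuration(
                    cfg, dc, name, scaled, scaling, spectra, features, p_idx
                )
                param_scans.append(scan)
                fragments.append(fragment)
                thresholds.append(scan.selected)
            modal_threshold = Counter(np.round(thresholds, 9)).most_common(1)[0][0]
            reports[name] = classify.aggregate_configurations(name, float(modal_threshold), scaling, fragments)
            scans[name] = param_scans
        except (ValueError, KeyError) as exc:
            logger.warning("PSG parameter %r failed: %s", name, exc)
            failures[name] = str(exc)

    manifest = {
        "package": "somnoscreen",
        "version": somnoscreen.__version__,
        "seed": cfg.seed,
        "settings": {
            k: v for k, v in dataclasses.asdict(cfg).items() if not isinstance(v, (pd.DataFrame,))
        },
        "n_subjects": len(signals),
        "psg_parameters": param_names,
        "failures": failures,
    }
    result = PipelineResult(
        reports=reports, failures=failures, scans=scans, features=features, manifest=manifest
    )
    if cfg.output_dir:
        persist_result(result, cfg.output_dir)
    return result


def report_table(reports: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """Summary table: one row per PSG parameter with averaged metrics
    (percentages for accuracy/sensitivity/specificity)."""
    rows = []
    for name, r in reports.items():
        rows.append(
            {
                "psg_name": name,
                "threshold": r.threshold,
                "scaling": r.scaling,
                "VF1": r.validation_mean["f1"],
                "VCA%": 100 * r.validation_mean["accuracy"],
                "VSpec%": 100 * r.validation_mean["specificity"],
                "VSens%": 100 * r.validation_mean["sensitivity"],
                "TF1": r.test_mean["f1"],
                "TCA%": 100 * r.test_mean["accuracy"],
                "TSpec%": 100 * r.test_mean["specificity"],
                "TSens%": 100 * r.test_mean["sensitivity"],
                "coverage": r.coverage,
            }
        )
    return pd.DataFrame(rows)


def persist_result(result: PipelineResult, outdir: str | Path) -> None:
    """Write reports, threshold scans, features and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_table(result.reports).to_csv(outdir / "reports.csv", index=False)
    result.features.to_csv(outdir / "features.csv")
    scan_rows = []
    for name, param_scans in result.scans.items():
        for fold, scan in enumerate(param_scans, start=1):
            for cand, gap, (nb, na) in zip(scan.candidates, scan.gap, scan.group_sizes):
                scan_rows.append(
                    {"psg_name": name, "fold": fold, "candidate": cand, "gap_db": gap,
                     "n_below": nb, "n_above": na, "selected": scan.selected,
                     "reason": scan.selection_reason}
                )
    pd.DataFrame(scan_rows).to_csv(outdir / "threshold_scans.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
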