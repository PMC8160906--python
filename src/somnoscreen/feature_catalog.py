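"""Declarative registry of the 79 anthropometric and sound features.

Features F1-F6 are anthropometric (BMI, age, sex, weight, neck
circumference, Mallampati score); F7-F79 are computed from the Welch power
spectrum P(f) or the bispectrum magnitude |B(f1,f2)| of one of the four
breathing maneuvers, plus one time-domain operator (the Higuchi fractal
dimension).

Every entry maps a feature label to ``(source maneuver, operator,
parameters)``.  Band limits are stored ordered (low, high) regardless of
the order in which a definition happens to print them.  Composite
definitions (difference or ratio of two band means) are encoded as
operator-composition entries so the registry stays declarative.

Feature computation is a pure function of (signals, anthropometrics,
registry, estimator settings); any per-feature failure (missing maneuver,
operator error) is recorded as missing with a reason — never silently 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from somnoscreen import bispectral, spectral
from somnoscreen.bispectral import BispectralRegion, BispectrumGrid
from somnoscreen.io_preprocess import MANEUVERS, AnthropometricRecord, BreathPhaseSignal
from somnoscreen.spectral import PowerSpectrum

logger = logging.getLogger(__name__)

#: Full analysis band used by "Total" bispectral regions.
TOTAL_BAND = (0.0, 1800.0)

SOUND_OPERATORS = (
    "band_mean",
    "band_diff",
    "band_ratio",
    "slope_mean",
    "centroid",
    "centroid_bandwidth",
    "skewness",
    "first_peak",
    "higuchi",
    "bispec",
)


@dataclass(frozen=True)
class FeatureSpec:
    """One registry entry: label, source, operator and its parameters."""

    label: str
    source: str  # 'anthro' or one of the four maneuvers
    operator: str
    params: dict = field(default_factory=dict)

    @property
    def is_sound(self) -> bool:
        return self.source != "anthro"


def _anthro(label: str) -> FeatureSpec:
    return FeatureSpec(label, "anthro", "anthro", {})


def _ps(label, man, op, f1, f2, **extra) -> FeatureSpec:
    return FeatureSpec(label, man, op, {"band": (float(min(f1, f2)), float(max(f1, f2))), **extra})


def _bs(label, man, stat, kind, f1=None, f2=None) -> FeatureSpec:
    band = TOTAL_BAND if f1 is None else (float(min(f1, f2)), float(max(f1, f2)))
    return FeatureSpec(label, man, "bispec", {"stat": stat, "kind": kind, "band": band})


#: The 79-entry feature registry.
REGISTRY: tuple[FeatureSpec, ...] = (
    _anthro("F1"),   # body mass index, kg/m^2
    _anthro("F2"),   # age, years
    _anthro("F3"),   # sex, 0 = female / 1 = male
    _anthro("F4"),   # weight, kg
    _anthro("F5"),   # neck circumference, cm
    _anthro("F6"),   # Mallampati score, ordinal 1-4
    _ps("F7", "InsN", "band_mean", 350, 525),
    FeatureSpec("F8", "ExpM", "band_diff", {"band_a": (130.0, 235.0), "band_b": (1260.0, 1410.0)}),
    FeatureSpec("F9", "InsN", "band_diff", {"band_a": (115.0, 275.0), "band_b": (915.0, 1240.0)}),
    _ps("F10", "InsM", "first_peak", 75, 1800, zero_crossing=False),
    _ps("F11", "InsM", "centroid_bandwidth", 75, 1700),
    _ps("F12", "ExpM", "centroid_bandwidth", 300, 550),
    _ps("F13", "InsM", "first_peak", 0, 600, zero_crossing=True),
    _bs("F14", "InsM", "entropy", "square"),
    _bs("F15", "InsM", "moment1", "positive_diagonal", 1200, 1515),
    _bs("F16", "InsM", "moment1", "negative_diagonal", 1200, 1515),
    _bs("F17", "ExpM", "moment2", "line_half_f_f", 130, 235),
    _bs("F18", "InsN", "weight_center", "positive_diagonal"),
    _bs("F19", "InsN", "mean", "positive_diagonal", 250, 355),
    _bs("F20", "InsN", "weight_center", "square", 250, 355),
    _bs("F21", "InsN", "moment1", "positive_diagonal", 115, 275),
    _bs("F22", "InsN", "weight_center", "negative_diagonal", 350, 525),
    _ps("F23", "InsN", "slope_mean", 245, 350),
    _ps("F24", "InsN", "centroid_bandwidth", 100, 350),
    FeatureSpec("F25", "InsM", "higuchi", {"kmax": 8}),
    _bs("F26", "InsM", "geometric_mean", "square", 140, 270),
    _bs("F27", "InsM", "weight_center", "square"),
    _bs("F28", "InsM", "moment1", "line_2f_f", 140, 270),
    _bs("F29", "ExpM", "weight_center", "square"),
    _bs("F30", "InsN", "mean", "square", 130, 275),
    _bs("F31", "InsN", "moment2", "positive_diagonal", 130, 275),
    _ps("F32", "InsM", "band_mean", 130, 230),
    _ps("F33", "InsN", "band_mean", 130, 280),
    _ps("F34", "InsN", "slope_mean", 240, 340),
    _ps("F35", "InsN", "centroid_bandwidth", 80, 350),
    _ps("F36", "InsN", "centroid", 80, 560),
    _ps("F37", "InsM", "first_peak", 0, 1800, zero_crossing=True),
    _bs("F38", "InsM", "weight_center", "positive_diagonal"),
    _bs("F39", "InsM", "moment1", "line_2f_f", 130, 230),
    _bs("F40", "InsM", "moment2", "line_2f_f", 130, 230),
    _bs("F41", "InsN", "mean", "square", 130, 280),
    _bs("F42", "InsN", "mean", "negative_diagonal", 130, 280),
    _bs("F43", "InsN", "moment2", "negative_diagonal", 130, 280),
    _ps("F44", "ExpM", "band_mean", 375, 485),
    _ps("F45", "InsN", "band_mean", 360, 500),
    _ps("F46", "InsN", "band_mean", 1010, 1250),
    _ps("F47", "InsN", "slope_mean", 270, 370),
    _ps("F48", "ExpN", "slope_mean", 450, 550),
    _ps("F49", "ExpM", "centroid_bandwidth", 200, 600),
    _ps("F50", "InsN", "centroid", 440, 620),
    _ps("F51", "ExpN", "centroid_bandwidth", 300, 600),
    _bs("F52", "InsM", "weight_center", "line_2f_f", 390, 510),
    _bs("F53", "ExpM", "weight_center", "negative_diagonal", 270, 390),
    _bs("F54", "ExpM", "weight_center", "positive_diagonal", 270, 390),
    _bs("F55", "ExpN", "mean", "negative_diagonal", 450, 550),
    FeatureSpec("F56", "InsN", "band_ratio", {"num_band": (355.0, 510.0), "den_band": (820.0, 1070.0)}),
    _ps("F57", "InsN", "slope_mean", 250, 350),
    _ps("F58", "InsM", "skewness", 90, 550),
    _ps("F59", "InsN", "first_peak", 0, 550, zero_crossing=True),
    _bs("F60", "InsM", "mean", "square", 120, 250),
    _bs("F61", "InsM", "moment1", "positive_diagonal", 120, 250),
    _bs("F62", "InsN", "weight_center", "negative_diagonal", 355, 510),
    _bs("F63", "InsN", "moment2", "line_2f_f", 820, 1070),
    _bs("F64", "ExpN", "weight_center", "line_half_f_f", 100, 600),
    _ps("F65", "InsN", "band_mean", 395, 520),
    _ps("F66", "InsM", "first_peak", 60, 600, zero_crossing=False),
    _ps("F67", "InsN", "centroid", 150, 550),
    _bs("F68", "InsM", "weight_center", "line_half_f_f", 60, 600),
    _bs("F69", "InsM", "moment2", "line_2f_f", 60, 600),
    _bs("F70", "InsN", "weight_center", "positive_diagonal", 395, 520),
    _bs("F71", "InsN", "mean", "negative_diagonal", 395, 520),
    _bs("F72", "ExpN", "weight_center", "negative_diagonal", 100, 600),
    FeatureSpec("F73", "InsM", "band_ratio", {"num_band": (130.0, 230.0), "den_band": (1260.0, 1460.0)}),
    _bs("F74", "InsM", "moment1", "positive_diagonal", 1090, 1460),
    _bs("F75", "InsM", "moment1", "positive_diagonal", 1260, 1460),
    _bs("F76", "InsM", "weight_center", "line_half_f_f", 1090, 1460),
    _bs("F77", "InsM", "moment1", "line_half_f_f", 1260, 1460),
    _bs("F78", "ExpM", "moment1", "negative_diagonal", 1260, 1410),
    _bs("F79", "InsN", "moment1", "line_half_f_f", 300, 1600),
)

ALL_LABELS: tuple[str, ...] = tuple(s.label for s in REGISTRY)
SOUND_LABELS: tuple[str, ...] = tuple(s.label for s in REGISTRY if s.is_sound)
ANTHRO_LABELS: tuple[str, ...] = tuple(s.label for s in REGISTRY if not s.is_sound)


def registry_selfcheck(registry: Sequence[FeatureSpec] = REGISTRY) -> list[str]:
    """Validate a registry; returns a list of violations (empty if clean)."""
    problems: list[str] = []
    if len(registry) != 79:
        problems.append(f"registry has {len(registry)} entries, expected 79")
    labels = [s.label for s in registry]
    if len(set(labels)) != len(labels):
        problems.append("duplicate feature labels")
    expected_sources = {"F8": "ExpM", "F9": "InsN", "F7": "InsN", "F25": "InsM", "F48": "ExpN"}
    for s in registry:
        if s.source not in MANEUVERS and s.source != "anthro":
            problems.append(f"{s.label}: unknown source {s.source!r}")
        if s.label in expected_sources and s.source != expected_sources[s.label]:
            problems.append(f"{s.label}: source {s.source!r}, expected {expected_sources[s.label]!r}")
        for key in ("band", "band_a", "band_b", "num_band", "den_band"):
            if key in s.params:
                f1, f2 = s.params[key]
                if not f1 < f2:
                    problems.append(f"{s.label}: band {key}=({f1}, {f2}) not ordered f1 < f2")
        if s.operator not in SOUND_OPERATORS and s.operator != "anthro":
            problems.append(f"{s.label}: unknown operator {s.operator!r}")
    return problems


def _check_or_raise(registry: Sequence[FeatureSpec]) -> None:
    problems = registry_selfcheck(registry)
    if problems:
        raise ValueError("invalid feature registry: " + "; ".join(problems))


def _eval_spectral(spec: FeatureSpec, P: PowerSpectrum) -> float:
    p = spec.params
    if spec.operator == "band_mean":
        return spectral.band_mean(P, *p["band"])
    if spec.operator == "band_diff":
        return spectral.band_diff(P, p["band_a"], p["band_b"])
    if spec.operator == "band_ratio":
        return spectral.band_ratio(P, p["num_band"], p["den_band"])
    if spec.operator == "slope_mean":
        return spectral.band_slope_mean(P, *p["band"])
    if spec.operator == "centroid":
        return spectral.spectral_centroid(P, *p["band"])
    if spec.operator == "centroid_bandwidth":
        return spectral.spectral_bandwidth(P, *p["band"])
    if spec.operator == "skewness":
        return spectral.spectral_skewness(P, *p["band"])
    if spec.operator == "first_peak":
        freq, no_peak = spectral.first_peak_freq(P, *p["band"], zero_crossing=p["zero_crossing"])
        if no_peak:
            logger.debug("%s: no spectral peak in band; using band argmax", spec.label)
        return freq
    raise ValueError(f"not a spectral operator: {spec.operator}")


def _eval_bispec(spec: FeatureSpec, G: BispectrumGrid) -> float:
    p = spec.params
    region = BispectralRegion(kind=p["kind"], f1=p["band"][0], f2=p["band"][1])
    coords, weights = bispectral.extract_region(G, region)
    return bispectral.region_stat(coords, weights, p["stat"], kind=p["kind"])


class _ManeuverCache:
    """Per-maneuver spectrum / bispectrum / signal cache for one subject."""

    def __init__(self, signals: Mapping[str, Sequence[BreathPhaseSignal]], welch_kwargs, bispec_kwargs):
        self.signals = signals
        self.welch_kwargs = welch_kwargs
        self.bispec_kwargs = bispec_kwargs
        self._spectra: dict[str, PowerSpectrum] = {}
        self._grids: dict[str, BispectrumGrid] = {}

    def spectrum(self, maneuver: str) -> PowerSpectrum:
        if maneuver not in self._spectra:
            self._spectra[maneuver] = spectral.mean_spectrum(self.signals[maneuver], **self.welch_kwargs)
        return self._spectra[maneuver]

    def grid(self, maneuver: str) -> BispectrumGrid:
        if maneuver not in self._grids:
            self._grids[maneuver] = bispectral.mean_bispectrum(self.signals[maneuver], **self.bispec_kwargs)
        return self._grids[maneuver]


def compute_features(
    signals: Mapping[str, Sequence[BreathPhaseSignal]],
    anthro: AnthropometricRecord | None,
    registry: Sequence[FeatureSpec] = REGISTRY,
    welch_kwargs: dict | None = None,
    bispec_kwargs: dict | None = None,
) -> tuple[dict[str, float], dict[str, str]]:
    """Evaluate every registry feature for one subject.

    ``signals`` maps maneuver label to the subject's breath-phase signals.
    Returns ``(values, reasons)``: values keyed by feature label (NaN when
    missing), and a reason string for each missing value.
    """
    _check_or_raise(registry)
    cache = _ManeuverCache(signals, welch_kwargs or {}, bispec_kwargs or {})
    values: dict[str, float] = {}
    reasons: dict[str, str] = {}
    anthro_values = anthro.as_features() if anthro is not None else {}
    for spec in registry:
        if spec.source == "anthro":
            if spec.label in anthro_values:
                values[spec.label] = anthro_values[spec.label]
            else:
                values[spec.label] = float("nan")
                reasons[spec.label] = "no anthropometric record"
            continue
        if spec.source not in signals or not signals[spec.source]:
            values[spec.label] = float("nan")
            reasons[spec.label] = f"no {spec.source} recording"
            continue
        try:
            if spec.operator == "higuchi":
                per_breath = [
                    bispectral.higuchi_fd(s, kmax=spec.params.get("kmax", 8))
                    for s in signals[spec.source]
                ]
                values[spec.label] = float(np.mean(per_breath))
            elif spec.operator == "bispec":
                values[spec.label] = _eval_bispec(spec, cache.grid(spec.source))
            else:
                values[spec.label] = _eval_spectral(spec, cache.spectrum(spec.source))
        except (ValueError, ZeroDivisionError) as exc:
            values[spec.label] = float("nan")
            reasons[spec.label] = str(exc)
            logger.warning("feature %s failed for %s: %s", spec.label, spec.source, exc)
    return values, reasons


def compute_feature_table(
    signals_by_subject: Mapping[str, Mapping[str, Sequence[BreathPhaseSignal]]],
    anthro: Mapping[str, AnthropometricRecord],
    registry: Sequence[FeatureSpec] = REGISTRY,
    **kwargs,
) -> pd.DataFrame:
    """Wide feature table (subjects x F1..F79) for a cohort."""
    rows = {}
    for sid, by_man in signals_by_subject.items():
        values, _ = compute_features(by_man, anthro.get(sid), registry, **kwargs)
        rows[sid] = values
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df[[s.label for s in registry]]


def dump_registry(path: str | Path, registry: Sequence[FeatureSpec] = REGISTRY) -> None:
    """Serialize a registry to versioned YAML."""
    payload = {
        "version": 1,
        "features": [
            {"label": s.label, "source": s.source, "operator": s.operator,
             "params": {k: list(v) if isinstance(v, tuple) else v for k, v in s.params.items()}}
            for s in registry
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_registry(path: str | Path) -> tuple[FeatureSpec, ...]:
    """Load a registry from YAML and validate it."""
    payload = yaml.safe_load(Path(path).read_text())
    registry = tuple(
        FeatureSpec(
            label=e["label"],
            source=e["source"],
            operator=e["operator"],
            params={k: tuple(v) if isinstance(v, list) else v for k, v in e.get("params", {}).items()},
        )
        for e in payload["features"]
    )
    _check_or_raise(registry)
    return registry
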