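"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates what the analysis needs from a clinical cohort and
nothing more:

* a latent severity scalar per subject (z-scored log-severity drives all
  effects);
* breathing sounds built from Gaussian noise shaped by two broad resonances
  (~200 Hz and ~900 Hz) whose gain inside four designated gap bands
  (150-300, 720-900, 1050-1120 and 1450-1700 Hz) shifts with severity, plus
  a quadratically phase-coupled tone triple (180, 220, 400 Hz) whose
  amplitude grows with severity so bispectral features are informative;
* anthropometrics linearly linked to severity (logistic link for sex);
* PSG parameters that are monotone functions of severity plus noise,
  clipped to their natural range.

Everything is a deterministic function of the spec and its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from dataclasses import replace as dataclasses_replace
from pathlib import Path
from typing import Mapping

import numpy as np

from somnoscreen.io_preprocess import (
    MANEUVERS,
    AnthropometricRecord,
    BreathPhaseSignal,
    PSGReport,
    write_recording,
    write_tables,
)

#: Frequency bands (Hz) in which severity shifts band power.
GAP_BANDS: tuple[tuple[float, float], ...] = ((150.0, 300.0), (720.0, 900.0), (1050.0, 1120.0), (1450.0, 1700.0))


@dataclass(frozen=True)
class PSGParamDef:
    """A synthetic PSG parameter: monotone link of severity + noise + range."""

    link: str  # 'exp' or 'linear'
    base: float
    slope: float  # per severity SD; sign sets direction
    noise_sd: float
    lo: float
    hi: float

    def sample(self, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.normal(0.0, self.noise_sd, size=z.shape)
        if self.link == "exp":
            raw = self.base * np.exp(self.slope * z + eps)
        elif self.link == "linear":
            raw = self.base + self.slope * z + eps
        else:
            raise ValueError(f"unknown link {self.link!r}")
        return np.clip(raw, self.lo, self.hi)


DEFAULT_PSG_PARAMS: dict[str, PSGParamDef] = {
    # events/hour; lognormal-shaped, strongly severity-linked
    "Total Arousal Index": PSGParamDef("exp", base=24.0, slope=0.55, noise_sd=0.30, lo=0.0, hi=130.0),
    # percent saturation; mild negative link
    "Mean SpO2% Total TST": PSGParamDef("linear", base=94.0, slope=-1.6, noise_sd=0.9, lo=75.0, hi=100.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort."""

    n_subjects: int = 120
    seed: int = 0
    fs: float = 10240.0
    breath_s: float = 1.2
    n_breaths: int = 5
    maneuvers: tuple[str, ...] = MANEUVERS
    # severity: lognormal(mu, sigma); z = standardized log-severity
    severity_mu: float = 0.0
    severity_sigma: float = 0.5
    # spectral effect: dB shift per severity SD inside each gap band
    gap_bands: tuple[tuple[float, float], ...] = GAP_BANDS
    band_effect_db: tuple[float, ...] = (-2.5, 2.5, 2.5, 2.5)
    # quadratic phase coupling: tone amplitude relative to noise RMS
    qpc_freqs: tuple[float, float] = (180.0, 220.0)
    qpc_base_amp: float = 0.15
    qpc_amp_slope: float = 0.08
    # anthropometrics (Table-2-like ranges)
    nc_base: float = 41.5
    nc_slope: float = 2.2
    nc_sd: float = 3.5
    bmi_base: float = 32.5
    bmi_slope: float = 2.0
    bmi_sd: float = 4.5
    age_mean: float = 50.0
    age_sd: float = 10.0
    sex_logit_base: float = 0.1
    sex_logit_slope: float = 0.6
    mallampati_slope: float = 0.8
    psg_params: Mapping[str, PSGParamDef] = field(default_factory=lambda: dict(DEFAULT_PSG_PARAMS))

    def __post_init__(self) -> None:
        if self.n_subjects < 40:
            raise ValueError("n_subjects must be >= 40")
        if self.severity_sigma <= 0:
            raise ValueError("severity_sigma must be > 0")
        for f1, f2 in self.gap_bands:
            if not (75.0 <= f1 < f2 <= 1800.0):
                raise ValueError(f"gap band ({f1}, {f2}) outside the 75-1800 Hz analysis band")
        if len(self.band_effect_db) != len(self.gap_bands):
            raise ValueError("band_effect_db must match gap_bands in length")

    def null(self) -> "CohortSpec":
        """Same cohort shape with every severity effect on the sounds and
        anthropometrics set to zero (PSG links stay monotone in severity)."""
        return replace(
            self,
            band_effect_db=tuple(0.0 for _ in self.gap_bands),
            qpc_amp_slope=0.0,
            nc_slope=0.0,
            bmi_slope=0.0,
            sex_logit_slope=0.0,
            mallampati_slope=0.0,
        )


@dataclass
class Cohort:
    """A generated cohort plus its ground truth."""

    spec: CohortSpec
    signals: dict[str, dict[str, list[BreathPhaseSignal]]]
    anthro: dict[str, AnthropometricRecord]
    psg: dict[str, PSGReport]
    severity_z: dict[str, float]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.signals.keys())


@dataclass(frozen=True)
class _Anatomy:
    """Per-subject airway acoustics: resonance shifts and gains.

    Upper-airway geometry differs between people, so resonance centers,
    widths and the relative weight of the second resonance vary across the
    cohort (independently of severity)."""

    dr1: float
    dr2: float
    w1: float
    w2: float
    a2_gain: float
    floor: float

    @staticmethod
    def sample(rng: np.random.Generator) -> "_Anatomy":
        return _Anatomy(
            dr1=float(rng.normal(0.0, 25.0)),
            dr2=float(rng.normal(0.0, 60.0)),
            w1=float(180.0 * rng.lognormal(0.0, 0.2)),
            w2=float(380.0 * rng.lognormal(0.0, 0.2)),
            a2_gain=float(rng.lognormal(0.0, 0.25)),
            floor=float(0.02 * rng.lognormal(0.0, 0.3)),
        )


def _base_envelope(freqs: np.ndarray, maneuver: str, anatomy: _Anatomy) -> np.ndarray:
    """Amplitude envelope: two broad resonances over a gently decaying floor.

    Mouth maneuvers sit slightly lower in frequency than nose maneuvers, and
    expirations carry relatively more low-frequency weight — enough contrast
    that per-maneuver features are not clones of one another.  Subject
    anatomy shifts both resonances.
    """
    r1 = (200.0 if maneuver.endswith("M") else 240.0) + anatomy.dr1
    r2 = (900.0 if maneuver.startswith("Ins") else 820.0) + anatomy.dr2
    a2 = (0.35 if maneuver.startswith("Ins") else 0.25) * anatomy.a2_gain
    env = (
        1.0 / (1.0 + ((freqs - r1) / anatomy.w1) ** 2)
        + a2 / (1.0 + ((freqs - r2) / anatomy.w2) ** 2)
        + anatomy.floor
    )
    env *= np.exp(-freqs / 2500.0)
    return env


def _band_gain(freqs: np.ndarray, spec: CohortSpec, z: float, edge_hz: float = 30.0) -> np.ndarray:
    """Severity-dependent amplitude gain with raised-cosine band edges."""
    gain_db = np.zeros_like(freqs)
    for (f1, f2), eff in zip(spec.gap_bands, spec.band_effect_db):
        shift = eff * z
        ramp_up = 0.5 * (1 + np.cos(np.pi * np.clip((f1 - freqs) / edge_hz, 0, 1)))
        ramp_dn = 0.5 * (1 + np.cos(np.pi * np.clip((freqs - f2) / edge_hz, 0, 1)))
        gain_db = gain_db + shift * ramp_up * ramp_dn
    return 10.0 ** (gain_db / 20.0)


def _synth_breath(
    rng: np.random.Generator, spec: CohortSpec, maneuver: str, z: float, anatomy: _Anatomy
) -> np.ndarray:
    n = int(round(spec.breath_s * spec.fs))
    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
    noise = rng.standard_normal(n)
    # small breath-to-breath wobble of the resonances
    jitter = dataclasses_replace(anatomy, dr1=anatomy.dr1 + float(rng.normal(0, 4.0)),
                                 dr2=anatomy.dr2 + float(rng.normal(0, 8.0)))
    shaped = np.fft.irfft(np.fft.rfft(noise) * _base_envelope(freqs, maneuver, jitter) * _band_gain(freqs, spec, z), n)
    rms = float(np.sqrt(np.mean(shaped**2)))
    amp = max(0.0, spec.qpc_base_amp + spec.qpc_amp_slope * z) * rms
    fa, fb = spec.qpc_freqs
    t = np.arange(n) / spec.fs
    p1, p2 = rng.uniform(0.0, 2 * np.pi, size=2)
    qpc = amp * (
        np.cos(2 * np.pi * fa * t + p1)
        + np.cos(2 * np.pi * fb * t + p2)
        + np.cos(2 * np.pi * (fa + fb) * t + p1 + p2)
    )
    x = shaped + qpc
    x = x - x.mean()
    return x / np.abs(x).max()


def _sample_mallampati(rng: np.random.Generator, spec: CohortSpec, z: float) -> int:
    latent = spec.mallampati_slope * z + rng.normal(0.0, 1.0)
    return int(1 + (latent > -0.3) + (latent > 0.9) + (latent > 1.9))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort.  Same spec (incl. seed) -> same cohort."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    z = (np.log(rng.lognormal(spec.severity_mu, spec.severity_sigma, size=n)) - spec.severity_mu) / spec.severity_sigma

    ids = [f"S{i + 1:03d}" for i in range(n)]
    signals: dict[str, dict[str, list[BreathPhaseSignal]]] = {}
    anthro: dict[str, AnthropometricRecord] = {}
    psg_values = {name: d.sample(z, rng) for name, d in spec.psg_params.items()}
    clip_frac = {
        name: float(np.mean((v <= d.lo) | (v >= d.hi)))
        for (name, d), v in zip(spec.psg_params.items(), psg_values.values())
    }
    for name, frac in clip_frac.items():
        if frac > 0.2:
            import warnings

            warnings.warn(f"PSG parameter {name!r}: {frac:.0%} of values clipped to range", stacklevel=2)

    psg: dict[str, PSGReport] = {}
    for i, sid in enumerate(ids):
        zi = float(z[i])
        anatomy = _Anatomy.sample(rng)
        by_man: dict[str, list[BreathPhaseSignal]] = {}
        for man in spec.maneuvers:
            by_man[man] = [
                BreathPhaseSignal(
                    subject_id=sid,
                    maneuver=man,
                    samples=_synth_breath(rng, spec, man, zi, anatomy),
                    fs=spec.fs,
                    breath_index=b + 1,
                )
                for b in range(spec.n_breaths)
            ]
        signals[sid] = by_man

        height = rng.normal(1.70, 0.08)
        bmi = max(16.0, spec.bmi_base + spec.bmi_slope * zi + rng.normal(0.0, spec.bmi_sd))
        sex = int(rng.random() < 1.0 / (1.0 + np.exp(-(spec.sex_logit_base + spec.sex_logit_slope * zi))))
        anthro[sid] = AnthropometricRecord(
            subject_id=sid,
            bmi=bmi,
            age=float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18.0, 90.0)),
            sex=sex,
            weight=float(bmi * height**2),
            neck_circumference=max(
                30.0, spec.nc_base + spec.nc_slope * zi + rng.normal(0.0, spec.nc_sd)
            ),
            mallampati=_sample_mallampati(rng, spec, zi),
        )
        psg[sid] = PSGReport(subject_id=sid, values={name: float(v[i]) for name, v in psg_values.items()})

    return Cohort(
        spec=spec,
        signals=signals,
        anthro=anthro,
        psg=psg,
        severity_z={sid: float(z[i]) for i, sid in enumerate(ids)},
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort in the exact formats the readers consume.

    Per subject: ``<id>.wav`` plus ``<id>_annotations.csv``; cohort-level
    ``anthropometrics.csv``, ``psg.csv``, and ground truth in
    ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, by_man in cohort.signals.items():
        flat = [s for sigs in by_man.values() for s in sigs]
        write_recording(outdir / f"{sid}.wav", outdir / f"{sid}_annotations.csv", flat)
    write_tables(outdir / "anthropometrics.csv", outdir / "psg.csv", cohort.anthro, cohort.psg)
    (outdir / "ground_truth.json").write_text(json.dumps({"severity_z": cohort.severity_z}, indent=1))


def worked_example_fixture() -> np.ndarray:
    """A deterministic, symmetric PSG value set on [0.5, 7.0] (n = 100).

    Mirrors a total-sleep-time-like parameter whose range, divided into 20
    equal parts, yields the candidate thresholds 0.825, 1.15, ..., 6.675.
    """
    return np.linspace(0.5, 7.0, 100)
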