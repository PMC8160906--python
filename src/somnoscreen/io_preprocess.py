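"""Reading and normalizing breathing-sound recordings and subject tables.

A recording session yields, per subject, five deep breaths through the nose
followed by five through the mouth; each breath is split into an inspiratory
and an expiratory phase, giving four breathing maneuvers:

* ``InsM`` / ``ExpM`` — mouth inspiration / expiration,
* ``InsN`` / ``ExpN`` — nose inspiration / expiration.

Automatic breath-phase detection is out of scope: phase boundaries are
supplied as an annotation table alongside the WAV file.  Each annotated
segment is sliced half-open ``[start, end)``, de-meaned, and rescaled to
unit maximum absolute amplitude so that downstream spectral features depend
on spectral shape rather than recording gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: The four breathing maneuvers (inspiration/expiration x mouth/nose).
MANEUVERS: tuple[str, ...] = ("InsM", "ExpM", "InsN", "ExpN")

#: Minimum sampling rate: twice the highest analysis band edge (1800 Hz).
MIN_FS_HZ = 3600.0

#: Minimum usable segment duration in seconds.
MIN_SEGMENT_S = 0.25

ANNOTATION_COLUMNS = ("subject_id", "maneuver", "breath_index", "start_s", "end_s")
ANTHRO_COLUMNS = ("subject_id", "bmi", "age", "sex", "weight", "neck_circumference", "mallampati")

_SEX_CODES = {"F": 0, "M": 1, "FEMALE": 0, "MALE": 1, "0": 0, "1": 1}


@dataclass
class BreathPhaseSignal:
    """One maneuver-labeled breath-phase waveform.

    ``samples`` are dimensionless (zero mean, unit max-abs after
    normalization); ``fs`` is the sampling rate in Hz.
    """

    subject_id: str
    maneuver: str
    samples: np.ndarray
    fs: float
    breath_index: int = 1

    def __post_init__(self) -> None:
        if self.maneuver not in MANEUVERS:
            raise ValueError(f"unknown maneuver label {self.maneuver!r}; expected one of {MANEUVERS}")
        if self.fs <= MIN_FS_HZ:
            raise ValueError(
                f"insufficient bandwidth: fs={self.fs} Hz must exceed {MIN_FS_HZ} Hz "
                "(twice the 1800 Hz analysis band edge)"
            )
        self.samples = np.asarray(self.samples, dtype=float)
        if self.breath_index < 1:
            raise ValueError("breath_index must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class AnthropometricRecord:
    """Anthropometric features of a subject (feature labels F1-F6).

    ``sex`` is coded 0 = female, 1 = male so it can enter regression models
    numerically; ``mallampati`` is the ordinal Mallampati score (1-4), a
    clinical grade of oropharyngeal visibility.
    """

    subject_id: str
    bmi: float
    age: float
    sex: int
    weight: float
    neck_circumference: float
    mallampati: int

    def __post_init__(self) -> None:
        for name in ("bmi", "age", "weight", "neck_circumference"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r} (subject {self.subject_id})")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (female) or 1 (male), got {self.sex!r}")
        if self.mallampati not in (1, 2, 3, 4):
            raise ValueError(f"mallampati must be in 1..4, got {self.mallampati!r}")

    def as_features(self) -> dict[str, float]:
        """Anthropometrics keyed by feature label."""
        return {
            "F1": float(self.bmi),
            "F2": float(self.age),
            "F3": float(self.sex),
            "F4": float(self.weight),
            "F5": float(self.neck_circumference),
            "F6": float(self.mallampati),
        }


@dataclass
class PSGReport:
    """Named polysomnography report parameters for one subject.

    Values may be missing (NaN); percentage-typed parameters must lie in
    [0, 100].
    """

    subject_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if v is None:
                self.values[name] = float("nan")
                continue
            v = float(v)
            if np.isinf(v):
                raise ValueError(f"PSG parameter {name!r} is not finite for subject {self.subject_id}")
            if "%" in name and np.isfinite(v) and not (0.0 <= v <= 100.0):
                raise ValueError(
                    f"percentage PSG parameter {name!r}={v} outside [0, 100] for subject {self.subject_id}"
                )
            self.values[name] = v


def _normalize_segment(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit max-abs.  A constant segment normalizes to all zeros."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak
    return x


def read_recording(audio_path: str | Path, annotation_path: str | Path) -> list[BreathPhaseSignal]:
    """Read a mono PCM WAV and its breath-phase annotation CSV.

    The annotation CSV has columns ``subject_id, maneuver, breath_index,
    start_s, end_s``; one :class:`BreathPhaseSignal` is returned per row,
    sliced half-open ``[start_s, end_s)`` and amplitude-normalized.

    Raises
    ------
    ValueError
        On non-mono audio, insufficient sampling rate, unknown maneuver
        labels, out-of-bounds or overlapping same-maneuver annotations.
    """
    fs, data = wavfile.read(str(audio_path))
    if data.ndim != 1:
        raise ValueError(f"{audio_path}: expected mono audio, got shape {data.shape}")
    if fs <= MIN_FS_HZ:
        raise ValueError(f"{audio_path}: insufficient bandwidth (fs={fs} Hz <= {MIN_FS_HZ} Hz)")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    duration = data.size / fs

    ann = pd.read_csv(annotation_path)
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"{annotation_path}: missing annotation columns {sorted(missing)}")

    # overlap check within each maneuver
    for man, grp in ann.groupby("maneuver"):
        iv = grp.sort_values("start_s")[["start_s", "end_s"]].to_numpy(float)
        if np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError(f"{annotation_path}: overlapping annotations for maneuver {man!r}")

    signals: list[BreathPhaseSignal] = []
    for row in ann.itertuples(index=False):
        start_s, end_s = float(row.start_s), float(row.end_s)
        if not (0.0 <= start_s < end_s):
            raise ValueError(f"bad annotation interval [{start_s}, {end_s}) for {row.subject_id}")
        if end_s > duration + 0.5 / fs:
            raise ValueError(
                f"annotation end {end_s:.3f}s beyond file duration {duration:.3f}s for {row.subject_id}"
            )
        i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
        seg = _normalize_segment(data[i0:i1])
        if seg.size < MIN_SEGMENT_S * fs:
            raise ValueError(
                f"segment [{start_s}, {end_s}) shorter than {MIN_SEGMENT_S}s for {row.subject_id}"
            )
        signals.append(
            BreathPhaseSignal(
                subject_id=str(row.subject_id),
                maneuver=str(row.maneuver),
                samples=seg,
                fs=float(fs),
                breath_index=int(row.breath_index),
            )
        )
    return signals


def write_recording(
    path: str | Path,
    annotation_path: str | Path,
    signals: list[BreathPhaseSignal],
    gap_s: float = 0.1,
) -> None:
    """Write breath-phase signals back to a WAV + annotation CSV pair.

    Segments are concatenated with short silent gaps; the generated
    annotation table round-trips through :func:`read_recording`.
    """
    if not signals:
        raise ValueError("no signals to write")
    fs = signals[0].fs
    if any(s.fs != fs for s in signals):
        raise ValueError("all signals must share one sampling rate")
    gap = np.zeros(int(round(gap_s * fs)))
    chunks, rows = [], []
    cursor = 0
    for s in signals:
        start = cursor / fs
        chunks.append(s.samples)
        cursor += s.samples.size
        rows.append((s.subject_id, s.maneuver, s.breath_index, start, cursor / fs))
        chunks.append(gap)
        cursor += gap.size
    audio = np.concatenate(chunks)
    peak = np.abs(audio).max()
    if peak > 0:
        audio = audio / peak * 0.9
    wavfile.write(str(path), int(fs), (audio * np.iinfo(np.int16).max).astype(np.int16))
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(annotation_path, index=False)


def _parse_sex(value) -> int:
    s = str(value).strip().upper()
    if s in _SEX_CODES:
        return _SEX_CODES[s]
    raise ValueError(f"cannot interpret sex value {value!r} (expected F/M or 0/1)")


def read_tables(
    anthro_path: str | Path, psg_path: str | Path
) -> tuple[dict[str, AnthropometricRecord], dict[str, PSGReport]]:
    """Read the anthropometrics and PSG report CSV tables.

    Returns ``(anthro, psg)`` maps keyed by subject id.  Subjects present in
    only one table are retained and logged.  Missing PSG cells become NaN;
    non-numeric values in numeric columns raise with row/column context.
    """
    at = pd.read_csv(anthro_path, dtype={"subject_id": str})
    missing = set(ANTHRO_COLUMNS) - set(at.columns)
    if missing:
        raise ValueError(f"{anthro_path}: missing columns {sorted(missing)}")
    anthro: dict[str, AnthropometricRecord] = {}
    for i, row in at.iterrows():
        kwargs = {}
        for col in ("bmi", "age", "weight", "neck_circumference", "mallampati"):
            try:
                kwargs[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{anthro_path}: non-numeric value {row[col]!r} in row {i}, column {col!r}") from exc
        anthro[str(row["subject_id"])] = AnthropometricRecord(
            subject_id=str(row["subject_id"]),
            bmi=kwargs["bmi"],
            age=kwargs["age"],
            sex=_parse_sex(row["sex"]),
            weight=kwargs["weight"],
            neck_circumference=kwargs["neck_circumference"],
            mallampati=int(kwargs["mallampati"]),
        )

    pt = pd.read_csv(psg_path, dtype={"subject_id": str})
    if "subject_id" not in pt.columns:
        raise ValueError(f"{psg_path}: missing subject_id column")
    psg: dict[str, PSGReport] = {}
    param_cols = [c for c in pt.columns if c != "subject_id"]
    for i, row in pt.iterrows():
        values = {}
        for col in param_cols:
            cell = row[col]
            if pd.isna(cell):
                values[col] = float("nan")
                continue
            try:
                values[col] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{psg_path}: non-numeric value {cell!r} in row {i}, column {col!r}") from exc
        psg[str(row["subject_id"])] = PSGReport(subject_id=str(row["subject_id"]), values=values)

    only_a = sorted(set(anthro) - set(psg))
    only_p = sorted(set(psg) - set(anthro))
    if only_a:
        logger.warning("subjects only in anthropometrics table: %s", only_a)
    if only_p:
        logger.warning("subjects only in PSG table: %s", only_p)
    return anthro, psg


def write_tables(
    anthro_path: str | Path,
    psg_path: str | Path,
    anthro: Mapping[str, AnthropometricRecord],
    psg: Mapping[str, PSGReport],
) -> None:
    """Write the two tables in the exact format :func:`read_tables` reads."""
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "bmi": r.bmi,
                "age": r.age,
                "sex": r.sex,
                "weight": r.weight,
                "neck_circumference": r.neck_circumference,
                "mallampati": r.mallampati,
            }
            for r in anthro.values()
        ]
    ).to_csv(anthro_path, index=False)
    rows = []
    for r in psg.values():
        row = {"subject_id": r.subject_id}
        row.update(r.values)
        rows.append(row)
    pd.DataFrame(rows).to_csv(psg_path, index=False)


def group_by_subject(signals: list[BreathPhaseSignal]) -> dict[str, dict[str, list[BreathPhaseSignal]]]:
    """Index signals as ``{subject_id: {maneuver: [breaths...]}}``."""
    out: dict[str, dict[str, list[BreathPhaseSignal]]] = {}
    for s in signals:
        out.setdefault(s.subject_id, {}).setdefault(s.maneuver, []).append(s)
    for by_man in out.values():
        for sigs in by_man.values():
            sigs.sort(key=lambda s: s.breath_index)
    return out
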