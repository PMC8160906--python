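"""Welch power spectra of breath-phase signals and the P(f) band operators.

Spectra are estimated with Welch's method (Hann window, 1024 samples — 100 ms
at the nominal 10,240 Hz rate — 50% overlap, 10 Hz bin spacing) and
normalized so that the total power over the 75-1800 Hz analysis band is 1.
All band operators therefore measure spectral *shape* and are invariant to
recording gain.

Band limits are taken as closed intervals on bin centers.  Band means,
ratios and differences are computed on linear power; the band slope is
computed on dB power (10 log10), matching how group-average spectra are
compared on a log scale elsewhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import signal as sps

from somnoscreen.io_preprocess import BreathPhaseSignal

#: Analysis band over which spectra are normalized to unit total power.
ANALYSIS_BAND = (75.0, 1800.0)

#: Default Welch settings: 1024-sample Hann window, 50% overlap.
DEFAULT_WINDOW_S = 0.1
DEFAULT_OVERLAP = 0.5


@dataclass
class PowerSpectrum:
    """A normalized Welch power spectrum on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    maneuver: str
    subject_id: str = ""

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_indices(self, f1: float, f2: float) -> np.ndarray:
        """Indices of bins with f1 <= f <= f2 (closed interval, bin centers)."""
        if not (0.0 <= f1 < f2 <= self.freqs[-1]):
            raise ValueError(f"invalid band [{f1}, {f2}] for grid up to {self.freqs[-1]} Hz")
        idx = np.nonzero((self.freqs >= f1) & (self.freqs <= f2))[0]
        if idx.size == 0:
            raise ValueError(f"empty band [{f1}, {f2}] at df={self.df} Hz")
        return idx


def _normalize(freqs: np.ndarray, power: np.ndarray) -> np.ndarray:
    band = (freqs >= ANALYSIS_BAND[0]) & (freqs <= ANALYSIS_BAND[1])
    total = power[band].sum()
    if total <= 0:
        raise ValueError("zero power in the 75-1800 Hz analysis band")
    return power / total


def welch_psd(
    signal: BreathPhaseSignal,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP,
) -> PowerSpectrum:
    """Welch-averaged modified periodogram of one breath-phase signal.

    The returned spectrum is normalized to unit total power over 75-1800 Hz.
    """
    nperseg = int(round(window_s * signal.fs))
    if nperseg < 64:
        raise ValueError(f"window of {nperseg} samples too short (need >= 64)")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in [0, 1)")
    if signal.samples.size < nperseg:
        raise ValueError(
            f"signal of {signal.samples.size} samples shorter than one {nperseg}-sample window"
        )
    freqs, pxx = sps.welch(
        signal.samples,
        fs=signal.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
        detrend="constant",
    )
    return PowerSpectrum(
        freqs=freqs, power=_normalize(freqs, pxx), maneuver=signal.maneuver, subject_id=signal.subject_id
    )


def mean_spectrum(signals: Iterable[BreathPhaseSignal], **welch_kwargs) -> PowerSpectrum:
    """Per-subject, per-maneuver spectrum: mean of the per-breath spectra.

    Each breath is weighted equally (spectra are normalized before
    averaging, and the average of unit-total spectra keeps unit total).
    """
    specs = [welch_psd(s, **welch_kwargs) for s in signals]
    if not specs:
        raise ValueError("no signals to average")
    if len({s.maneuver for s in specs}) > 1:
        raise ValueError("signals mix maneuvers; average one maneuver at a time")
    power = np.mean([s.power for s in specs], axis=0)
    return PowerSpectrum(
        freqs=specs[0].freqs, power=power, maneuver=specs[0].maneuver, subject_id=specs[0].subject_id
    )


def to_db(power: np.ndarray, floor_rel: float = 1e-12) -> np.ndarray:
    """10*log10 of power with a relative floor to keep the log defined."""
    power = np.asarray(power, float)
    floor = floor_rel * power.max()
    return 10.0 * np.log10(np.maximum(power, floor))


def band_mean(P: PowerSpectrum, f1: float, f2: float) -> float:
    """Arithmetic mean of linear power over the closed band [f1, f2]."""
    return float(P.power[P.band_indices(f1, f2)].mean())


def band_diff(P: PowerSpectrum, band_a: tuple[float, float], band_b: tuple[float, float]) -> float:
    """band_mean(band_a) - band_mean(band_b)."""
    return band_mean(P, *band_a) - band_mean(P, *band_b)


def band_ratio(P: PowerSpectrum, num_band: tuple[float, float], den_band: tuple[float, float]) -> float:
    """band_mean(num_band) / band_mean(den_band)."""
    den = band_mean(P, *den_band)
    if den == 0:
        raise ValueError(f"zero denominator band mean over {den_band}")
    return band_mean(P, *num_band) / den


def band_slope_mean(P: PowerSpectrum, f1: float, f2: float) -> float:
    """Mean slope of the dB spectrum over [f1, f2], in dB per Hz.

    Power is floored at 1e-12 of the spectrum maximum before taking logs so
    an exact-zero bin does not blow up the slope.
    """
    idx = P.band_indices(f1, f2)
    if idx.size < 3:
        raise ValueError(f"band [{f1}, {f2}] has {idx.size} bins; need >= 3")
    db = to_db(P.power)[idx]
    return float(np.diff(db).mean() / P.df)


def _band_moments(P: PowerSpectrum, f1: float, f2: float) -> tuple[float, float, np.ndarray, np.ndarray]:
    idx = P.band_indices(f1, f2)
    if idx.size < 3:
        raise ValueError(f"band [{f1}, {f2}] has {idx.size} bins; need >= 3")
    w = P.power[idx]
    total = w.sum()
    if total <= 0:
        raise ValueError(f"zero band power over [{f1}, {f2}]")
    p = w / total
    f = P.freqs[idx]
    c = float(np.sum(f * p))
    bw = float(np.sqrt(np.sum((f - c) ** 2 * p)))
    return c, bw, f, p


def spectral_centroid(P: PowerSpectrum, f1: float, f2: float) -> float:
    """Power-weighted mean frequency of the band, in Hz."""
    return _band_moments(P, f1, f2)[0]


def spectral_bandwidth(P: PowerSpectrum, f1: float, f2: float) -> float:
    """Power-weighted standard deviation about the centroid, in Hz."""
    return _band_moments(P, f1, f2)[1]


def spectral_skewness(P: PowerSpectrum, f1: float, f2: float) -> float:
    """Power-weighted skewness of the in-band frequency distribution."""
    c, bw, f, p = _band_moments(P, f1, f2)
    if bw == 0:
        return 0.0
    return float(np.sum(((f - c) / bw) ** 3 * p))


def first_peak_freq(
    P: PowerSpectrum, f1: float, f2: float, zero_crossing: bool = True
) -> tuple[float, bool]:
    """Frequency of the first spectral peak within [f1, f2].

    ``zero_crossing=True``: the spectrum is smoothed with a 5-bin centered
    moving average and the first + -> - sign change of its first difference
    is returned.  ``zero_crossing=False``: the first local maximum of the
    raw spectrum exceeding 10% of the band maximum.

    Returns ``(frequency_hz, no_peak_flag)``; if no peak exists the band's
    argmax frequency is returned with the flag set.
    """
    idx = P.band_indices(f1, f2)
    if idx.size < 7:
        raise ValueError(f"band [{f1}, {f2}] has {idx.size} bins; need >= 7")
    f = P.freqs[idx]
    if zero_crossing:
        # 5-bin centered moving average on the full grid, then restrict
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(P.power, kernel, mode="same")[idx]
        d = np.diff(smooth)
        sign_change = np.nonzero((d[:-1] > 0) & (d[1:] < 0))[0]
        if sign_change.size:
            return _parabolic_refine(f, smooth, int(sign_change[0] + 1), P.df), False
        return _parabolic_refine(f, smooth, int(np.argmax(smooth)), P.df), True
    raw = P.power[idx]
    thresh = 0.10 * raw.max()
    local_max = np.nonzero((raw[1:-1] > raw[:-2]) & (raw[1:-1] >= raw[2:]) & (raw[1:-1] > thresh))[0]
    if local_max.size:
        return _parabolic_refine(f, raw, int(local_max[0] + 1), P.df), False
    return _parabolic_refine(f, raw, int(np.argmax(raw)), P.df), True


def _parabolic_refine(f: np.ndarray, y: np.ndarray, i: int, df: float) -> float:
    """Sub-bin peak location by a parabola through the peak and its
    neighbors (plain bin center at the band edges or for a flat triple)."""
    if not 0 < i < y.size - 1:
        return float(f[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0 or not np.isfinite(denom):
        return float(f[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(f[i] + np.clip(delta, -0.5, 0.5) * df)
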