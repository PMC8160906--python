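"""Indirect-method bispectrum estimation and the B(f1,f2) region operators.

The bispectrum B(f1,f2) — the 2-D Fourier transform of the third-order
cumulant c3(tau1, tau2) — vanishes for Gaussian signals and lights up at
bifrequencies (fa, fb) where quadratic phase coupling (QPC) ties the phase
of the fa+fb component to the sum of the phases at fa and fb.  Tracheal
breathing sounds carry such non-Gaussian structure, which is why several
sound features integrate |B| over diagonals and lines of the bifrequency
plane.

Estimator (indirect class, conventional):

1. decimate the signal to ~5 kHz (the analysis content ends at 1800 Hz and
   the bifrequency grid still reaches 2560 Hz);
2. split into 1024-sample records, subtract each record's mean;
3. per record, accumulate the biased third-order cumulant estimate on the
   square |tau1|,|tau2| <= max_lag; average cumulants over records (the
   complex averaging is what cancels non-phase-coupled content);
4. apply a Parzen lag window (triple product w(t1) w(t2) w(t1-t2), which
   preserves all cumulant symmetries);
5. 2-D FFT; keep the modulus on the non-negative quadrant.

Defaults: ``max_lag=128``, ``nfft=256`` at the 5120 Hz internal rate, i.e.
a 20 Hz bifrequency grid — the narrowest catalog band still spans >= 3 bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import signal as sps

from somnoscreen.io_preprocess import BreathPhaseSignal

#: Internal sampling rate ceiling for cumulant estimation (Hz).
TARGET_FS = 5120.0

DEFAULT_MAX_LAG = 128
DEFAULT_NFFT = 256
DEFAULT_RECLEN = 1024

RegionKind = Literal["square", "positive_diagonal", "negative_diagonal", "line_2f_f", "line_half_f_f"]
StatKind = Literal["mean", "geometric_mean", "entropy", "weight_center", "moment1", "moment2"]

_LINE_KINDS = ("positive_diagonal", "negative_diagonal", "line_2f_f", "line_half_f_f")


@dataclass
class BispectrumGrid:
    """|B(f1, f2)| on a uniform non-negative bifrequency grid."""

    freqs: np.ndarray
    mag: np.ndarray
    maneuver: str
    subject_id: str = ""

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def nearest(self, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
        """Magnitude at the grid node nearest each (f1, f2) coordinate."""
        i = np.clip(np.round(np.asarray(f1) / self.df).astype(int), 0, self.freqs.size - 1)
        j = np.clip(np.round(np.asarray(f2) / self.df).astype(int), 0, self.freqs.size - 1)
        return self.mag[i, j]


@dataclass
class BispectralRegion:
    """A region of the bifrequency plane: a band square, a diagonal, or a line."""

    kind: RegionKind
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not self.f1 < self.f2:
            raise ValueError(f"region band must satisfy f1 < f2, got [{self.f1}, {self.f2}]")


def parzen_window(lags: np.ndarray, max_lag: int) -> np.ndarray:
    """Parzen lag window w(tau), supported on |tau| <= max_lag."""
    a = np.abs(np.asarray(lags, float)) / max_lag
    w = np.zeros_like(a)
    m1 = a <= 0.5
    m2 = (a > 0.5) & (a <= 1.0)
    w[m1] = 1 - 6 * a[m1] ** 2 + 6 * a[m1] ** 3
    w[m2] = 2 * (1 - a[m2]) ** 3
    return w


def _third_order_cumulant(records: np.ndarray, L: int) -> np.ndarray:
    """Record-averaged biased cumulant c3 on the lag square [-L, L]^2.

    Rows tau1 = 0..L come from FFT cross-correlation of
    z_a[n] = x[n] x[n+a] with x; tau1 < 0 follows from the stationarity
    symmetry c3(-a, b) = c3(a, b + a), which holds exactly for the biased
    estimator.
    """
    from scipy import fft as sfft

    nrec, reclen = records.shape
    nfft_c = sfft.next_fast_len(reclen + 2 * L, real=True)
    rec32 = records.astype(np.float32)
    Z = np.zeros((nrec, L + 1, reclen), dtype=np.float32)
    for a in range(L + 1):
        Z[:, a, : reclen - a] = rec32[:, : reclen - a] * rec32[:, a:]
    ZF = sfft.rfft(Z, nfft_c, axis=2)
    XF = sfft.rfft(rec32, nfft_c, axis=1)
    corr = sfft.irfft(np.conj(ZF) * XF[:, None, :], nfft_c, axis=2).mean(axis=0, dtype=np.float64)
    lags = np.arange(-2 * L, 2 * L + 1)
    half = corr[:, lags % nfft_c]  # rows a = 0..L, cols b = -2L..2L
    c3 = np.empty((2 * L + 1, 2 * L + 1))
    c3[L:, :] = half[:, L : 3 * L + 1]
    for a in range(1, L + 1):
        c3[L - a, :] = half[a, L + a : 3 * L + 1 + a]
    c3 = 0.5 * (c3 + c3.T)  # enforce the swap symmetry exactly
    return c3 / reclen


def _decimation_factor(fs: float) -> int:
    q = 1
    while fs / (q + 1) >= TARGET_FS:
        q += 1
    return q


def estimate_bispectrum(
    signal: BreathPhaseSignal,
    max_lag: int = DEFAULT_MAX_LAG,
    nfft: int = DEFAULT_NFFT,
    reclen: int = DEFAULT_RECLEN,
) -> BispectrumGrid:
    """Indirect-method bispectrum magnitude of one breath-phase signal."""
    if nfft < 2 * max_lag:
        raise ValueError("nfft must be >= 2 * max_lag")
    q = _decimation_factor(signal.fs)
    x = sps.decimate(signal.samples, q, zero_phase=True) if q > 1 else np.asarray(signal.samples, float)
    fs = signal.fs / q
    if x.size < 4 * max_lag:
        raise ValueError(
            f"signal too short: {x.size} samples at {fs:.0f} Hz; need >= {4 * max_lag} (max_lag < length/4)"
        )
    x = x - x.mean()
    rl = min(reclen, x.size)
    nrec = x.size // rl
    records = x[: nrec * rl].reshape(nrec, rl)
    records = records - records.mean(axis=1, keepdims=True)
    c3 = _third_order_cumulant(records, max_lag)

    tau = np.arange(-max_lag, max_lag + 1)
    T1, T2 = np.meshgrid(tau, tau, indexing="ij")
    W = parzen_window(T1, max_lag) * parzen_window(T2, max_lag) * parzen_window(T1 - T2, max_lag)
    A = np.zeros((nfft, nfft))
    np.add.at(A, (T1.ravel() % nfft, T2.ravel() % nfft), (c3 * W).ravel())
    B = np.fft.fft2(A)
    half = nfft // 2
    freqs = np.arange(half + 1) * fs / nfft
    return BispectrumGrid(
        freqs=freqs,
        mag=np.abs(B[: half + 1, : half + 1]),
        maneuver=signal.maneuver,
        subject_id=signal.subject_id,
    )


def mean_bispectrum(signals: Iterable[BreathPhaseSignal], **kwargs) -> BispectrumGrid:
    """Per-subject, per-maneuver grid: mean of the per-breath |B| grids."""
    grids = [estimate_bispectrum(s, **kwargs) for s in signals]
    if not grids:
        raise ValueError("no signals to average")
    if len({g.maneuver for g in grids}) > 1:
        raise ValueError("signals mix maneuvers; average one maneuver at a time")
    return BispectrumGrid(
        freqs=grids[0].freqs,
        mag=np.mean([g.mag for g in grids], axis=0),
        maneuver=grids[0].maneuver,
        subject_id=grids[0].subject_id,
    )


def extract_region(grid: BispectrumGrid, region: BispectralRegion) -> tuple[np.ndarray, np.ndarray]:
    """Weighted sample set of a bifrequency region.

    Returns ``(coords, weights)`` where ``coords`` has shape (n, 2); for the
    1-D region kinds the first column is the line parameter f.  Weights are
    |B| at the nearest grid node.
    """
    df = grid.df
    fmax = grid.freqs[-1]
    f1, f2 = region.f1, region.f2
    if f2 > fmax and region.kind != "line_2f_f":
        raise ValueError(f"region [{f1}, {f2}] exceeds grid maximum {fmax} Hz")
    f = grid.freqs[(grid.freqs >= f1) & (grid.freqs <= f2)]
    if region.kind == "square":
        if f.size == 0:
            raise ValueError(f"empty square region [{f1}, {f2}]")
        A, Bf = np.meshgrid(f, f, indexing="ij")
        coords = np.column_stack([A.ravel(), Bf.ravel()])
    elif region.kind == "positive_diagonal":
        coords = np.column_stack([f, f])
    elif region.kind == "negative_diagonal":
        coords = np.column_stack([f, f1 + f2 - f])
    elif region.kind == "line_2f_f":
        f = f[2 * f <= fmax]
        coords = np.column_stack([f, 2 * f])
    elif region.kind == "line_half_f_f":
        # keep f whose half also lies on the grid
        on_grid = np.isclose((f / 2) % df, 0.0) | np.isclose((f / 2) % df, df)
        f = f[on_grid]
        coords = np.column_stack([f, f / 2])
    else:  # pragma: no cover - guarded by the Literal type
        raise ValueError(f"unknown region kind {region.kind!r}")
    if coords.shape[0] == 0:
        raise ValueError(f"empty region {region.kind} over [{f1}, {f2}]")
    weights = grid.nearest(coords[:, 0], coords[:, 1])
    return coords, weights


def region_stat(coords: np.ndarray, weights: np.ndarray, stat: StatKind, kind: RegionKind = "square") -> float:
    """A summary statistic of a weighted bifrequency sample set.

    With normalized weights p_i = w_i / sum(w):

    * ``mean``            — sum(w)/n (0 for an all-zero region);
    * ``geometric_mean``  — exp(mean(ln(w + eps))), eps = 1e-12 max(w);
    * ``entropy``         — -sum(p ln p);
    * ``weight_center``   — weighted median of the line parameter for 1-D
      regions; for 2-D regions the average of the two weighted centroid
      coordinates;
    * ``moment1``         — weighted mean of the line parameter;
    * ``moment2``         — weighted variance of the line parameter about
      its weighted mean.
    """
    w = np.asarray(weights, float)
    coords = np.asarray(coords, float)
    if w.size == 0:
        raise ValueError("empty sample set")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if stat == "mean":
        return float(total / w.size)
    if stat == "geometric_mean":
        eps = 1e-12 * (w.max() if w.max() > 0 else 1.0)
        return float(np.exp(np.mean(np.log(w + eps))))
    if total == 0:
        raise ValueError(f"all-zero weights: {stat} undefined")
    p = w / total
    if stat == "entropy":
        nz = p[p > 0]
        return float(-np.sum(nz * np.log(nz)))
    if stat == "weight_center":
        if kind in _LINE_KINDS:
            # interpolated weighted median along the line parameter: mass
            # centered at each node, piecewise-linear CDF inverted at 0.5
            order = np.argsort(coords[:, 0], kind="stable")
            fo = coords[order, 0]
            centers = np.cumsum(p[order]) - p[order] / 2.0
            if 0.5 <= centers[0]:
                return float(fo[0])
            if 0.5 >= centers[-1]:
                return float(fo[-1])
            return float(np.interp(0.5, centers, fo))
        c1 = float(np.sum(coords[:, 0] * p))
        c2 = float(np.sum(coords[:, 1] * p))
        return (c1 + c2) / 2.0
    f = coords[:, 0]
    m1 = float(np.sum(f * p))
    if stat == "moment1":
        return m1
    if stat == "moment2":
        return float(np.sum((f - m1) ** 2 * p))
    raise ValueError(f"unknown stat {stat!r}")


def higuchi_fd(signal: BreathPhaseSignal | np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension of a sampled waveform.

    Computes the mean normalized curve length L(k) over decimation steps
    k = 1..kmax and returns the negative slope of ln L(k) vs ln k.  The
    result is clipped to [1, 2], the attainable range for sampled real
    signals.
    """
    x = signal.samples if isinstance(signal, BreathPhaseSignal) else np.asarray(signal, float)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    n = x.size
    if n < 10 * kmax:
        raise ValueError(f"signal of {n} samples too short for kmax={kmax}")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: fractal dimension undefined")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (k * (idx.size - 1))
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    slope = np.polyfit(np.log(np.arange(1, kmax + 1)), np.log(lk), 1)[0]
    return float(np.clip(-slope, 1.0, 2.0))
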