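"""Diagnostic plots: group-average spectra with confidence bands and
gap-versus-threshold scans."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from somnoscreen.cohort_prep import ThresholdScan, _group_ci
from somnoscreen.spectral import ANALYSIS_BAND, PowerSpectrum, to_db


def plot_group_spectra(
    spectra: Mapping[str, Mapping[str, PowerSpectrum]],
    below_ids: Sequence[str],
    above_ids: Sequence[str],
    maneuver: str,
    ax=None,
):
    """Mean dB spectra of the two severity groups with 95% confidence bands."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for ids, color, label in ((below_ids, "tab:blue", "below threshold"), (above_ids, "tab:red", "above threshold")):
        rows = [spectra[s][maneuver] for s in ids if maneuver in spectra.get(s, {})]
        if len(rows) < 2:
            continue
        idx = rows[0].band_indices(*ANALYSIS_BAND)
        freqs = rows[0].freqs[idx]
        mean, lo, hi = _group_ci(np.array([to_db(r.power)[idx] for r in rows]))
        ax.plot(freqs, mean, color=color, label=f"{label} (n={len(rows)})")
        ax.plot(freqs, lo, color=color, ls=":", lw=0.8)
        ax.plot(freqs, hi, color=color, ls=":", lw=0.8)
    ax.set_xlabel("Frequency (Hz)")
    ax.set_ylabel("Power (dB, normalized)")
    ax.set_title(f"Group-average spectrum, {maneuver}")
    ax.legend()
    return ax


def plot_gap_scan(scan: ThresholdScan, min_group: int = 20, ax=None):
    """Spectral-gap score versus candidate threshold; ineligible candidates
    (either group below the minimum size) are greyed out."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ok = scan.eligible(min_group)
    ax.plot(scan.candidates, scan.gap, "-", color="0.7", zorder=1)
    ax.scatter(scan.candidates[ok], scan.gap[ok], color="tab:green", label="eligible", zorder=2)
    ax.scatter(scan.candidates[~ok], scan.gap[~ok], color="0.6", marker="x", label=f"group < {min_group}", zorder=2)
    if np.isfinite(scan.selected):
        ax.axvline(scan.selected, color="tab:red", ls="--", label=f"selected ({scan.selection_reason})")
    ax.set_xlabel(f"Candidate threshold ({scan.scaling}-scaled values)")
    ax.set_ylabel("Average CI gap (dB)")
    ax.set_title(scan.psg_name)
    ax.legend()
    return ax
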