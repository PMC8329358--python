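"""Per-segment power spectra and alpha-band (8–12 Hz) area under the curve.

A 2-s epoch at 250 Hz yields a 0.5 Hz frequency grid, so the band edges
8.0 and 12.0 Hz fall exactly on grid points.  Spectra are single-taper Hann
periodograms normalised as one-sided densities (µV²/Hz) with the window
power compensated, so the integral over [0, Nyquist] equals the signal's
mean square (Parseval-consistent).  Band power is the trapezoidal integral
over [8, 12] Hz, endpoints included.  Per subject × electrode × condition
the per-segment AUCs are averaged over non-rejected segments and the
natural log is taken of the mean (log after average).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from efaa.preprocess import EMOTIONS, RELEVANCES, SegmentSet

ALPHA_BAND = (8.0, 12.0)

#: floor applied to band AUC before taking logs, guards ln(0) on degenerate input
POWER_FLOOR = 1e-12


@dataclass
class PowerSpectrum:
    freqs: np.ndarray          # Hz, [0, Nyquist], uniform grid
    density: np.ndarray        # µV²/Hz, channels × freqs (or 1-D)


def power_spectrum(samples: np.ndarray, rate: float) -> PowerSpectrum:
    """Hann-tapered one-sided periodogram of one epoch.

    ``samples`` may be 1-D (one channel) or channels × time.
    """
    samples = np.asarray(samples, dtype=np.float64)
    n = samples.shape[-1]
    if n < 2:
        raise ValueError("epoch too short for a spectrum")
    freqs, pxx = signal.periodogram(
        samples, fs=rate, window="hann", detrend=False, scaling="density",
        axis=-1,
    )
    return PowerSpectrum(freqs=freqs, density=pxx)


def band_auc(spec: PowerSpectrum, lo: float = ALPHA_BAND[0],
             hi: float = ALPHA_BAND[1]) -> np.ndarray | float:
    """Trapezoidal integral of the density over [lo, hi], endpoints included."""
    f = spec.freqs
    if lo > hi or lo < f[0] or hi > f[-1]:
        raise ValueError(f"band ({lo}, {hi}) outside grid [{f[0]}, {f[-1]}]")
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return np.zeros(spec.density.shape[:-1]) if spec.density.ndim > 1 else 0.0
    return np.trapezoid(spec.density[..., mask], f[mask], axis=-1)


def segment_band_power(segs: SegmentSet, electrodes: tuple[str, ...] = ("F3", "F4"),
                       band: tuple[float, float] = ALPHA_BAND) -> pd.DataFrame:
    """Per-segment band AUC for the requested electrodes.

    Returns one row per non-rejected segment with columns
    (emotion, relevance, response, <electrode> ...).
    """
    idx = [segs.channels.index(e) for e in electrodes]
    rows = []
    for s in segs.kept():
        spec = power_spectrum(s.data[idx], segs.sfreq)
        auc = band_auc(spec, *band)
        rows.append((*s.condition, *np.atleast_1d(auc)))
    return pd.DataFrame(rows, columns=["emotion", "relevance", "response",
                                       *electrodes])


def condition_alpha_table(
    segs_by_subject: dict[str, SegmentSet],
    electrodes: tuple[str, ...] = ("F3", "F4"),
    band: tuple[float, float] = ALPHA_BAND,
    pool_response: bool = True,
    min_segments: int = 10,
) -> pd.DataFrame:
    """Subject × electrode × condition mean alpha AUC and its natural log.

    ``pool_response`` collapses go/nogo before averaging (the asymmetry
    analysis has only Emotion and Relevance factors).  Cells with fewer than
    ``min_segments`` contributing segments are marked missing; subjects with
    any missing Emotion × Relevance cell are reported by
    :func:`incomplete_subjects` and excluded from ANOVA input downstream.

    Returns a long table: subject, electrode, emotion, relevance, auc,
    ln_auc, n_segments.
    """
    rows = []
    group_cols = ["emotion", "relevance"] if pool_response else \
        ["emotion", "relevance", "response"]
    for subject, segs in segs_by_subject.items():
        per_seg = segment_band_power(segs, electrodes, band)
        for cond, chunk in per_seg.groupby(group_cols, sort=True):
            for e in electrodes:
                n = len(chunk)
                auc = float(chunk[e].mean()) if n else np.nan
                if n < min_segments:
                    auc = np.nan
                ln = np.log(max(auc, POWER_FLOOR)) if np.isfinite(auc) else np.nan
                rows.append((subject, e, *cond, auc, ln, n))
    cols = ["subject", "electrode", *group_cols, "auc", "ln_auc", "n_segments"]
    return pd.DataFrame(rows, columns=cols)


def incomplete_subjects(table: pd.DataFrame) -> list[str]:
    """Subjects missing any of the four Emotion × Relevance cells on any
    electrode (either absent rows or NaN AUC)."""
    bad = []
    n_cells = len(EMOTIONS) * len(RELEVANCES)
    for subject, chunk in table.groupby("subject"):
        for _, echunk in chunk.groupby("electrode"):
            if len(echunk) < n_cells or echunk["auc"].isna().any():
                bad.append(subject)
                break
    return sorted(bad)
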