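"""Spectrograms, baseline-normalized power spectra, and band-power summaries.

Power estimates use Hann-windowed 4 s segments with 50 % overlap, which at a
1000 Hz sampling rate yields the 0.25 Hz frequency resolution of the study
pipeline.  Epoch spectra are normalized by the pre-flurothyl baseline
spectrum and expressed as a dimensionless power ratio (1 = at baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import BANDS, Epoch, SUMMARY_BANDS, TimeSeries
from .errors import InsufficientDataError, ParameterError

#: Bins inside this interval are excluded from band means: the 60 Hz
#: acquisition notch makes them untrustworthy.
NOTCH_EXCLUDE = (59.5, 60.5)


@dataclass
class Spectrogram:
    freqs: np.ndarray   # Hz, 0.25 Hz spacing
    times: np.ndarray   # s, window centers
    power: np.ndarray   # (freq, time), µV²/Hz


@dataclass
class NormalizedSpectrum:
    freqs: np.ndarray
    ratio: np.ndarray   # epoch PSD / baseline PSD
    epoch_kind: str = ""


def compute_spectrogram(ts: TimeSeries, window_s: float = 4.0,
                        overlap: float = 0.5) -> Spectrogram:
    """Short-time Hann-windowed power spectrogram (one-sided density)."""
    if ts.duration < window_s:
        raise InsufficientDataError(
            f"need >= {window_s} s of data, have {ts.duration:.2f} s")
    nperseg = int(round(window_s * ts.rate))
    noverlap = int(round(overlap * nperseg))
    f, t, p = sps.spectrogram(ts.samples, fs=ts.rate, window="hann",
                              nperseg=nperseg, noverlap=noverlap,
                              scaling="density", mode="psd")
    return Spectrogram(freqs=f, times=t + ts.t0, power=p)


def compute_psd(ts: TimeSeries, epoch: Epoch, window_s: float = 4.0):
    """Welch PSD of the epoch: 4 s Hann segments, 50 % overlap.

    Returns ``(freqs, psd)`` with 0.25 Hz bin spacing at 1000 Hz.
    """
    if epoch.duration < window_s:
        raise InsufficientDataError(
            f"epoch {epoch.kind!r} shorter than one {window_s} s segment")
    seg = ts.slice(epoch.start, epoch.end)
    nperseg = int(round(window_s * ts.rate))
    f, psd = sps.welch(seg.samples, fs=ts.rate, window="hann",
                       nperseg=nperseg, noverlap=nperseg // 2,
                       scaling="density")
    return f, psd


def normalize_psd(epoch_psd, baseline_psd, freqs=None,
                  epoch_kind: str = "") -> NormalizedSpectrum:
    """Elementwise epoch/baseline power ratio on a shared frequency grid."""
    epoch_psd = np.asarray(epoch_psd, dtype=float)
    baseline_psd = np.asarray(baseline_psd, dtype=float)
    if epoch_psd.shape != baseline_psd.shape:
        raise ParameterError("epoch and baseline PSDs are on different grids")
    if freqs is None:
        freqs = np.arange(epoch_psd.size, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != epoch_psd.shape:
        raise ParameterError("frequency grid does not match PSD shape")
    keep = baseline_psd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} bins with zero baseline power",
                      stacklevel=2)
    return NormalizedSpectrum(freqs=freqs[keep],
                              ratio=epoch_psd[keep] / baseline_psd[keep],
                              epoch_kind=epoch_kind)


def band_power(nspec: NormalizedSpectrum, bands=SUMMARY_BANDS,
               exclude_notch: bool = True) -> pd.DataFrame:
    """Mean normalized power per canonical band.

    Bins inside :data:`NOTCH_EXCLUDE` are skipped when ``exclude_notch``.
    """
    rows = []
    for name in bands:
        band = BANDS[name] if isinstance(name, str) else name
        mask = (nspec.freqs >= band.lo) & (nspec.freqs <= band.hi)
        if exclude_notch:
            mask &= ~((nspec.freqs >= NOTCH_EXCLUDE[0]) & (nspec.freqs <= NOTCH_EXCLUDE[1]))
        if not mask.any():
            raise ParameterError(f"band {band.name!r} lies outside the frequency grid")
        rows.append({"band": band.name, "mean_ratio": float(nspec.ratio[mask].mean())})
    return pd.DataFrame(rows)


def broadband_ratio(nspec: NormalizedSpectrum, lo: float = 1.0,
                    hi: float = 60.0, exclude_notch: bool = True) -> float:
    """Mean normalized power over [lo, hi] Hz (default 1–60 Hz)."""
    mask = (nspec.freqs >= lo) & (nspec.freqs <= hi)
    if exclude_notch:
        mask &= ~((nspec.freqs >= NOTCH_EXCLUDE[0]) & (nspec.freqs <= NOTCH_EXCLUDE[1]))
    if not mask.any():
        raise ParameterError("no bins inside the requested range")
    return float(nspec.ratio[mask].mean())
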