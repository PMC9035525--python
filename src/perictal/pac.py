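"""Time-resolved phase-amplitude coupling (tPAC) and comodulograms.

The coupling between a slow rhythm's phase (fP, 0.5–30 Hz) and a fast
rhythm's amplitude (fA, 30–200 Hz) is estimated per sliding 4 s window as a
mean-centered, amplitude-normalized mean vector length:

    PAC = | <(a - a̅) · e^{iφ}> | / <a>

with φ the Hilbert phase of the fP-filtered signal and a the Hilbert
envelope of the fA-filtered signal.  Centering the envelope removes the
spurious contribution of the (generally non-zero) window mean of e^{iφ};
normalizing by the mean envelope makes the estimate invariant to amplitude
rescaling and bounded in [0, 1].  For a noiseless sinusoidal modulation
a(t) = A(1 + m cos φ) the estimate equals m/2, so it is linear in the
modulation depth m.  Windowed values are averaged over the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .core import Epoch, FrequencyBand, TimeSeries
from .errors import InsufficientDataError, ParameterError

#: Comodulogram boxes (fP lo, fP hi, fA lo, fA hi) for the delta:gamma summaries.
DELTA_LOW_GAMMA_BOX = (0.5, 4.0, 30.0, 70.0)
DELTA_HIGH_GAMMA_BOX = (0.5, 4.0, 80.0, 200.0)


def analytic(x: np.ndarray) -> np.ndarray:
    """Hilbert analytic signal, padded to a fast FFT length."""
    n = x.size
    nf = next_fast_len(n)
    return sps.hilbert(x, N=nf)[:n]


def _narrowband(x: np.ndarray, rate: float, lo: float, hi: float, order: int = 3):
    nyq = rate / 2.0
    hi = min(hi, nyq * 0.99)
    if not 0 < lo < hi:
        raise ParameterError(f"invalid band ({lo}, {hi}) at rate {rate}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def _window_index(n: int, rate: float, window_s: float, step_s: float) -> np.ndarray:
    """(W, L) integer index matrix of full windows inside an n-sample segment."""
    L = int(round(window_s * rate))
    step = int(round(step_s * rate))
    if n < L:
        raise InsufficientDataError("segment shorter than one PAC window")
    starts = np.arange(0, n - L + 1, step)
    return starts[:, None] + np.arange(L)[None, :]


def _coupling_vectors(env: np.ndarray, phasor: np.ndarray, idx: np.ndarray):
    """Per-window complex coupling vector <(a-ā)e^{iφ}> and mean envelope ā."""
    a = env[idx]
    e = phasor[idx]
    abar = a.mean(axis=1)
    num = (a * e).mean(axis=1) - abar * e.mean(axis=1)
    return num, abar


def _pac_per_window(env: np.ndarray, phasor: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """PAC value per window from envelope and unit phasor e^{iφ}."""
    num, abar = _coupling_vectors(env, phasor, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        pac = np.where(abar > 0, np.abs(num) / abar, 0.0)
    return np.clip(pac, 0.0, 1.0)


def _pac_epoch(env: np.ndarray, phasor: np.ndarray, idx: np.ndarray) -> float:
    """Epoch-level PAC: coupling vectors averaged *coherently* over windows.

    Because the envelope-phase relationship keeps a fixed preferred phase
    throughout an epoch, averaging the complex per-window vectors before
    taking the magnitude suppresses the stochastic-envelope noise floor by
    ~1/sqrt(n_windows), while per-window magnitudes (the time-resolved
    view) retain a floor that no amount of averaging removes.
    """
    num, abar = _coupling_vectors(env, phasor, idx)
    denom = abar.mean()
    if denom <= 0:
        return 0.0
    return float(np.clip(np.abs(num.mean()) / denom, 0.0, 1.0))


def tpac(ts: TimeSeries, fP, fA, window_s: float = 4.0, step_s: float = 2.0,
         epoch: Epoch | None = None):
    """Time-resolved PAC between phase band fP and amplitude band fA.

    Returns ``(window_center_times, pac_values)``.  The amplitude band must
    satisfy the modulation-sideband admissibility rule ``fA.lo > 2*fP.hi``
    so the fA filter can pass the modulation sidebands without leaking the
    phase rhythm itself.
    """
    fP = fP if isinstance(fP, FrequencyBand) else FrequencyBand("fP", *fP)
    fA = fA if isinstance(fA, FrequencyBand) else FrequencyBand("fA", *fA)
    if fA.lo <= 2 * fP.hi:
        raise ParameterError(
            f"amplitude band low edge {fA.lo} Hz must exceed twice the phase "
            f"band high edge (2*{fP.hi} Hz): sideband admissibility")
    seg = ts.slice(epoch.start, epoch.end) if epoch is not None else ts
    phasor = np.exp(1j * np.angle(analytic(_narrowband(seg.samples, seg.rate, fP.lo, fP.hi))))
    env = np.abs(analytic(_narrowband(seg.samples, seg.rate, fA.lo, fA.hi)))
    idx = _window_index(seg.n, seg.rate, window_s, step_s)
    pac = _pac_per_window(env, phasor, idx)
    centers = seg.t0 + (idx[:, 0] + idx.shape[1] / 2) / seg.rate
    return centers, pac


@dataclass
class Comodulogram:
    fP_grid: np.ndarray   # Hz, phase-band centers
    fA_grid: np.ndarray   # Hz, amplitude-band centers
    strength: np.ndarray  # (fP, fA) PAC values in [0, 1]

    def box_mean(self, box) -> float:
        """Mean strength over cells whose centers fall in (fPlo, fPhi, fAlo, fAhi)."""
        fplo, fphi, falo, fahi = box
        pm = (self.fP_grid >= fplo) & (self.fP_grid <= fphi)
        am = (self.fA_grid >= falo) & (self.fA_grid <= fahi)
        if not (pm.any() and am.any()):
            raise ParameterError("box lies outside the comodulogram grid")
        return float(self.strength[np.ix_(pm, am)].mean())


@dataclass
class PacSummary:
    region: str
    outcome: str
    delta_low_gamma: float
    delta_high_gamma: float


def comodulogram(ts: TimeSeries, epoch: Epoch, fP_range=(0.5, 30.0),
                 fA_range=(30.0, 200.0), fP_step: float = 1.0,
                 fA_step: float = 5.0, window_s: float = 4.0,
                 step_s: float = 2.0) -> Comodulogram:
    """PAC strength over an (fP, fA) grid, averaged over epoch windows.

    Phase bins are 2 Hz wide (center ±1 Hz, floored at 0.5 Hz); amplitude
    bins are ``max(10 Hz, 2*fP.hi + 2 Hz)`` wide so the modulation sidebands
    of the slowest admissible rhythm fit inside the passband.  Envelope
    filters are cached per distinct (center, bandwidth) pair, which makes
    the delta-row boxes cheap.
    """
    if epoch.duration < 2 * window_s:
        raise InsufficientDataError("epoch must cover at least two PAC windows")
    seg = ts.slice(epoch.start, epoch.end)
    idx = _window_index(seg.n, seg.rate, window_s, step_s)

    fP_centers = np.arange(max(1.0, fP_range[0] + 0.5), fP_range[1] + 1e-9, fP_step)
    fA_centers = np.arange(fA_range[0] + fA_step / 2, fA_range[1], fA_step)
    strength = np.zeros((fP_centers.size, fA_centers.size))

    env_cache: dict[tuple, np.ndarray] = {}
    for i, cp in enumerate(fP_centers):
        lo, hi = max(0.5, cp - 1.0), cp + 1.0
        phasor = np.exp(1j * np.angle(analytic(_narrowband(seg.samples, seg.rate, lo, hi))))
        bw = max(10.0, 2 * hi + 2.0)
        for j, ca in enumerate(fA_centers):
            key = (round(ca, 3), round(bw, 3))
            if key not in env_cache:
                env_cache[key] = np.abs(analytic(
                    _narrowband(seg.samples, seg.rate, max(ca - bw / 2, hi + 1.0), ca + bw / 2)))
            strength[i, j] = _pac_epoch(env_cache[key], phasor, idx)
    return Comodulogram(fP_grid=fP_centers, fA_grid=fA_centers, strength=strength)


def delta_gamma_boxes(ts: TimeSeries, epoch: Epoch, **kwargs) -> tuple[float, float]:
    """(delta/low-gamma, delta/high-gamma) box means from a delta-row comodulogram."""
    comod = comodulogram(ts, epoch, fP_range=(0.5, 4.0), fA_range=(30.0, 200.0), **kwargs)
    return (comod.box_mean(DELTA_LOW_GAMMA_BOX), comod.box_mean(DELTA_HIGH_GAMMA_BOX))


def pac_summary(comod: Comodulogram, region: str, outcome: str) -> PacSummary:
    """Delta:low-gamma and delta:high-gamma box means of a comodulogram."""
    return PacSummary(
        region=region, outcome=outcome,
        delta_low_gamma=comod.box_mean(DELTA_LOW_GAMMA_BOX),
        delta_high_gamma=comod.box_mean(DELTA_HIGH_GAMMA_BOX),
    )
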