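"""Domain types, filtering, seizure detection and peri-ictal epoch segmentation.

The recording model is a freely-moving mouse undergoing a flurothyl-induced
generalized seizure: two LFP channels (primary motor cortex M1 and dorsal
raphe DR of the brainstem, 1000 Hz) and one ECG channel (2000 Hz), with event
markers for flurothyl infusion start, generalized-seizure (GS) onset,
convulsion end, and — for non-survivors — time of death.  All times are in
seconds on the recording clock; epochs are half-open intervals ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)

SURVIVOR = "survivor"
NON_SURVIVOR = "non_survivor"


@dataclass
class TimeSeries:
    """Uniformly sampled signal.

    Parameters
    ----------
    samples : array-like
        Signal values (µV for LFP, mV for ECG).
    rate : float
        Sampling rate in samples/second.
    t0 : float
        Time of the first sample on the recording clock, seconds.
    label : str
        Channel name (e.g. ``"M1"``, ``"DR"``, ``"ECG"``).
    units : str
        Physical unit of the samples.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not self.rate > 0:
            raise ValidationError(f"rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"channel {self.label!r} contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def index_of(self, t: float) -> int:
        return int(round((t - self.t0) * self.rate))

    def slice(self, start: float, end: float) -> "TimeSeries":
        """Return the sub-series covering the half-open interval [start, end)."""
        i0 = max(self.index_of(start), 0)
        i1 = min(self.index_of(end), self.n)
        if i1 <= i0:
            raise ParameterError(f"empty slice [{start}, {end}) for channel {self.label!r}")
        return TimeSeries(
            self.samples[i0:i1], self.rate, t0=self.t0 + i0 / self.rate,
            label=self.label, units=self.units,
        )

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return TimeSeries(samples, self.rate, t0=self.t0, label=self.label, units=self.units)


@dataclass
class EventMarkers:
    """Seizure event markers, seconds on the recording clock."""

    flurothyl_start: float
    gs_onset: float
    convulsion_end: float
    death_time: Optional[float] = None

    def __post_init__(self):
        if not (self.flurothyl_start < self.gs_onset < self.convulsion_end):
            raise ValidationError(
                "marker ordering must satisfy flurothyl_start < gs_onset < convulsion_end; "
                f"got {self.flurothyl_start}, {self.gs_onset}, {self.convulsion_end}"
            )
        if self.death_time is not None and self.death_time < self.gs_onset:
            raise ValidationError("death_time must be >= gs_onset")


@dataclass
class Epoch:
    """Analysis epoch, half-open interval [start, end)."""

    kind: str  # baseline | ictal | postictal
    start: float
    end: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValidationError(f"epoch end must exceed start: [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class FrequencyBand:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValidationError(f"band {self.name!r} requires 0 < lo < hi")


#: Canonical band table.  ``gamma`` (30–60 Hz) is the band used for power /
#: PLV / GC summaries; ``low_gamma`` / ``high_gamma`` are the comodulogram
#: amplitude boxes.
BANDS = {
    "delta": FrequencyBand("delta", 0.5, 4.0),
    "theta": FrequencyBand("theta", 5.0, 8.0),
    "alpha": FrequencyBand("alpha", 9.0, 12.0),
    "beta": FrequencyBand("beta", 13.0, 29.0),
    "gamma": FrequencyBand("gamma", 30.0, 60.0),
    "low_gamma": FrequencyBand("low_gamma", 30.0, 70.0),
    "high_gamma": FrequencyBand("high_gamma", 80.0, 200.0),
}

#: The five bands used for band-averaged power, PLV and GC summaries.
SUMMARY_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass
class SeizureRecording:
    """Paired M1/DR LFP + ECG + markers + outcome for one animal."""

    m1: TimeSeries
    dr: TimeSeries
    ecg: TimeSeries
    markers: EventMarkers
    outcome: str
    animal_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.outcome not in (SURVIVOR, NON_SURVIVOR):
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        has_death = self.markers.death_time is not None
        if has_death != (self.outcome == NON_SURVIVOR):
            raise ValidationError(
                "outcome must be non_survivor iff death_time is present "
                f"(outcome={self.outcome!r}, death_time={self.markers.death_time})"
            )

    @property
    def duration(self) -> float:
        return min(self.m1.duration, self.dr.duration, self.ecg.duration)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _check_edges(edges, rate):
    nyq = rate / 2.0
    for e in np.atleast_1d(edges):
        if not (0 < e < nyq):
            raise ParameterError(f"filter edge {e} Hz outside (0, Nyquist={nyq} Hz)")


def filter_signal(ts: TimeSeries, kind: str, edges) -> TimeSeries:
    """Zero-phase filter a signal.

    ``kind`` is one of ``highpass`` / ``lowpass`` / ``bandpass`` / ``notch``.
    High/low/bandpass are 4th-order Butterworth applied forward-backward
    (`sosfiltfilt`); the notch is a Q=30 IIR notch applied with `filtfilt`.
    Zero-phase filtering preserves the phase relationships that the coupling
    analyses depend on.
    """
    edges = np.atleast_1d(np.asarray(edges, dtype=float))
    _check_edges(edges, ts.rate)
    if kind == "notch":
        b, a = sps.iirnotch(edges[0], Q=30.0, fs=ts.rate)
        out = sps.filtfilt(b, a, ts.samples)
        return ts.with_samples(out)
    if kind in ("highpass", "lowpass"):
        if edges.size != 1:
            raise ParameterError(f"{kind} expects one edge, got {edges.size}")
        sos = sps.butter(4, edges[0], btype=kind, fs=ts.rate, output="sos")
    elif kind == "bandpass":
        if edges.size != 2 or not edges[0] < edges[1]:
            raise ParameterError("bandpass expects two increasing edges")
        sos = sps.butter(4, edges, btype="bandpass", fs=ts.rate, output="sos")
    else:
        raise ParameterError(f"unknown filter kind {kind!r}")
    return ts.with_samples(sps.sosfiltfilt(sos, ts.samples))


# ---------------------------------------------------------------------------
# Generalized-seizure detection
# ---------------------------------------------------------------------------

def _sliding_rms(x: np.ndarray, rate: float, window_s: float, step_s: float):
    """RMS in sliding windows; returns (window start times relative to x[0], rms)."""
    win = int(round(window_s * rate))
    step = int(round(step_s * rate))
    if x.size < win:
        raise InsufficientDataError("signal shorter than one RMS window")
    csum = np.concatenate([[0.0], np.cumsum(x.astype(np.float64) ** 2)])
    starts = np.arange(0, x.size - win + 1, step)
    rms = np.sqrt((csum[starts + win] - csum[starts]) / win)
    return starts / rate, rms


def detect_generalized_seizure(
    lfp: TimeSeries,
    baseline: Epoch,
    min_duration_s: float = 5.0,
    amp_factor: float = 2.0,
    window_s: float = 1.0,
    step_s: float = 0.25,
) -> Optional[float]:
    """Detect generalized-seizure onset by the amplitude criterion.

    A generalized seizure is scored when the sliding-window RMS (1 s window,
    0.25 s hop) stays at or above ``amp_factor`` times the baseline RMS
    continuously for more than ``min_duration_s`` (the >5 s, 2x-baseline
    electrographic criterion).  Returns the earliest qualifying time, or
    ``None`` when the criterion is never met.
    """
    if baseline.duration < 30.0:
        raise InsufficientDataError("baseline epoch must provide >= 30 s of data")
    base = lfp.slice(baseline.start, baseline.end)
    base_rms = float(np.sqrt(np.mean(base.samples**2)))
    if base_rms == 0.0:
        raise DegenerateInputError("baseline RMS is zero")
    t_rel, rms = _sliding_rms(lfp.samples, lfp.rate, window_s, step_s)
    above = rms >= amp_factor * base_rms
    need = int(np.ceil(min_duration_s / step_s)) + 1  # strictly > min_duration_s
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            onset_idx = i - run + 1
            return float(lfp.t0 + t_rel[onset_idx])
    return None


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------

def segment_epochs(
    recording: SeizureRecording,
    baseline_target_s: float = 100.0,
    postictal_s: float = 10.0,
) -> dict:
    """Segment a recording into baseline / ictal / postictal epochs.

    Baseline is the final ``baseline_target_s`` seconds before flurothyl
    infusion start (shorter accepted with a warning, minimum 30 s); ictal is
    [GS onset, convulsion end); postictal is the ``postictal_s`` seconds
    anchored at convulsion end for survivors or at death for non-survivors.
    """
    mk = recording.markers
    t0 = recording.m1.t0
    pre = mk.flurothyl_start - t0
    if pre < 30.0:
        raise InsufficientDataError(
            f"only {pre:.1f} s of pre-flurothyl data; >= 30 s required"
        )
    if pre < baseline_target_s:
        warnings.warn(
            f"baseline shortened to {pre:.1f} s (target {baseline_target_s:.0f} s)",
            stacklevel=2,
        )
    base_len = min(baseline_target_s, pre)
    baseline = Epoch("baseline", mk.flurothyl_start - base_len, mk.flurothyl_start)
    ictal = Epoch("ictal", mk.gs_onset, mk.convulsion_end)
    anchor = mk.death_time if recording.outcome == NON_SURVIVOR else mk.convulsion_end
    postictal = Epoch("postictal", anchor, anchor + postictal_s)
    return {"baseline": baseline, "ictal": ictal, "postictal": postictal}
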