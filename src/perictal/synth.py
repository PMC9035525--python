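"""Synthetic survivor / non-survivor seizure cohorts.

Each synthetic animal is a :class:`~perictal.core.SeizureRecording` whose
spectral, cross-frequency, cross-regional and cardiac structure is
programmable.  LFP channels are built from 1/f background noise plus
narrowband oscillators (delta, theta, alpha, beta, low/high gamma):

* amplitudes follow a stage plan (baseline → flurothyl pre-ictal → ictal
  × ``ictal_gain`` → postictal), with per-band ictal suppression of the
  brainstem channel in non-survivors (strongest in beta);
* gamma carriers are amplitude-modulated by the region's delta phase with
  programmable depth m (delta:gamma phase-amplitude coupling);
* the two regions' delta components share a common source with mixing
  fraction ρ (delta phase synchrony), elevated ictally in non-survivors;
* directed cortex–brainstem coupling is injected as lagged, band-limited
  copies of the source region's oscillators, with gains expressed relative
  to the *target* channel's in-band amplitude so that coupling strength is
  not confounded by the brainstem suppression;
* at death all LFP activity collapses to a 5 % noise floor.

ECG is a train of P-QRS-T templates at stage-programmed heart rates
(ictal tachycardia in non-survivors, post-mortem bradycardia decaying to
asystole 2–7 min later), with RR jitter scaled to a target SDNN.

Between-animal variability is injected as mean-preserving lognormal or
Gaussian jitter on amplitudes, coupling gains, modulation depths and heart
rates, so the statistics layer sees cohorts rather than replicas.
Generation is a pure function of the configuration (bit-identical output
for identical config and seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage, signal as sps

from .core import (
    NON_SURVIVOR,
    SURVIVOR,
    EventMarkers,
    SeizureRecording,
    TimeSeries,
)
from .errors import CalibrationError, ParameterError

LFP_RATE = 1000.0
ECG_RATE = 2000.0

_BAND_EDGES = {
    # the delta component stops at 3.5 Hz so its filter skirt does not
    # leak shared-source energy into the 5-8 Hz theta analysis bins
    "delta": (0.5, 3.5),
    "theta": (5.0, 8.0),
    "alpha": (9.0, 12.0),
    "beta": (13.0, 29.0),
    "low_gamma": (30.0, 70.0),
    "high_gamma": (80.0, 200.0),
}

#: Injection band -> generator component carrying it.
_GC_COMPONENT = {"alpha": "alpha", "beta": "beta", "gamma": "low_gamma"}

#: Sub-band used as the injected waveform (kept away from neighbouring
#: analysis bands so the finite-order VAR does not smear coupling across
#: band boundaries).  None = use the component as-is.
_GC_INJECTION_SUBBAND = {"alpha": None, "beta": (17.0, 29.0), "gamma": (32.0, 68.0)}


def _default_band_rms():
    return {"delta": 25.0, "theta": 10.0, "alpha": 8.0, "beta": 7.0,
            "low_gamma": 8.0, "high_gamma": 6.0}


def _default_dr_suppression():
    # amplitude multipliers; squared in power, minimum at beta
    return {"delta": 0.75, "theta": 0.65, "alpha": 0.60, "beta": 0.45,
            "low_gamma": 0.60, "high_gamma": 0.60}


def _default_pac_m():
    # cortical delta:gamma coupling reduced in non-survivors by 43.0 %
    # (low gamma) and 32.3 % (high gamma); brainstem depth equal by outcome
    return {
        "m1": {
            "low_gamma": {SURVIVOR: 0.6, NON_SURVIVOR: 0.6 * (1 - 0.430)},
            "high_gamma": {SURVIVOR: 0.6, NON_SURVIVOR: 0.6 * (1 - 0.323)},
        },
        "dr": {
            "low_gamma": {SURVIVOR: 0.4, NON_SURVIVOR: 0.4},
            "high_gamma": {SURVIVOR: 0.4, NON_SURVIVOR: 0.4},
        },
    }


def _default_gc_base_gain():
    # alpha is larger to dilute the delta-spillover fold; beta/gamma are
    # small so the target folds need little injected coherence (keeping
    # narrowband PLV differences below detectability)
    return {"dr_to_m1": {"alpha": 0.08, "beta": 0.04, "gamma": 0.04},
            "m1_to_dr": {"alpha": 0.08, "beta": 0.04, "gamma": 0.04}}


def _default_gc_ictal_gain():
    # Survivor ictal gains stay at base; non-survivor gains below were frozen
    # from scripts/calibrate_defaults.py so that the analysis pipeline
    # recovers fold increases of 2.8 (alpha), 3.8 (beta), 3.3 (gamma) in the
    # DR->M1 direction and 2.6 (gamma) M1->DR on default cohorts.
    return {
        SURVIVOR: {"dr_to_m1": {"alpha": 0.08, "beta": 0.04, "gamma": 0.04},
                   "m1_to_dr": {"alpha": 0.08, "beta": 0.04, "gamma": 0.04}},
        NON_SURVIVOR: {"dr_to_m1": {"alpha": 0.0799, "beta": 0.1513, "gamma": 0.1047},
                       "m1_to_dr": {"alpha": 0.08, "beta": 0.04, "gamma": 0.1082}},
    }


@dataclass
class LfpParams:
    """Parameters of the two-channel LFP generator (amplitudes in µV)."""

    background_exponent: float = 1.0      # 1/f^χ background
    background_rms: float = 10.0
    band_rms: dict = field(default_factory=_default_band_rms)
    ictal_gain: float = 3.0               # satisfies the >= 2x GS criterion
    preictal_gain: float = 1.2
    postictal_gain: float = 0.8
    dr_suppression: dict = field(default_factory=_default_dr_suppression)
    dr_background_suppression: float = 0.6  # ictal DR 1/f background, non-survivors
    pac_m: dict = field(default_factory=_default_pac_m)
    delta_sync_baseline: float = 0.2
    delta_sync_ictal: dict = field(
        default_factory=lambda: {SURVIVOR: 0.35, NON_SURVIVOR: 0.50})
    gc_base_gain: dict = field(default_factory=_default_gc_base_gain)
    gc_ictal_gain: dict = field(default_factory=_default_gc_ictal_gain)
    gc_lag_ms: dict = field(
        default_factory=lambda: {"dr_to_m1": 12.0, "m1_to_dr": 18.0})
    death_floor: float = 0.05             # fraction of baseline RMS after death
    amp_jitter: float = 0.15              # lognormal sigma, band amplitudes
    m_jitter: float = 0.04                # gaussian sigma, modulation depths
    rho_jitter: float = 0.03              # gaussian sigma, delta mixing
    gain_jitter: float = 0.30             # lognormal sigma, coupling gains

    def __post_init__(self):
        for region in self.pac_m.values():
            for sub in region.values():
                for m in sub.values():
                    if not 0.0 <= m <= 1.0:
                        raise ParameterError(f"modulation depth {m} outside [0, 1]")
        for rho in [self.delta_sync_baseline, *self.delta_sync_ictal.values()]:
            if not 0.0 <= rho <= 1.0:
                raise ParameterError(f"delta mixing fraction {rho} outside [0, 1]")
        for mult in self.dr_suppression.values():
            if mult <= 0:
                raise ParameterError("suppression multipliers must be > 0")


@dataclass
class EcgParams:
    """Stage heart-rate plan and waveform parameters (rates in b.p.m.)."""

    baseline_hr: float = 600.0
    ictal_hr: dict = field(default_factory=lambda: {SURVIVOR: 553.0,
                                                    NON_SURVIVOR: 725.0})
    postictal_hr: dict = field(default_factory=lambda: {SURVIVOR: 600.0,
                                                        NON_SURVIVOR: 181.0})
    sdnn_ms: float = 5.0
    asystole_delay_range_s: tuple = (120.0, 420.0)   # ~2–7 min after death
    death_amp_floor: float = 0.25                    # terminal beat amplitude
    hr_jitter_bpm: float = 25.0                      # between-animal SD
    noise_mv: float = 0.02
    r_amp_mv: float = 1.0

    def __post_init__(self):
        rates = [self.baseline_hr, *self.ictal_hr.values(),
                 *self.postictal_hr.values()]
        for r in rates:
            if not 60.0 < r < 1500.0:
                raise ParameterError(f"heart rate {r} b.p.m. outside (60, 1500)")
        lo, hi = self.asystole_delay_range_s
        if not (120.0 <= lo <= hi <= 420.0):
            raise ParameterError("asystole delay range must lie within [120, 420] s")


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic cohort."""

    n_survivor: int = 7
    n_non_survivor: int = 5
    seed: int = 0
    baseline_s: float = 200.0
    preictal_s: float = 60.0
    ictal_s: float = 40.0
    postictal_s: float = 120.0
    death_offset_s: float = 2.0
    lfp: LfpParams = field(default_factory=LfpParams)
    ecg: EcgParams = field(default_factory=EcgParams)

    def __post_init__(self):
        if self.n_survivor < 1 or self.n_non_survivor < 1:
            raise ParameterError("group sizes must be >= 1")
        for d in (self.baseline_s, self.preictal_s, self.ictal_s, self.postictal_s):
            if d <= 0:
                raise ParameterError("all durations must be > 0")

    def markers(self, outcome: str) -> EventMarkers:
        flu = self.baseline_s
        gs = flu + self.preictal_s
        end = gs + self.ictal_s
        death = end + self.death_offset_s if outcome == NON_SURVIVOR else None
        return EventMarkers(flu, gs, end, death)

    @property
    def total_s(self) -> float:
        return float(int(np.ceil(self.baseline_s + self.preictal_s + self.ictal_s
                                 + self.death_offset_s + self.postictal_s)))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _smooth(env: np.ndarray, fs: float, tau_s: float = 0.5) -> np.ndarray:
    size = max(int(tau_s * fs / 2), 1)
    return ndimage.uniform_filter1d(
        ndimage.uniform_filter1d(env, size=size, mode="nearest"),
        size=size, mode="nearest")


def _band_noise(rng, n, fs, lo, hi):
    """Unit-RMS bandlimited Gaussian noise."""
    sos = sps.butter(2, [lo, min(hi, fs / 2 * 0.99)], btype="bandpass",
                     fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / max(x.std(), 1e-12)


def _pink_noise(rng, n, fs, chi):
    """Unit-RMS 1/f^χ background (flat below 0.3 Hz, zero DC)."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = np.maximum(freqs[nz], 0.3) ** (-chi / 2.0)
    spec = amp * (rng.standard_normal(freqs.size)
                  + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / max(x.std(), 1e-12)


def _analytic_phase(x: np.ndarray) -> np.ndarray:
    from .pac import analytic
    return np.angle(analytic(x))


def _lognormal_factor(rng, sigma):
    """Mean-preserving multiplicative jitter."""
    if sigma <= 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, sigma) - sigma**2 / 2))


# ---------------------------------------------------------------------------
# LFP pair
# ---------------------------------------------------------------------------

def generate_lfp_pair(params: LfpParams, config: CohortConfig, outcome: str,
                      seed) -> tuple[TimeSeries, TimeSeries]:
    """Generate the (M1, DR) LFP pair for one animal."""
    if outcome not in (SURVIVOR, NON_SURVIVOR):
        raise ParameterError(f"unknown outcome {outcome!r}")
    rng = _rng(seed)
    fs = LFP_RATE
    mk = config.markers(outcome)
    n = int(config.total_s * fs)
    t_idx = np.arange(n)
    i_flu, i_gs = int(mk.flurothyl_start * fs), int(mk.gs_onset * fs)
    i_end = int(mk.convulsion_end * fs)
    i_death = int(mk.death_time * fs) if mk.death_time is not None else None

    # --- per-animal jitter draws (order fixed for determinism) ------------
    bands = list(_BAND_EDGES)
    amp_fac = {r: {b: _lognormal_factor(rng, params.amp_jitter) for b in bands}
               for r in ("m1", "dr")}
    bg_fac = {r: _lognormal_factor(rng, params.amp_jitter) for r in ("m1", "dr")}
    m_val = {r: {sb: float(np.clip(
        params.pac_m[r][sb][outcome] + rng.normal(0, params.m_jitter), 0.0, 1.0))
        for sb in ("low_gamma", "high_gamma")} for r in ("m1", "dr")}
    rho_ict = float(np.clip(params.delta_sync_ictal[outcome]
                            + rng.normal(0, params.rho_jitter), 0.0, 0.98))
    gain_fac = {d: {b: _lognormal_factor(rng, params.gain_jitter)
                    for b in params.gc_base_gain[d]}
                for d in ("dr_to_m1", "m1_to_dr")}

    # --- stage envelopes --------------------------------------------------
    gain_env = np.ones(n)
    gain_env[i_flu:i_gs] = params.preictal_gain
    gain_env[i_gs:i_end] = params.ictal_gain
    gain_env[i_end:] = params.postictal_gain
    gain_env = _smooth(gain_env, fs)

    supp_env = {}
    for b in bands + ["bg"]:
        e = np.ones(n)
        if outcome == NON_SURVIVOR:
            e[i_gs:i_end] = params.dr_suppression[b] if b in bands \
                else params.dr_background_suppression
            e = _smooth(e, fs)
        supp_env[b] = e

    w = np.full(n, params.delta_sync_baseline)
    w[i_gs:i_end] = rho_ict
    w = _smooth(w, fs)

    # --- unit waveforms ---------------------------------------------------
    shared_delta = _band_noise(rng, n, fs, *_BAND_EDGES["delta"])
    units = {}
    for region in ("m1", "dr"):
        own_delta = _band_noise(rng, n, fs, *_BAND_EDGES["delta"])
        delta = (w * shared_delta + (1 - w) * own_delta) \
            / np.sqrt(w**2 + (1 - w) ** 2)
        phi = _analytic_phase(delta)
        u = {"delta": delta}
        for b in ("theta", "alpha", "beta"):
            u[b] = _band_noise(rng, n, fs, *_BAND_EDGES[b])
        for sb in ("low_gamma", "high_gamma"):
            carrier = _band_noise(rng, n, fs, *_BAND_EDGES[sb])
            m = m_val[region][sb]
            u[sb] = carrier * (1 + m * np.cos(phi)) / np.sqrt(1 + m**2 / 2)
        u["bg"] = _pink_noise(rng, n, fs, params.background_exponent)
        units[region] = u

    # --- amplitudes and own signals --------------------------------------
    amp = {r: {} for r in ("m1", "dr")}
    for region in ("m1", "dr"):
        for b in bands:
            a = params.band_rms[b] * amp_fac[region][b] * gain_env
            if region == "dr":
                a = a * supp_env[b]
            amp[region][b] = a
    own = {}
    for region in ("m1", "dr"):
        sig = params.background_rms * bg_fac[region] * gain_env * units[region]["bg"]
        if region == "dr":
            sig = sig * supp_env["bg"]
        for b in bands:
            sig = sig + amp[region][b] * units[region][b]
        own[region] = sig

    # --- directed injections ----------------------------------------------
    ict_gain = params.gc_ictal_gain[outcome]
    inj = {"m1": 0.0, "dr": 0.0}
    for direction, (src, dst) in (("dr_to_m1", ("dr", "m1")),
                                  ("m1_to_dr", ("m1", "dr"))):
        lag = int(round(params.gc_lag_ms[direction] * fs / 1000.0))
        for band, base_g in params.gc_base_gain[direction].items():
            g = np.full(n, base_g)
            g[i_gs:i_end] = ict_gain[direction][band]
            g = _smooth(g, fs) * gain_fac[direction][band]
            comp = _GC_COMPONENT[band]
            wave = units[src][comp]
            sub = _GC_INJECTION_SUBBAND[band]
            if sub is not None:
                sos = sps.butter(2, sub, btype="bandpass", fs=fs, output="sos")
                wave = sps.sosfiltfilt(sos, wave)
                wave = wave / max(wave.std(), 1e-12)
            shifted = np.concatenate([np.zeros(lag), wave[:n - lag]])
            inj[dst] = inj[dst] + g * amp[dst][comp] * shifted

    m1 = own["m1"] + inj["m1"]
    dr = own["dr"] + inj["dr"]

    # --- death: terminal cessation of cerebral activity -------------------
    if i_death is not None:
        mask = np.ones(n)
        mask[i_death:] = 0.0
        mask = _smooth(mask, fs, tau_s=0.2)
        base_rms = {
            r: float(np.sqrt(
                sum((params.band_rms[b] * amp_fac[r][b]) ** 2 for b in bands)
                + (params.background_rms * bg_fac[r]) ** 2))
            for r in ("m1", "dr")}
        floor_m1 = params.death_floor * base_rms["m1"] * rng.standard_normal(n)
        floor_dr = params.death_floor * base_rms["dr"] * rng.standard_normal(n)
        m1 = m1 * mask + floor_m1 * (1 - mask)
        dr = dr * mask + floor_dr * (1 - mask)

    return (TimeSeries(m1, fs, label="M1", units="uV"),
            TimeSeries(dr, fs, label="DR", units="uV"))


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def _pqrst_template(fs: float, r_amp: float = 1.0):
    """Murine P-QRS-T template; returns (samples, index of the R peak)."""
    t = np.arange(-0.030, 0.050, 1 / fs)
    wave = (0.12 * np.exp(-((t + 0.020) ** 2) / (2 * 0.004**2))       # P
            - 0.15 * np.exp(-((t + 0.0045) ** 2) / (2 * 0.001**2))    # Q
            + 1.00 * np.exp(-(t**2) / (2 * 0.0015**2))                # R
            - 0.30 * np.exp(-((t - 0.004) ** 2) / (2 * 0.0015**2))    # S
            + 0.20 * np.exp(-((t - 0.025) ** 2) / (2 * 0.008**2)))    # T
    return r_amp * wave, int(np.argmin(np.abs(t)))


def generate_ecg(params: EcgParams, config: CohortConfig, outcome: str,
                 seed) -> TimeSeries:
    """Generate one animal's ECG channel (mV, 2000 Hz)."""
    if outcome not in (SURVIVOR, NON_SURVIVOR):
        raise ParameterError(f"unknown outcome {outcome!r}")
    rng = _rng(seed)
    fs = ECG_RATE
    mk = config.markers(outcome)
    total = config.total_s
    n = int(total * fs)

    jit = rng.normal(0.0, params.hr_jitter_bpm, size=3)
    hr_base = params.baseline_hr + jit[0]
    hr_ictal = params.ictal_hr[outcome] + jit[1]
    hr_post = params.postictal_hr[outcome] + jit[2]
    for hr in (hr_base, hr_ictal, hr_post):
        if 60000.0 / hr < 45.0:
            raise ParameterError(
                f"heart rate {hr:.0f} b.p.m. implies RR shorter than the beat template")

    death = mk.death_time
    asystole = None
    if outcome == NON_SURVIVOR:
        lo, hi = params.asystole_delay_range_s
        asystole = death + rng.uniform(lo, hi)

    def stage_hr(t):
        if t < mk.gs_onset:
            return hr_base
        if outcome == SURVIVOR:
            return hr_ictal if t < mk.convulsion_end else hr_post
        return hr_ictal if t < death else hr_post

    beats, amps = [], []
    t = -0.2
    while t < total:
        if asystole is not None and t >= asystole:
            break
        rr_ms = 60000.0 / stage_hr(t) + rng.normal(0.0, params.sdnn_ms)
        rr_ms = max(rr_ms, 45.0)
        t = t + rr_ms / 1000.0
        if t >= total:
            break
        amp = 1.0
        if asystole is not None and t >= death:
            frac = (t - death) / (asystole - death)
            amp = 1.0 + (params.death_amp_floor - 1.0) * frac
        beats.append(t)
        amps.append(amp)

    template, r_idx = _pqrst_template(fs, params.r_amp_mv)
    sig = rng.normal(0.0, params.noise_mv, size=n)
    L = template.size
    for tb, amp in zip(beats, amps):
        i = int(round(tb * fs)) - r_idx
        lo, hi = max(i, 0), min(i + L, n)
        if hi > lo:
            sig[lo:hi] += amp * template[lo - i:hi - i]
    return TimeSeries(sig, fs, label="ECG", units="mV")


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_recording(config: CohortConfig, outcome: str, seed,
                       animal_id: str = "") -> SeizureRecording:
    """Generate one animal; ``seed`` may be an int or a SeedSequence."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    lfp_ss, ecg_ss = ss.spawn(2)
    m1, dr = generate_lfp_pair(config.lfp, config, outcome,
                               np.random.default_rng(lfp_ss))
    ecg = generate_ecg(config.ecg, config, outcome, np.random.default_rng(ecg_ss))
    return SeizureRecording(m1=m1, dr=dr, ecg=ecg, markers=config.markers(outcome),
                            outcome=outcome, animal_id=animal_id or outcome[:1],
                            meta={"seed": repr(ss.entropy)})


def generate_cohort(config: CohortConfig) -> list[SeizureRecording]:
    """Generate the full cohort; per-animal sub-seeds derive from config.seed."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_survivor + config.n_non_survivor)
    cohort = []
    for i in range(config.n_survivor):
        cohort.append(generate_recording(config, SURVIVOR, children[i],
                                         animal_id=f"S{i + 1:02d}"))
    for j in range(config.n_non_survivor):
        cohort.append(generate_recording(config, NON_SURVIVOR,
                                         children[config.n_survivor + j],
                                         animal_id=f"N{j + 1:02d}"))
    return cohort


# ---------------------------------------------------------------------------
# GC gain calibration
# ---------------------------------------------------------------------------

def _measure_band_gc(config: CohortConfig, outcome: str, seeds) -> dict:
    """Group-mean ictal band GC per (direction, band) over per-animal fits."""
    from .connectivity import FREQ_GRID, band_mean, fit_var, gc_spectrum
    from .core import segment_epochs

    acc = {}
    for s in seeds:
        rec = generate_recording(config, outcome, np.random.SeedSequence(s))
        ep = segment_epochs(rec)
        model = fit_var(rec.m1, rec.dr, ep["ictal"])
        gc_dr_m1, gc_m1_dr = gc_spectrum(model)
        for band in ("alpha", "beta", "gamma"):
            acc.setdefault(("dr_to_m1", band), []).append(
                band_mean(FREQ_GRID, gc_dr_m1, band))
            acc.setdefault(("m1_to_dr", band), []).append(
                band_mean(FREQ_GRID, gc_m1_dr, band))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def calibrate_gc_coupling(targets: dict, base_params: Optional[LfpParams] = None,
                          tolerance: float = 0.15, seed: int = 0,
                          n_recordings: int = 4, max_iter: int = 9,
                          config: Optional[CohortConfig] = None) -> dict:
    """Calibrate non-survivor ictal coupling gains to GC fold-change targets.

    ``targets`` maps ``(direction, band)`` to the desired non-survivor /
    survivor band-mean GC ratio.  The survivor reference and every candidate
    non-survivor cohort are generated from *common random numbers* (identical
    sub-seeds), making the measured fold a smooth, monotone function of the
    gain, solved by bisection in log-gain.  Returns a nested
    ``direction -> band -> gain`` mapping; raises :class:`CalibrationError`
    with the best achieved ratios on non-convergence.
    """
    base_params = base_params if base_params is not None else LfpParams()
    cfg = config if config is not None else CohortConfig()
    cfg = replace(cfg, lfp=copy.deepcopy(base_params))
    seeds = [int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
             for k in range(n_recordings)]

    ref = _measure_band_gc(cfg, SURVIVOR, seeds)
    gains = copy.deepcopy(cfg.lfp.gc_ictal_gain[NON_SURVIVOR])
    best = {}
    for (direction, band), fold in targets.items():
        if fold <= 0:
            raise ParameterError("fold targets must be positive")
        base_g = cfg.lfp.gc_base_gain[direction][band]

        def measured_ratio(g):
            trial = copy.deepcopy(cfg)
            trial.lfp.gc_ictal_gain[NON_SURVIVOR] = copy.deepcopy(gains)
            trial.lfp.gc_ictal_gain[NON_SURVIVOR][direction][band] = g
            got = _measure_band_gc(trial, NON_SURVIVOR, seeds)
            return got[(direction, band)] / ref[(direction, band)]

        lo, hi = np.log(base_g * 0.3), np.log(base_g * 10.0)
        g = base_g * np.sqrt(fold)
        ratio = measured_ratio(g)
        it = 0
        while abs(ratio / fold - 1.0) > tolerance and it < max_iter:
            if ratio < fold:
                lo = np.log(g)
            else:
                hi = np.log(g)
            g = float(np.exp((lo + hi) / 2))
            ratio = measured_ratio(g)
            it += 1
        best[(direction, band)] = ratio
        if abs(ratio / fold - 1.0) > tolerance:
            raise CalibrationError(
                f"calibration for {direction}/{band} did not reach fold {fold} "
                f"(best ratio {ratio:.2f})", best=best)
        gains[direction][band] = float(g)
    return gains
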