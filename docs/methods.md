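# Methods

`perictal` re-implements, as a tested pipeline, the peri-ictal analyses that
distinguish fatal from non-fatal generalized seizures in a two-region
LFP + ECG mouse preparation: baseline-normalized spectral power,
time-resolved delta:gamma phase-amplitude coupling (PAC), cortex–brainstem
phase locking (PLV) and spectral Granger causality (GC), and cardiac
rate/variability metrics.  Because the original animal recordings are not
publicly deposited, verification is closed-loop: a synthetic cohort
generator is parameterized with the published group effect sizes, and the
analysis modules must recover those effects from generated raw signals.

## Recording model and epochs

A recording holds two LFP channels (M1 motor cortex and DR dorsal raphe,
1000 Hz, µV) plus one ECG channel (2000 Hz, mV) and event markers
(flurothyl infusion start, generalized-seizure onset, convulsion end, and —
for non-survivors — time of death).  Time is seconds on the recording
clock; all epochs are half-open `[start, end)`:

* **baseline** — the final ~100 s before flurothyl infusion (shorter
  accepted to a 30 s minimum, with a warning);
* **ictal** — generalized-seizure onset to convulsion end;
* **postictal** — 10 s anchored at convulsion end (survivors) or at death
  (non-survivors).

The electrographic generalized-seizure criterion — continuous activity
longer than 5 s with amplitude at least twice baseline — is implemented as
a sliding-window RMS detector (1 s window, 0.25 s hop) against the baseline
RMS.  RMS is the standard amplitude proxy; the window/hop resolve the
\>5 s rule with 0.25 s granularity.

Acquisition-style filtering (0.3 Hz high-pass, 60 Hz notch, 200 Hz
low-pass) is zero-phase: 4th-order Butterworth applied forward–backward,
and a Q=30 IIR notch.  Zero-phase filtering is essential because the
coupling analyses downstream are phase-based.

## Spectral power

Spectrograms and Welch spectra use 4 s Hann windows with 50 % overlap,
giving the 0.25 Hz bin size at 1000 Hz.  Epoch spectra are divided by the
baseline spectrum bin-wise and reported as a dimensionless power ratio
(1 = at baseline); band summaries average the ratio over delta (0.5–4 Hz),
theta (5–8), alpha (9–12), beta (13–29) and gamma (30–60).  The 59.5–60.5 Hz
bins are excluded from band means because the acquisition notch makes them
untrustworthy.

## Phase-amplitude coupling

For a phase band fP and amplitude band fA, each channel is zero-phase
bandpass filtered at both bands; φ(t) is the Hilbert phase of the fP
signal and a(t) the Hilbert envelope of the fA signal.  Within a sliding
4 s window (2 s step) the coupling estimate is the mean-centered,
amplitude-normalized mean vector length

    PAC = | ⟨(a − ā) e^{iφ}⟩ | / ⟨a⟩ .

Centering removes the spurious contribution of the non-zero window mean of
e^{iφ} (a 4 s window holds only ~8 delta cycles); normalizing by ⟨a⟩ makes
the estimate scale-invariant and bounded in [0, 1].  For a noiseless
sinusoidal modulation a = A(1 + m cos φ) the estimate equals m/2 — linear
in the modulation depth, which is what makes the percent-reduction
recovery unbiased.  Epoch-level values (comodulogram cells, box means)
average the *complex* per-window coupling vectors before taking the
magnitude: the envelope–phase relationship holds a fixed preferred phase
within an epoch, so coherent averaging suppresses the stochastic-envelope
null floor by ~1/√(windows), whereas the time-resolved view (per-window
magnitudes) retains an irreducible floor.  Comodulograms cover fP 0.5–30 Hz
(1 Hz steps, 2 Hz-wide bins) × fA 30–200 Hz (5 Hz steps, bin bandwidth
max(10 Hz, 2·fP_hi + 2 Hz) so the modulation sidebands fit the passband);
the delta:low-gamma (fP 0.5–4 × fA 30–70) and delta:high-gamma (fA 80–200)
box means are the coupling-strength summaries.  The standalone `tpac`
operation enforces the sideband admissibility rule fA_lo > 2·fP_hi.

## Connectivity

PLV and GC are computed over 0.5–60 Hz in 1 Hz bins (the lowest bin spans
0.5–1.5 Hz).  Both channels are anti-alias decimated to 200 Hz first:
1000 Hz VAR models of 0.5–60 Hz content would need impractical orders,
while 200 Hz leaves 40 Hz of headroom above the 60 Hz ceiling.

**PLV.**  Per bin, both channels are filtered to the 1 Hz band, Hilbert
phases extracted, and |⟨e^{i(φx−φy)}⟩| evaluated in sliding 4 s windows
(50 % overlap) and averaged — the single-trial, time-resolved variant
appropriate for one continuous ictal epoch.  Windowed PLV has a higher
null floor than a whole-epoch estimate (~0.3–0.4 at these bandwidths);
group comparisons are unaffected since the floor is common to all animals.

**GC.**  A bivariate VAR is fitted by least squares on de-meaned,
variance-normalized data with BIC order selection up to order 20
(stability enforced; channel scaling does not affect GC).  The Geweke
frequency-domain measures follow from the transfer function H(f) and
innovation covariance Σ:

    GC_{y→x}(f) = ln [ S_xx(f) / (S_xx(f) − (Σ_yy − Σ²_xy/Σ_xx) |H_xy(f)|²) ]

with S = H Σ H*.  Non-positive denominators (numerical) are clamped to
zero with a warning.  Band means over the canonical five bands summarize
both directions.

## Cardiac metrics

R peaks are detected with a simplified Pan–Tompkins chain adapted to mouse
rates: 10–100 Hz bandpass, squared derivative, adaptive threshold at 0.4 of
the rolling 2 s maximum (with a global floor), local-maximum refinement on
the raw trace within ±10 ms, 40 ms refractory (supports >1000 b.p.m.).
When an epoch is requested, detection runs on the whole trace — so
thresholds adapt on real beats — and peaks are filtered to the epoch.
Instant heart rate is 60000/RR per beat, interpolated to a 10 Hz grid and
smoothed with a 1 s moving average; epoch means skip the first second of
the epoch so the smoother does not drag pre-epoch rate across a rate
discontinuity (seizure onset, death).  HRV metrics (SDNN with the n−1
estimator, CV = 100·SDNN/mean RR, RMSSD) use at most the first 1200
intervals of an epoch, mirroring the ~1000–1200-beat windows conventional
for murine HRV.  QT correction uses the rodent formula
QTc = QT/(RR/100)^½ (RR in ms); QT delineation is manual input, not
computed.

## Statistics

Shapiro–Wilk (α = 0.05, every group) gates two-group comparisons between
the unpaired two-tailed t-test and the Mann–Whitney U test (exact
distribution for groups of ≤ 8 without ties).  Factorial comparisons use
fixed-effects ANOVA with type-II sums of squares — the designs here are
near-balanced, making the SS type low-impact — with Šídák
(1 − (1 − p)^m) or Tukey post hoc adjustment.  Summaries are reported as
mean ± SEM with n.

## The synthetic cohort generator

Each LFP channel is a sum of unit-RMS narrowband oscillators (delta,
theta, alpha, beta, low gamma 30–70, high gamma 80–200; bandpassed white
noise) plus 1/f background, with a stage envelope (baseline 1×, infusion
1.2×, ictal 3× — comfortably above the 2× detection criterion — postictal
0.8×).  Programmable structure:

* **Brainstem suppression.**  In non-survivors, DR amplitudes are
  multiplied during the ictal span by per-band factors (0.75 delta, 0.65
  theta, 0.60 alpha, 0.45 beta, 0.60 gamma; background 0.6) — power
  suppression across 1–60 Hz with the minimum at beta.  The magnitudes are
  free parameters (only their ordering and significance are constrained by
  the study design).  The background is suppressed along with the
  oscillators so that amplitude-normalized PAC in DR is not confounded by
  a change in the in-band signal-to-background ratio.
* **PAC.**  Gamma carriers are modulated as (1 + m cos φ_δ)/√(1 + m²/2)
  by the region's delta phase.  Cortex: m = 0.6 in survivors, reduced by
  43.0 % (low gamma) and 32.3 % (high gamma) in non-survivors; brainstem:
  m = 0.4 in both outcomes.  The √(1+m²/2) normalization keeps gamma power
  independent of m.
* **Delta synchrony.**  Each region's delta is w·(shared source) +
  (1−w)·(independent), renormalized; w = 0.2 at baseline for both
  outcomes, and ictally 0.35 (survivors) vs 0.50 (non-survivors).  Keeping
  baseline w common is what makes the baseline-connectivity null hold.
  The delta component itself spans 0.5–3.5 Hz so that its filter skirt
  does not leak shared-source energy into the theta PLV bins.
* **Directed coupling.**  Lagged (12 ms DR→M1, 18 ms M1→DR), band-limited
  copies of the source region's oscillators are added to the target, with
  gains expressed relative to the *target's* in-band amplitude, decoupling
  injected coherence from the DR suppression.  The beta and gamma
  injections use interior sub-bands (17–29, 32–68 Hz) so the finite-order
  VAR does not smear coupling across band boundaries.  Baseline gains are
  0.08 (alpha) and 0.04 (beta, gamma) in both directions — alpha larger to
  dilute the delta-spillover fold, beta/gamma small so the fold targets
  need little injected coherence and narrowband PLV stays group-neutral;
  non-survivor ictal gains were calibrated
  (`scripts/calibrate_defaults.py`) so the analysis pipeline recovers the
  target GC folds.  A sizable part of the measured non-survivor GC
  elevation is contributed by the shared ictal delta source, which a
  finite-order VAR redistributes across the spectrum; the calibration
  absorbs this, and it usefully decouples the GC folds from narrowband PLV
  (which is immune to that redistribution).
* **Death.**  At the marked death time all LFP collapses to white noise at
  5 % of the baseline RMS (filters and spectra stay well-conditioned).
* **ECG.**  Beats are P-QRS-T Gaussian templates placed at cumulative RR
  times; RR per stage is 60000/HR plus Gaussian jitter scaled to the
  target SDNN (5 ms default).  Stage heart rates: baseline 600 b.p.m.
  (no printed value exists; 600 is a standard conscious-mouse rate), ictal
  553 (survivors) vs 725 (non-survivors), postictal 600 vs 181; after
  death the rate drops to 181 b.p.m. with amplitude decaying linearly to
  asystole at a uniform 120–420 s after death.
* **Between-animal variability.**  Mean-preserving lognormal jitter on
  band amplitudes (σ = 0.15) and coupling gains (σ = 0.30), Gaussian
  jitter on modulation depths (0.04), delta mixing (0.03) and stage heart
  rates (25 b.p.m.).  Without it the statistics layer would declare every
  microscopic difference significant; with it, cohorts behave like small
  animal groups.  The heart-rate SD is deliberately smaller than the
  biological spread implied by the printed SEMs (~130 b.p.m.), so that a
  single 7+5 cohort recovers the printed group means within one SEM —
  the recovery checks are about the pipeline, not about re-simulating
  biological variance.

Cohort generation is a pure function of the configuration: per-animal
sub-seeds spawn deterministically from the cohort seed, and identical
configurations yield bit-identical signals.

### What the generator does not emulate

No biophysical seizure dynamics (no neural-mass model), no respiration
channel, no movement or electrode artifacts, no non-stationarity within
stages beyond the programmed envelopes, and between-animal variability is
reduced relative to real cohorts (above).  Passing recovery tests
therefore demonstrates that the analysis pipeline measures what it claims
to measure at realistic signal-to-noise — not that it is robust to every
artifact of in-vivo recordings.

## Calibration of the coupling gains

`calibrate_gc_coupling` solves, per (direction, band), for the
non-survivor ictal gain whose *measured* group-mean GC fold matches a
target, using bisection in log-gain.  Candidate and reference cohorts are
generated with common random numbers, making the measured fold a smooth,
nearly deterministic function of the gain.  The shipped defaults were
frozen by `scripts/calibrate_defaults.py`, which adds a refinement stage on
a 12-cohort replication (the injected part of a fold scales ≈ gain² above
the gain-independent delta-spillover part) and verifies on an independent
replication.  Per-seed fold estimates are noisy (SD ≈ 0.5–1.2 depending on
band) because the survivor-side denominator is a small GC value; the
recovery criteria therefore average folds over 20 seed-cohorts.

## Numerical choices and degenerate inputs

EDF(+) I/O is 16-bit against ±2000 µV (LFP) / ±5 mV (ECG) physical ranges,
1 s records, markers in a tab-separated sidecar.  Constant or zero-power
inputs raise typed errors (degenerate baseline RMS, rank-deficient VAR);
flatline ECG returns an empty R-peak series with a warning rather than an
error.  Zero-baseline spectral bins are dropped from normalized spectra
with a warning.  PAC values are clipped to [0, 1]; GC denominators that go
non-positive numerically are clamped to zero causality with a warning.
All analyses are deterministic given their inputs; all randomness lives in
the generator and is seed-derived.

## Problem sizes

Default cohorts are 7 survivors + 5 non-survivors, ~420 s per animal
(200 s baseline, 60 s infusion, 40 s ictal, 120 s postictal).  Replication
suites use 20 seed-cohorts; unit tests use shortened stage plans (30–60 s)
that preserve the full analysis structure.

## Known limitations

* The VAR order cap (20 at 200 Hz = 100 ms memory) cannot fully represent
  the narrowband delta process; a strongly shared delta source therefore
  produces broadband GC elevation ("spillover").  The generator keeps the
  ictal delta-synchrony contrast moderate (0.35 vs 0.50) so per-band gain
  calibration retains headroom, and the calibration absorbs the residual.
* GC fold estimates are ratio statistics with small denominators; single
  cohorts give noisy folds (SD up to ~1), and only multi-seed means are
  meaningful.
* The PLV null floor of the windowed estimator (~0.3) compresses group
  differences at low coherence; this is deliberate (single-trial data) and
  common to both groups.
* QT intervals are taken as given; there is no waveform QT delineation.
* The comodulogram's cell bandwidth rule trims modulation sidebands near
  cell edges, attenuating absolute PAC by a band-dependent factor; group
  ratios are largely unaffected, but residual background dilution in the
  high-gamma cells compresses the recovered delta:high-gamma percent
  reduction by ~5–8 points relative to the programmed value (within the
  recovery tolerance).  Absolute PAC values are estimator-specific.
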