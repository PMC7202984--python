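# Methods

## Overview

`circosc` analyses slow oscillations (10–1,000 s periods) in beat-to-beat
cardiovascular variables derived from raw ECG and invasive arterial
pressure. Because no patient recordings are distributed with the package,
a synthetic generator with a ground-truth ledger provides the recordings on
which the pipeline is exercised and validated. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## Synthetic recordings

**Beat placement.** The instantaneous heart rate is
HR(t) = HR₀ + Σ modulations + respiration (bpm). The cardiac phase
φ(t) = ∫ HR/60 dt is integrated on a 10 ms grid (trapezoid rule; RR error
< 1 µs for modulation periods ≥ 10 s) and a beat fires at every integer
crossing. This integrate-and-fire rule guarantees that 60/RR computed
downstream recovers the injected modulation: RR_i ≈ 60/HR(interval
midpoint) to second order. A config whose modulations drive HR(t) ≤ 0 is
rejected. Beats in the first or last 0.2 s are not realized, because their
waveform templates would be clipped by the record edges.

**Modulations.** A `ModulationSpec` applies
depth·sin(2π(t − lead_lag)/P) per target variable (HR in bpm, SBP in mmHg,
R-/PPG-amplitude as a fraction of the base amplitude). The target with the
smallest `lead_lag` leads. The preoperative preset injects one P = 25 s
modulation into HR (4 bpm), SBP (5 mmHg) and R-amplitude (10%), with HR
leading SBP by 3.5 s and SBP leading R-amplitude by 8.2 s — magnitudes
typical of LF-band baroreflex oscillations, lags matching the worked
lag-composition example (3.5 + 8.2 = 11.7 s).

**Waveforms.** Only per-beat maxima carry information downstream, so the
templates are deliberately minimal: a Gaussian QRS (σ = 12 ms) whose peak
equals the per-beat R amplitude, and a gamma-shaped arterial pulse
(rise 150 ms, shape k = 3) whose peak equals the per-beat systolic value
over an 80 mmHg diastolic baseline. Both templates peak at the sample
nearest the beat time, aligning the extracted variables across channels
(≤ 1.25 ms quantization at 400 Hz, inside the ±5 ms recovery tolerance).
The PPG channel reuses the pulse template in arbitrary units; LDF is a
slow smoothed random fluctuation around 200 a.u. with no injected
modulation.

**Respiration.** Sinusoidal amplitude modulation of the beat-to-beat
variables. Spontaneous mode: period 4 s, HR 2 bpm (sinus arrhythmia),
SBP 2 mmHg, amplitudes 3%. Mechanical mode: fixed ventilator period 4.5 s
(~13/min), strong amplitude modulation (R-amplitude 40%, SBP 6 mmHg,
PPG 30%) and almost no HR component (0.5 bpm) — positive-pressure
ventilation moves the heart and preload cyclically but barely drives the
sinus node. This reproduces the on-respirator phenomenon: the respiration
dominates iAmp so thoroughly that no slow iAmp peak is detectable.

**Noise.** Per-channel white noise defaults to 1% of signal amplitude
(0.01 mV, 0.4 mmHg) — low enough that clean-condition tests are exact,
non-zero so that detection robustness is exercised. ECG baseline wander is
a 0.1 mV, 3.5 s sinusoid. Transient noise episodes add a Hann-shaped
excursion (default 10 mmHg on BP, 0.4 mV on ECG) plus broadband noise over
a stated interval; episodes are ledger-recorded, merged when overlapping
(with a warning), and rejected when outside the record. Every component
draws from its own seeded substream, so switching one component on or off
leaves the others bit-identical (this underlies the wander-additivity
invariant).

**What the generator does not emulate:** realistic 12-lead ECG
morphology, ectopy/arrhythmia, pulse-wave transit delays, non-sinusoidal
or drifting oscillators, nonstationary noise floors, sensor dropouts.
Passing tests therefore establish that the pipeline recovers known
structure under controlled conditions, not that it is robust to every
failure mode of bedside recordings.

## Beat-to-beat extraction

* **Baseline wander**: the baseline is a Savitzky–Golay smooth (window
  1.0 s, order 3) of a median-filtered (200 ms) copy of the ECG, then
  subtracted. The median pre-filter flattens the narrow QRS complexes so
  they do not leak into the baseline estimate; plain SG smoothing of the
  raw ECG biases R amplitudes by several percent.
* **R peaks**: local maxima above both 40% of the rolling 2-s maximum
  (tracks amplitude modulation) and a global floor of median + 10 MAD
  (rejects pure noise; the probability of a false event on a 30-min white
  noise trace is ≪ 10⁻³), with a 250 ms refractory period and
  local-maximum refinement. Amplitude = ECG value at the peak sample.
* **Systolic peaks**: prominence ≥ 30% of the robust pulse amplitude
  (p95 − p5 of the trace), same refractory period; a flat trace yields no
  events.
* **HR**: HR_i = 60/RR_i, timestamped at the RR-interval midpoint (60/RR
  is the mean rate over the interval, i.e. the instantaneous rate at its
  centre; the interval-start alternative is available via
  `timestamp="start"` but introduces an ~RR/2 phase advance in iHR that
  corrupts lag estimates by ~0.4 s).
* **Outliers**: a beat is dropped when it deviates more than k = 4
  normalized-MAD units from the median of a 60-beat sliding window;
  windows of zero scale (constant stretches) keep all beats; screening is
  applied to SBP, RR and R-amplitude before interpolation, and removed
  beats are deleted (the spline simply bridges them).
* **Interpolation**: natural cubic spline evaluated on the uniform 10 Hz
  grid aligned to multiples of 0.1 s (so all variables share grid phase),
  spanning only the event range — no extrapolation. LDF is instead FIR
  low-pass filtered (4 Hz cutoff, 2001 taps, zero-phase polyphase
  resampling) and decimated 400 → 10 Hz.

## Wavelet analysis

The Morlet CWT (ω₀ = 6) is computed in the frequency domain: the series is
standardized (zero mean, unit variance — spectra of variables with
different units become comparable; an unstandardized transform is
available and is linear in amplitude), zero-padded to the next power of
two, and multiplied by the analytic Morlet filter at each scale; one
inverse FFT per scale. Scale s corresponds to Fourier period
λ = 4πs/(ω₀ + √(2+ω₀²)) ≈ 1.033 s. The period grid is log2-spaced,
10 → 1,024 s at 12 voices per octave (81 scales). Under this
normalization, unit-variance white noise has expected power ≈ 1 at every
period, which gives the peak-detection floor a natural scale.

The cone of influence is the e-folding time √2·s of the wavelet envelope:
within distance d of an edge, periods above ≈ 0.73·d are flagged.
Averaged spectra exclude COI cells by default (periods whose cells are all
edge-affected are reported as NaN); the exclusion is switchable, and the
noise-artifact analysis near 800 s on 30-min records must include the COI,
since at that record length the whole 700–1,000 s band is edge-affected.

**Peak detection** (average spectra): a reported peak must be an interior
local maximum, stand a factor 2 above the surrounding valleys (log-power
prominence), reach twice the median band power, and exceed an absolute
floor of 6 on the standardized-power scale. The floor sits above the
fluctuation ceiling (~5.5) measured for pure white noise at 30-min length,
so pure-noise spectra yield no peaks while injected modulations (typical
peak power 10²–10³) always clear it.

**Cross-wavelet**: W_a·conj(W_b) on a shared grid; phase difference
Δφ = arg(·) ∈ (−π, π], with Δφ > 0 meaning the first series leads;
lag = Δφ·P/(2π) wrapped into (−P/2, P/2]. Significance is assessed per
period against the (1−α) quantile of cross-power pooled over time from
white-noise surrogate pairs of the same length (default 100 surrogates,
α = 0.05; a red-noise null is a straightforward extension but the
white-noise null is what the calibration tests certify). The threshold
depends only on series length and grid and can be computed once and shared
across pairs. Calibration: on independent white-noise pairs the flagged
fraction averages ≈ 0.05.

## Loess decomposition and cross-correlation

Loess: locally weighted quadratic regression with tricube weights over a
nearest-neighbour span, evaluated on a subgrid of ~10 points per bandwidth
and linearly interpolated (the smooth varies on the bandwidth scale, so
the interpolation error is far below other numerical noise; a constant or
quadratic input is reproduced essentially exactly). Three passes with
strictly decreasing spans (defaults 0.30, 0.07, 0.015 of the series
length) each smooth the running residual and subtract, yielding components
of increasing frequency; by construction components + residual reconstruct
the input to machine precision. On a 30-min series the default spans give
component bands around ~500 s, ~100 s and ~20–30 s; spans are
config-exposed. Spans much wider than a component's period let that
component bleed into the next band (a 900-s window captures only about
half of a 600-s oscillation), which is why the defaults are narrower than
a naive reading of "half the series" would suggest.

CCF: Pearson correlation of the overlapping segments at every displacement
on the native 0.1 s lag grid, each segment mean-removed and normalized
over the overlap; a positive `lag_at_max` means the first series lags the
second. Lags with zero-variance overlap are NaN. For lag analysis the CCF
is computed on the Loess component carrying the band of interest (selected
per variable by sinusoidal projection amplitude at the target period), with
max_lag = 0.48·P so the reported lag is unambiguous within one cycle; the
raw interpolated series can be used instead, but respiration and noise
then bias multi-component lags by a few tenths of a second. Pairwise lags
from a common band compose additively.

## Pipeline and comparison

`run_pipeline` maps a declarative YAML config (situations A–D, each a
generator preset/parameter set or a recording path; wavelet, extraction,
Loess and peak-detection settings; a global seed) to a report of
per-situation spectra, peaks, cross-wavelet summaries, lags and a
processing log. Failures are isolated per situation. Identical configs
and seeds give byte-identical report tables.

`compare_situations` judges "loss of an oscillatory component" by an
explicit proxy: a baseline peak is "retained" in another situation if that
situation has a detected peak within one voice step (2^(1/12)) of its
period, else "lost". This replaces a visual judgement with a documented,
configurable rule.

## Problem sizes and defaults used in validation

Validation runs use the study's native problem size — 30-min recordings at
400 Hz (~2,100 beats, 18,000-point 10 Hz series) — except where a property
is length-independent, where shorter series keep the unit tests quick. The
cross-wavelet type-I calibration uses 50 surrogate pairs and 50 test pairs;
the pipeline's default of 100 surrogates tightens the threshold estimate
but does not change the calibration. All randomness is seeded; the
acceptance script derives independent substreams from a single `--seed`.

## Known limitations

* The white-noise significance null is liberal for strongly autocorrelated
  series; a red-noise (AR(1)) null would flag fewer cells at long periods.
* Peak detection at periods approaching the record length rests on very
  few independent wavelet cells; with COI exclusion those periods are
  reported as missing rather than estimated.
* The outlier screen is a per-beat amplitude rule; consecutive corrupted
  beats of consistent amplitude (as in the transient-episode emulation)
  partly survive it — which is precisely the mechanism by which short
  noise events masquerade as slow oscillations.
* Lag estimates are grid-quantized to 0.1 s and assume a common oscillator
  band across variables; they are not meaningful when the variables share
  no spectral peak (the pipeline then skips the lag analysis).
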