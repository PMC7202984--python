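"""Core containers for circulatory-signal analysis.

The package moves data through three representations:

* :class:`RawRecording` — multichannel, uniformly sampled waveforms
  (ECG in mV, arterial BP in mmHg, optional PPG and laser-Doppler flow).
* :class:`BeatSeries` — irregular per-beat event series (systolic pressure,
  R-wave amplitude, heart rate) extracted from the waveforms.
* :class:`InterpolatedSeries` — the per-beat series resampled to a uniform
  10 Hz grid, the input to spectral and correlation analysis.

All arrays are plain ``numpy`` arrays; containers are lightweight dataclasses
so that they serialize cleanly to delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "RawRecording",
    "BeatSeries",
    "InterpolatedSeries",
    "ModulationSpec",
    "RespirationSpec",
    "WanderSpec",
    "NoiseEpisode",
    "GeneratorConfig",
    "GroundTruthLedger",
    "WaveletConfig",
    "WaveletSpectrum",
    "AvgPowerSpectrum",
    "CrossWaveletResult",
    "LoessComponents",
    "CCFResult",
    "SituationSpec",
]

# Modulation targets understood by the generator.  "R-amplitude" and
# "PPG-amplitude" depths are fractional; HR is in bpm, SBP in mmHg.
MOD_TARGETS = ("HR", "SBP", "R-amplitude", "PPG-amplitude")


@dataclass
class RawRecording:
    """Uniformly sampled multichannel recording.

    channels maps channel name ("ecg", "bp", "ppg", "ldf") to a 1-D array.
    All channels share the sampling rate ``fs`` and length.
    """

    channels: dict[str, np.ndarray]
    fs: float
    units: dict[str, str] = field(default_factory=dict)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class BeatSeries:
    """Irregular event series: one value per cardiac event.

    role is one of {"SBP", "R-amplitude", "HR", "RR", "PPG-amplitude"}.
    """

    times: np.ndarray
    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if self.role == "HR" and np.any(self.values <= 0):
            raise ValueError("HR values must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class InterpolatedSeries:
    """Uniformly sampled derived series (iSBP, iHR, iAmp, PPG-iAmp, LDF)."""

    name: str
    values: np.ndarray
    fs: float = 10.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    def __len__(self) -> int:
        return len(self.values)


# --------------------------------------------------------------------------
# Generator configuration
# --------------------------------------------------------------------------


@dataclass
class ModulationSpec:
    """A slow sinusoidal modulation shared by several beat-to-beat variables.

    Each target's modulation is ``depth * sin(2*pi*(t - lead_lag)/period)``:
    a target with a larger ``lead_lag`` is delayed relative to one with a
    smaller ``lead_lag``, so the variable with the smallest ``lead_lag``
    leads.  Depth units: bpm for HR, mmHg for SBP, dimensionless fraction of
    the base amplitude for R-amplitude and PPG-amplitude.
    """

    period: float
    depths: dict[str, float]
    lead_lags: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("modulation period must be positive")
        for target, depth in self.depths.items():
            if target not in MOD_TARGETS:
                raise ValueError(f"unknown modulation target {target!r}")
            if depth < 0:
                raise ValueError("modulation depth must be >= 0")
        for target, lag in self.lead_lags.items():
            if abs(lag) >= self.period:
                raise ValueError("|lead_lag| must be < period")

    def waveform(self, t: np.ndarray, target: str) -> np.ndarray:
        """Evaluate this modulation for one target at times ``t``."""
        depth = self.depths.get(target, 0.0)
        if depth == 0.0:
            return np.zeros_like(np.asarray(t, dtype=float))
        lag = self.lead_lags.get(target, 0.0)
        return depth * np.sin(2.0 * np.pi * (np.asarray(t, dtype=float) - lag) / self.period)


@dataclass
class RespirationSpec:
    """Respiratory modulation of the beat-to-beat variables.

    mode "spontaneous" emulates quiet breathing (modest sinus arrhythmia and
    pulse-pressure variation); "mechanical" emulates positive-pressure
    ventilation, which strongly amplitude-modulates the ECG and the arterial
    pulse at a fixed ventilator rate while barely moving the sinus node.
    """

    period: float = 4.0
    depths: dict[str, float] = field(default_factory=dict)
    mode: str = "spontaneous"

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("respiration period must be positive")
        if self.mode not in ("spontaneous", "mechanical"):
            raise ValueError("mode must be 'spontaneous' or 'mechanical'")
        if not self.depths:
            if self.mode == "spontaneous":
                self.depths = {"HR": 2.0, "SBP": 2.0, "R-amplitude": 0.03, "PPG-amplitude": 0.03}
            else:
                self.depths = {"HR": 0.5, "SBP": 6.0, "R-amplitude": 0.40, "PPG-amplitude": 0.30}

    def waveform(self, t: np.ndarray, target: str) -> np.ndarray:
        depth = self.depths.get(target, 0.0)
        if depth == 0.0:
            return np.zeros_like(np.asarray(t, dtype=float))
        return depth * np.sin(2.0 * np.pi * np.asarray(t, dtype=float) / self.period)


@dataclass
class WanderSpec:
    """Sinusoidal ECG baseline wander (electrode/respiration drift)."""

    period: float = 3.5
    amplitude: float = 0.0  # mV

    def waveform(self, t: np.ndarray) -> np.ndarray:
        if self.amplitude == 0.0:
            return np.zeros_like(np.asarray(t, dtype=float))
        return self.amplitude * np.sin(2.0 * np.pi * np.asarray(t, dtype=float) / self.period)


@dataclass
class NoiseEpisode:
    """A short transient artifact superimposed on the raw channels."""

    start: float
    duration: float
    amplitude: dict[str, float] = field(default_factory=lambda: {"bp": 10.0, "ecg": 0.4})

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("episode duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class GeneratorConfig:
    """Full description of a synthetic circulatory recording.

    Defaults describe a resting adult in sinus rhythm recorded for 30 min at
    400 Hz with quiet spontaneous respiration, mild ECG baseline wander and a
    white-noise floor of about 1% of each channel's signal amplitude.
    """

    duration: float = 1800.0
    fs_raw: float = 400.0
    base_hr: float = 70.0
    base_sbp: float = 120.0
    base_dbp: float = 80.0
    base_r_amp: float = 1.0  # mV
    base_ppg_amp: float = 1.0  # a.u.
    base_ldf: float = 200.0  # a.u.
    modulations: list[ModulationSpec] = field(default_factory=list)
    respiration: Optional[RespirationSpec] = field(default_factory=RespirationSpec)
    wander: WanderSpec = field(default_factory=lambda: WanderSpec(period=3.5, amplitude=0.1))
    white_noise_sd: dict[str, float] = field(default_factory=dict)
    noise_episodes: list[NoiseEpisode] = field(default_factory=list)
    brody_gain: float = 0.0
    include_ppg: bool = False
    include_ldf: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (20.0 < self.base_hr < 220.0):
            raise ValueError("base_hr must lie in (20, 220) bpm")
        # QRS template occupies ~25 ms half-width -> highest template
        # frequency ~40 Hz; 400 Hz sampling is comfortably above 2x that.
        if self.fs_raw <= 100.0:
            raise ValueError("fs_raw too low for the waveform templates")
        if not self.white_noise_sd:
            pulse = self.base_sbp - self.base_dbp
            self.white_noise_sd = {
                "ecg": 0.01 * self.base_r_amp,
                "bp": 0.01 * pulse,
                "ppg": 0.01 * self.base_ppg_amp,
                "ldf": 0.01 * self.base_ldf,
            }
        for ep in self.noise_episodes:
            if ep.start < 0 or ep.end > self.duration:
                raise ValueError("noise episode outside recording bounds")


@dataclass
class GroundTruthLedger:
    """Simulator ground truth used as the oracle in recovery tests."""

    beat_times: np.ndarray
    true_sbp: np.ndarray
    true_r_amp: np.ndarray
    true_hr: np.ndarray  # length n_beats - 1, value for interval i -> i+1
    true_ppg_amp: Optional[np.ndarray] = None
    modulations: list[ModulationSpec] = field(default_factory=list)
    noise_episode_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.beat_times) > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("ledger beat times must be strictly increasing")
        n = len(self.beat_times)
        if len(self.true_sbp) != n or len(self.true_r_amp) != n:
            raise ValueError("per-beat arrays must match beat_times length")
        if n >= 2 and len(self.true_hr) != n - 1:
            raise ValueError("true_hr must have length n_beats - 1")


# --------------------------------------------------------------------------
# Wavelet containers
# --------------------------------------------------------------------------


@dataclass
class WaveletConfig:
    """Morlet CWT settings.

    The period grid is log2-spaced from ``period_min`` to ``period_max``
    with ``voices_per_octave`` scales per octave.  ``omega0`` is the Morlet
    central (angular) frequency; 6 is the conventional choice balancing time
    and frequency resolution.
    """

    omega0: float = 6.0
    period_min: float = 10.0
    period_max: float = 1024.0
    voices_per_octave: int = 12
    alpha: float = 0.05
    n_surrogates: int = 100
    padding: str = "pow2"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.period_min <= 0 or self.period_max <= self.period_min:
            raise ValueError("need 0 < period_min < period_max")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")

    @property
    def fourier_factor(self) -> float:
        """Period per unit scale for the Morlet wavelet."""
        w0 = self.omega0
        return 4.0 * np.pi / (w0 + np.sqrt(2.0 + w0 * w0))

    def periods(self) -> np.ndarray:
        n_oct = np.log2(self.period_max / self.period_min)
        n = int(np.floor(n_oct * self.voices_per_octave)) + 1
        return self.period_min * 2.0 ** (np.arange(n) / self.voices_per_octave)


@dataclass
class WaveletSpectrum:
    """Time-period wavelet power with its cone of influence.

    power has shape (n_periods, n_times); coi[t] is the longest period
    free of edge effects at time t.
    """

    times: np.ndarray
    periods: np.ndarray
    power: np.ndarray
    coi: np.ndarray

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.periods), len(self.times)):
            raise ValueError("power must be (n_periods, n_times)")
        if np.any(self.power < 0):
            raise ValueError("wavelet power must be non-negative")


@dataclass
class AvgPowerSpectrum:
    """Time-averaged wavelet power per period (NaN where fully inside COI)."""

    periods: np.ndarray
    avg_power: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.periods) != len(self.avg_power):
            raise ValueError("periods and avg_power must align")
        finite = np.isfinite(self.avg_power)
        if np.any(self.avg_power[finite] < 0):
            raise ValueError("average power must be non-negative")


@dataclass
class CrossWaveletResult:
    """Cross-wavelet spectrum of two series on a shared grid.

    phase_diff is in (-pi, pi]; positive phase means the first series leads.
    significant marks cells whose cross power exceeds the white-noise
    surrogate threshold at the configured alpha.
    """

    times: np.ndarray
    periods: np.ndarray
    cross_power: np.ndarray
    phase_diff: np.ndarray
    significant: np.ndarray
    coi: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.periods), len(self.times))
        for name in ("cross_power", "phase_diff", "significant"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must be (n_periods, n_times)")
        if np.any(self.phase_diff > np.pi) or np.any(self.phase_diff <= -np.pi):
            raise ValueError("phase_diff must lie in (-pi, pi]")


# --------------------------------------------------------------------------
# Decomposition and correlation containers
# --------------------------------------------------------------------------


@dataclass
class LoessComponents:
    """Iterative Loess decomposition: slow-to-fast components plus residual.

    components[0] + components[1] + components[2] + residual reconstructs the
    input exactly (telescoping identity).
    """

    components: list[np.ndarray]
    residual: np.ndarray
    spans: tuple[float, ...]
    fs: float = 10.0
    start_time: float = 0.0


@dataclass
class CCFResult:
    """Cross-correlation function on the uniform lag grid.

    Sign convention: positive ``lag_at_max`` means the first series lags the
    second (the second leads).
    """

    lags: np.ndarray
    correlations: np.ndarray
    ccf_max: float
    lag_at_max: float


@dataclass
class SituationSpec:
    """One 30-min perioperative selection (labels A-D in the study design)."""

    label: str
    segment_start: float = 0.0
    segment_length: float = 1800.0
    ventilated: bool = False
    generator: Optional[GeneratorConfig] = None
    recording_path: Optional[str] = None


def copy_config(config: GeneratorConfig, **changes) -> GeneratorConfig:
    """Return a copy of a generator config with fields replaced."""
    return replace(config, **changes)
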