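"""End-to-end orchestration over perioperative situations.

``run_pipeline`` takes a declarative config (YAML file or dict) describing
one or more 30-min situations — each either a synthetic-generator preset /
parameter set or a recording on disk — and produces a :class:`RunReport`
holding, per situation and variable, the average wavelet power spectrum and
its detected peaks; cross-wavelet summaries for the pairs (iAmp, iSBP) and
(iSBP, iHR); Loess band-limited cross-correlation lags; and a processing
log (beats detected, outliers removed, seeds, config echo).

``compare_situations`` tabulates, for every spectral peak of a baseline
situation, whether a peak within one voice step survives in each other
situation — a explicit, configurable proxy for judging "loss of an
oscillatory component" between recordings.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .beats import align_series, extract_variables
from .decompose import compose_lags, cross_correlation, loess_decompose
from .io import load_recording, save_avg_spectrum, save_recording
from .types import (
    AvgPowerSpectrum,
    CCFResult,
    GeneratorConfig,
    InterpolatedSeries,
    ModulationSpec,
    NoiseEpisode,
    RawRecording,
    RespirationSpec,
    WanderSpec,
    WaveletConfig,
)
from .wavelet import average_power, cross_wavelet, find_spectral_peaks, morlet_cwt, phase_to_lag

__all__ = [
    "RunReport",
    "SituationResult",
    "run_pipeline",
    "analyze_situation",
    "band_component",
    "lag_analysis",
    "compare_situations",
    "generator_from_dict",
]

CROSS_PAIRS = (("iAmp", "iSBP"), ("iSBP", "iHR"))
PRESETS = {
    "patient1a": synthetic.patient1a_config,
    "ventilated": synthetic.ventilated_config,
    "noise_artifact": synthetic.noise_artifact_config,
    "quiet": synthetic.quiet_config,
}


# --------------------------------------------------------------------------
# Config handling
# --------------------------------------------------------------------------


def generator_from_dict(d: dict[str, Any]) -> GeneratorConfig:
    """Build a GeneratorConfig from plain-dict (YAML) parameters."""
    d = dict(d)
    mods = [
        ModulationSpec(
            period=float(m["period"]),
            depths={k: float(v) for k, v in m.get("depths", {}).items()},
            lead_lags={k: float(v) for k, v in m.get("lead_lags", {}).items()},
        )
        for m in d.pop("modulations", [])
    ]
    resp = d.pop("respiration", "default")
    if resp is None:
        respiration = None
    elif resp == "default":
        respiration = RespirationSpec()
    else:
        respiration = RespirationSpec(
            period=float(resp.get("period", 4.0)),
            depths={k: float(v) for k, v in resp.get("depths", {}).items()},
            mode=resp.get("mode", "spontaneous"),
        )
    wander = d.pop("wander", None)
    wspec = (
        WanderSpec(period=float(wander.get("period", 3.5)), amplitude=float(wander.get("amplitude", 0.0)))
        if wander
        else WanderSpec(period=3.5, amplitude=0.1)
    )
    episodes = [
        NoiseEpisode(
            start=float(e["start"]),
            duration=float(e["duration"]),
            amplitude={k: float(v) for k, v in e.get("amplitude", {"bp": 10.0, "ecg": 0.4}).items()},
        )
        for e in d.pop("noise_episodes", [])
    ]
    return GeneratorConfig(
        modulations=mods, respiration=respiration, wander=wspec, noise_episodes=episodes, **d
    )


def _situation_recording(spec: dict[str, Any], default_seed: int) -> tuple[RawRecording, Optional[object], Optional[GeneratorConfig]]:
    """Obtain the recording for one situation spec (simulate or load)."""
    from .beats import select_segment

    if "recording" in spec:
        rec, ledger = load_recording(spec["recording"])
        cfg = None
    else:
        if "preset" in spec:
            kwargs = dict(spec.get("generator", {}))
            kwargs.setdefault("seed", spec.get("seed", default_seed))
            cfg = PRESETS[spec["preset"]](**kwargs)
        elif "generator" in spec:
            g = dict(spec["generator"])
            g.setdefault("seed", spec.get("seed", default_seed))
            cfg = generator_from_dict(g)
        else:
            raise ValueError("situation needs 'recording', 'preset' or 'generator'")
        rec, ledger = synthetic.generate_recording(cfg)
    start = float(spec.get("segment_start", 0.0))
    length = float(spec.get("segment_length", min(1800.0, rec.duration - start)))
    if start != 0.0 or abs(length - rec.duration) > 1e-9:
        rec = select_segment(rec, start, length)
    return rec, ledger, cfg


# --------------------------------------------------------------------------
# Band-limited lag analysis
# --------------------------------------------------------------------------


def band_component(series: InterpolatedSeries, period: float,
                   spans: tuple[float, float, float] = (0.3, 0.07, 0.015)) -> InterpolatedSeries:
    """Loess component of a series that best represents a target period.

    The series is decomposed into three Loess components; the one with the
    largest sinusoidal projection amplitude at ``period`` is returned (the
    residual is also a candidate, for periods below the narrowest span).
    """
    dec = loess_decompose(series, spans=spans)
    t = series.times
    phasor = np.exp(-2j * np.pi * t / period)
    candidates = list(dec.components) + [dec.residual]
    amps = [np.abs((c - c.mean()) @ phasor) for c in candidates]
    best = candidates[int(np.argmax(amps))]
    return InterpolatedSeries(name=f"{series.name}@{period:g}s", values=best,
                              fs=series.fs, start_time=series.start_time)


def common_peak_period(spectra: dict[str, AvgPowerSpectrum], voices: int = 12,
                       **peak_kwargs) -> Optional[float]:
    """Period of the strongest peak shared (within one voice step) by all variables."""
    per_var = {v: find_spectral_peaks(a, **peak_kwargs) for v, a in spectra.items()}
    if any(len(p) == 0 for p in per_var.values()):
        return None
    step = 2.0 ** (1.0 / voices)
    first = next(iter(per_var))
    best: tuple[float, float] | None = None  # (min power across vars, period)
    for period, power in per_var[first]:
        powers = [power]
        ok = True
        for v, peaks in per_var.items():
            if v == first:
                continue
            match = [pw for pd, pw in peaks if period / step <= pd <= period * step]
            if not match:
                ok = False
                break
            powers.append(max(match))
        if ok:
            score = min(powers)
            if best is None or score > best[0]:
                best = (score, period)
    return None if best is None else best[1]


def lag_analysis(
    series: dict[str, InterpolatedSeries],
    period: float,
    spans: tuple[float, float, float] = (0.3, 0.07, 0.015),
) -> dict[str, Any]:
    """Pairwise CCF lags on the Loess band at ``period``, plus composition.

    Computes CCF for (iAmp, iSBP) and (iSBP, iHR) on the band-limited
    components, with max_lag just under half the target period so that the
    reported lag is unambiguous, and composes the two pairwise lags into the
    total iAmp-vs-iHR lag.
    """
    bands = {v: band_component(s, period, spans) for v, s in series.items()
             if v in {"iAmp", "iSBP", "iHR"}}
    max_lag = 0.48 * period
    out: dict[str, Any] = {"period": period}
    ccfs: dict[str, CCFResult] = {}
    for a, b in CROSS_PAIRS:
        r = cross_correlation(bands[a], bands[b], max_lag=max_lag)
        ccfs[f"{a}-{b}"] = r
        out[f"lag_{a}_{b}"] = r.lag_at_max
        out[f"ccfmax_{a}_{b}"] = r.ccf_max
    out["lag_iAmp_iHR_composed"] = compose_lags(
        out["lag_iAmp_iSBP"], out["lag_iSBP_iHR"]
    )
    out["ccf"] = ccfs
    return out


# --------------------------------------------------------------------------
# Situation analysis and the full run
# --------------------------------------------------------------------------


@dataclass
class SituationResult:
    label: str
    series: dict[str, InterpolatedSeries]
    spectra: dict[str, AvgPowerSpectrum]
    peaks: dict[str, list[tuple[float, float]]]
    cross: dict[str, dict[str, Any]]
    lags: Optional[dict[str, Any]]
    counts: dict[str, dict[str, int]]
    error: Optional[str] = None


@dataclass
class RunReport:
    situations: dict[str, SituationResult]
    config: dict[str, Any]
    failures: dict[str, str] = field(default_factory=dict)

    def to_dir(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        log: dict[str, Any] = {"config": self.config, "failures": self.failures, "situations": {}}
        for label, res in self.situations.items():
            sdir = directory / f"situation_{label}"
            sdir.mkdir(exist_ok=True)
            for var, avg in res.spectra.items():
                save_avg_spectrum(sdir / f"avg_spectrum_{var}.csv", avg)
            peaks_rows = [
                {"variable": v, "period_s": p, "power": w}
                for v, pk in res.peaks.items()
                for p, w in pk
            ]
            pd.DataFrame(peaks_rows, columns=["variable", "period_s", "power"]).to_csv(
                sdir / "peaks.csv", index=False
            )
            if res.lags is not None:
                lag_rows = {k: v for k, v in res.lags.items() if k != "ccf"}
                pd.DataFrame([lag_rows]).to_csv(sdir / "lags.csv", index=False)
            cross_rows = [
                {"pair": pair, **{k: v for k, v in summ.items()}}
                for pair, summ in res.cross.items()
            ]
            pd.DataFrame(cross_rows).to_csv(sdir / "cross_wavelet.csv", index=False)
            log["situations"][label] = {
                "counts": res.counts,
                "error": res.error,
                "n_variables": len(res.series),
            }
        (directory / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
        return directory


def analyze_situation(
    recording: RawRecording,
    label: str = "A",
    wavelet_config: WaveletConfig | None = None,
    extraction: dict[str, Any] | None = None,
    loess_spans: tuple[float, float, float] = (0.3, 0.07, 0.015),
    exclude_coi: bool = True,
    cross_rng: int = 0,
    peak_kwargs: dict[str, Any] | None = None,
) -> SituationResult:
    """Run the complete analysis chain on one recording."""
    wc = wavelet_config or WaveletConfig()
    peak_kwargs = peak_kwargs or {}
    res = extract_variables(recording, **(extraction or {}))
    core = [v for v in ("iSBP", "iHR", "iAmp") if v in res.series]
    spectra: dict[str, AvgPowerSpectrum] = {}
    peaks: dict[str, list[tuple[float, float]]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)  # all-COI nanmean rows
        for var, s in res.series.items():
            avg = average_power(morlet_cwt(s, wc), exclude_coi=exclude_coi)
            avg.name = var
            spectra[var] = avg
            peaks[var] = find_spectral_peaks(avg, **peak_kwargs)
        cross: dict[str, dict[str, Any]] = {}
        # The surrogate threshold depends only on series length and grid:
        # compute it once per length and reuse across pairs.
        from .wavelet import _surrogate_threshold

        thr_cache: dict[int, np.ndarray] = {}
        for a, b in CROSS_PAIRS:
            if a not in res.series or b not in res.series:
                continue
            sa, sb = align_series([res.series[a], res.series[b]])
            n = len(sa)
            if n not in thr_cache:
                thr_cache[n] = _surrogate_threshold(
                    n, 1.0 / sa.fs, wc, np.random.default_rng(cross_rng)
                )
            cw = cross_wavelet(sa, sb, wc, threshold=thr_cache[n])
            in_coi = cw.periods[:, None] > cw.coi[None, :]
            sig_frac = float(cw.significant[~in_coi].mean()) if (~in_coi).any() else float(
                cw.significant.mean()
            )
            avg_cross = np.where(
                (~in_coi).any(axis=1),
                np.nanmean(np.where(~in_coi, cw.cross_power, np.nan), axis=1),
                np.nan,
            )
            i_pk = int(np.nanargmax(avg_cross))
            band = np.abs(np.log2(cw.periods / cw.periods[i_pk])) <= 0.5 / wc.voices_per_octave
            sel = band[:, None] & ~in_coi & cw.significant
            med_phase = float(np.median(cw.phase_diff[sel])) if sel.any() else float("nan")
            cross[f"{a}-{b}"] = {
                "significant_fraction": sig_frac,
                "peak_period_s": float(cw.periods[i_pk]),
                "median_phase_rad": med_phase,
                "phase_lag_s": phase_to_lag(med_phase, float(cw.periods[i_pk]))
                if np.isfinite(med_phase)
                else float("nan"),
            }
    common = common_peak_period({v: spectra[v] for v in core}, wc.voices_per_octave,
                                **peak_kwargs)
    lags = None
    if common is not None:
        aligned = align_series([res.series[v] for v in core])
        lags = lag_analysis({s.name: s for s in aligned}, common, spans=loess_spans)
    return SituationResult(
        label=label,
        series=res.series,
        spectra=spectra,
        peaks=peaks,
        cross=cross,
        lags=lags,
        counts=res.counts,
    )


def run_pipeline(config: str | Path | dict[str, Any],
                 output_dir: str | Path | None = None) -> RunReport:
    """Run the full analysis over all configured situations.

    ``config`` is a YAML path or an equivalent dict; see the package docs
    for the schema.  Failures in one situation are recorded and do not stop
    the others.  Deterministic given the configured seeds.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    situations = cfg.get("situations", [])
    if not situations:
        raise ValueError("config must list at least one situation")
    labels = [s.get("label") for s in situations]
    if len(set(labels)) != len(labels) or any(not l for l in labels):
        raise ValueError("situation labels must be unique and non-empty")
    seed = int(cfg.get("seed", 0))
    wc = WaveletConfig(**cfg.get("wavelet", {}))
    extraction = cfg.get("extraction", {})
    spans = tuple(cfg.get("loess_spans", (0.3, 0.07, 0.015)))
    exclude_coi = bool(cfg.get("exclude_coi", True))
    peak_kwargs = cfg.get("peaks", {})
    report = RunReport(situations={}, config=cfg)
    for spec in situations:
        label = spec["label"]
        try:
            rec, ledger, gen_cfg = _situation_recording(spec, seed)
            result = analyze_situation(
                rec,
                label=label,
                wavelet_config=wc,
                extraction=extraction,
                loess_spans=spans,
                exclude_coi=exclude_coi,
                cross_rng=seed,
                peak_kwargs=peak_kwargs,
            )
            report.situations[label] = result
            if output_dir is not None and gen_cfg is not None and cfg.get("save_recordings"):
                save_recording(Path(output_dir) / f"recording_{label}", rec,
                               ledger=ledger, config=gen_cfg)
        except Exception as exc:  # noqa: BLE001 - per-situation isolation
            report.failures[label] = f"{type(exc).__name__}: {exc}"
    if output_dir is not None:
        report.to_dir(output_dir)
    return report


def compare_situations(
    report: RunReport,
    baseline: str,
    others: list[str],
    voices: int = 12,
) -> pd.DataFrame:
    """Tabulate per-variable peak presence/absence relative to a baseline.

    For every spectral peak of the baseline situation, each other situation
    is marked "retained" if it has a peak within one voice step of the
    baseline period, else "lost".  Returns an empty table when the baseline
    has no peaks.
    """
    for label in [baseline, *others]:
        if label not in report.situations:
            raise KeyError(f"situation {label!r} missing from the report")
    step = 2.0 ** (1.0 / voices)
    rows = []
    base = report.situations[baseline]
    for var, pks in base.peaks.items():
        for period, power in pks:
            row: dict[str, Any] = {"variable": var, "period_s": period, "power": power}
            for other in others:
                opks = report.situations[other].peaks.get(var, [])
                present = any(period / step <= p <= period * step for p, _ in opks)
                row[other] = "retained" if present else "lost"
            rows.append(row)
    return pd.DataFrame(rows, columns=["variable", "period_s", "power", *others])
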