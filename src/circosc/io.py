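"""Delimited-text I/O for recordings, ledgers, series and spectra.

A recording is stored as a directory:

    channels.csv   one column per channel, header row naming channels
    metadata.yaml  fs, channel units, seed and a config echo
    ledger_beats.csv / ledger_modulations.csv / ledger_episodes.csv
                   (only for synthetic recordings)

Derived series are two-column CSV (time_s, value); spectra are matrices with
a header row of times and the period grid in the first column.  A reader for
MATLAB-v5 container exports (channel-name mapping supplied by the caller) is
included for acquisition-software exports.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .types import (
    AvgPowerSpectrum,
    GeneratorConfig,
    GroundTruthLedger,
    InterpolatedSeries,
    ModulationSpec,
    RawRecording,
    WaveletSpectrum,
)

__all__ = [
    "save_recording",
    "load_recording",
    "save_series",
    "load_series",
    "save_avg_spectrum",
    "load_avg_spectrum",
    "save_spectrum_matrix",
    "read_mat_recording",
]


def _config_echo(config: GeneratorConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(config)


def save_recording(
    directory: str | Path,
    recording: RawRecording,
    ledger: Optional[GroundTruthLedger] = None,
    config: Optional[GeneratorConfig] = None,
) -> Path:
    """Write a recording (and optional ledger/config echo) as delimited text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(recording.channels).to_csv(directory / "channels.csv", index=False)
    meta = {
        "fs": float(recording.fs),
        "start_time": float(recording.start_time),
        "units": dict(recording.units),
    }
    if config is not None:
        meta["seed"] = int(config.seed)
        meta["config"] = _config_echo(config)
    (directory / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    if ledger is not None:
        beats = pd.DataFrame(
            {
                "beat_time_s": ledger.beat_times,
                "true_sbp_mmHg": ledger.true_sbp,
                "true_r_amp_mV": ledger.true_r_amp,
            }
        )
        if ledger.true_ppg_amp is not None:
            beats["true_ppg_amp"] = ledger.true_ppg_amp
        beats.to_csv(directory / "ledger_beats.csv", index=False)
        rows = []
        for mod in ledger.modulations:
            for target, depth in mod.depths.items():
                rows.append(
                    {
                        "period_s": mod.period,
                        "target": target,
                        "depth": depth,
                        "lead_lag_s": mod.lead_lags.get(target, 0.0),
                    }
                )
        pd.DataFrame(rows, columns=["period_s", "target", "depth", "lead_lag_s"]).to_csv(
            directory / "ledger_modulations.csv", index=False
        )
        pd.DataFrame(
            ledger.noise_episode_intervals, columns=["start_s", "end_s"]
        ).to_csv(directory / "ledger_episodes.csv", index=False)
    return directory


def load_recording(directory: str | Path) -> tuple[RawRecording, Optional[GroundTruthLedger]]:
    """Read a recording directory written by :func:`save_recording`."""
    directory = Path(directory)
    meta = yaml.safe_load((directory / "metadata.yaml").read_text())
    df = pd.read_csv(directory / "channels.csv")
    rec = RawRecording(
        channels={c: df[c].to_numpy() for c in df.columns},
        fs=float(meta["fs"]),
        units=dict(meta.get("units", {})),
        start_time=float(meta.get("start_time", 0.0)),
    )
    ledger = None
    beats_path = directory / "ledger_beats.csv"
    if beats_path.exists():
        beats = pd.read_csv(beats_path)
        mods = []
        mods_path = directory / "ledger_modulations.csv"
        if mods_path.exists():
            mdf = pd.read_csv(mods_path)
            for period, grp in mdf.groupby("period_s"):
                mods.append(
                    ModulationSpec(
                        period=float(period),
                        depths=dict(zip(grp["target"], grp["depth"])),
                        lead_lags=dict(zip(grp["target"], grp["lead_lag_s"])),
                    )
                )
        episodes: list[tuple[float, float]] = []
        ep_path = directory / "ledger_episodes.csv"
        if ep_path.exists():
            edf = pd.read_csv(ep_path)
            episodes = [tuple(r) for r in edf.to_numpy()]
        times = beats["beat_time_s"].to_numpy()
        ledger = GroundTruthLedger(
            beat_times=times,
            true_sbp=beats["true_sbp_mmHg"].to_numpy(),
            true_r_amp=beats["true_r_amp_mV"].to_numpy(),
            true_hr=60.0 / np.diff(times) if len(times) > 1 else np.array([]),
            true_ppg_amp=beats["true_ppg_amp"].to_numpy() if "true_ppg_amp" in beats else None,
            modulations=mods,
            noise_episode_intervals=episodes,
        )
    return rec, ledger


def save_series(path: str | Path, series: InterpolatedSeries) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": series.times, "value": series.values}).to_csv(path, index=False)
    return path


def load_series(path: str | Path, name: str | None = None) -> InterpolatedSeries:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return InterpolatedSeries(
        name=name or Path(path).stem,
        values=df["value"].to_numpy(),
        fs=round(fs, 6),
        start_time=float(t[0]),
    )


def save_avg_spectrum(path: str | Path, avg: AvgPowerSpectrum) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"period_s": avg.periods, "avg_power": avg.avg_power}).to_csv(path, index=False)
    return path


def load_avg_spectrum(path: str | Path, name: str = "") -> AvgPowerSpectrum:
    df = pd.read_csv(path)
    return AvgPowerSpectrum(
        periods=df["period_s"].to_numpy(), avg_power=df["avg_power"].to_numpy(), name=name
    )


def save_spectrum_matrix(path: str | Path, spectrum: WaveletSpectrum,
                         matrix: np.ndarray | None = None) -> Path:
    """Write a time-period matrix: header row of times, periods first column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m = spectrum.power if matrix is None else matrix
    df = pd.DataFrame(m, index=spectrum.periods, columns=np.round(spectrum.times, 3))
    df.index.name = "period_s"
    df.to_csv(path)
    return path


def read_mat_recording(
    path: str | Path,
    channel_map: dict[str, str],
    fs: float = 400.0,
) -> RawRecording:
    """Read a MATLAB-v5 container export into a RawRecording.

    ``channel_map`` maps package channel names ("ecg", "bp", ...) to the
    variable names inside the file.
    """
    from scipy.io import loadmat

    data = loadmat(str(path), squeeze_me=True)
    channels = {}
    for name, var in channel_map.items():
        if var not in data:
            raise KeyError(f"variable {var!r} not found in {path}")
        channels[name] = np.asarray(data[var], dtype=float).ravel()
    return RawRecording(channels=channels, fs=fs)
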