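#!/usr/bin/env python
"""Average wavelet power spectra and peak retention across situations A-D.

For every situation and variable: Morlet CWT (10-1,024 s, 12 voices per
octave), time-averaged power, and distinct-peak detection.  Then each peak
of the preoperative baseline (A) is checked for survival (within one voice
step) in B, C and D — the loss-of-oscillation tabulation.
"""

import warnings
from pathlib import Path

import pandas as pd

from circosc import average_power, find_spectral_peaks, morlet_cwt
from circosc.io import load_series, save_avg_spectrum

ROOT = Path(__file__).resolve().parents[1]
STEP = 2 ** (1 / 12)


def main() -> None:
    warnings.filterwarnings("ignore", category=UserWarning)
    series_root = ROOT / "scratch" / "series"
    peaks_rows = []
    peaks_by = {}
    for sdir in sorted(series_root.iterdir()):
        label = sdir.name
        for path in sorted(sdir.glob("*.csv")):
            s = load_series(path)
            avg = average_power(morlet_cwt(s))
            save_avg_spectrum(ROOT / "scratch" / "spectra" / label / path.name, avg)
            pk = find_spectral_peaks(avg)
            peaks_by[(label, s.name)] = pk
            for period, power in pk:
                peaks_rows.append({"situation": label, "variable": s.name,
                                   "period_s": round(period, 1),
                                   "power": round(power, 1)})
    peaks = pd.DataFrame(peaks_rows, columns=["situation", "variable", "period_s", "power"])
    peaks.to_csv(ROOT / "results" / "03_peaks_by_situation.csv", index=False)
    print("detected peaks:")
    print(peaks.to_string(index=False))

    rows = []
    for (label, var), pk in peaks_by.items():
        if label != "A":
            continue
        for period, power in pk:
            row = {"variable": var, "period_s": round(period, 1)}
            for other in ("B", "C", "D"):
                opk = peaks_by.get((other, var), [])
                present = any(period / STEP <= p <= period * STEP for p, _ in opk)
                row[other] = "retained" if present else "lost"
            rows.append(row)
    retention = pd.DataFrame(rows, columns=["variable", "period_s", "B", "C", "D"])
    retention.to_csv(ROOT / "results" / "03_peak_retention.csv", index=False)
    print("\nbaseline-A peak retention:")
    print(retention.to_string(index=False) if len(retention) else "(no baseline peaks)")


if __name__ == "__main__":
    main()
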