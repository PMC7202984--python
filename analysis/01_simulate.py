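#!/usr/bin/env python
"""Generate the four perioperative situation emulations (A-D).

A: preoperative, with a 25-s oscillation shared by HR, SBP and R-amplitude
   (HR leading SBP by 3.5 s, SBP leading R-amplitude by 8.2 s).
B: postoperative on respirator — mechanical ventilation dominates the
   amplitude channels; only a slow (60 s) HR oscillation remains.
C: post-extubation, D: next morning — spontaneous breathing, no slow
   modulation (the 25-s oscillation does not return).

Recordings (30 min at 400 Hz, ~100 MB as text) go to scratch/recordings/;
a small summary table goes to results/.
"""

from pathlib import Path

import pandas as pd

from circosc import generate_recording
from circosc.io import save_recording
from circosc.synthetic import patient1a_config, quiet_config, ventilated_config

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

CONFIGS = {
    "A": patient1a_config(seed=SEED),
    "B": ventilated_config(seed=SEED + 1),
    "C": quiet_config(seed=SEED + 2),
    "D": quiet_config(seed=SEED + 3),
}


def main() -> None:
    out = ROOT / "scratch" / "recordings"
    rows = []
    for label, cfg in CONFIGS.items():
        rec, ledger = generate_recording(cfg)
        save_recording(out / f"situation_{label}", rec, ledger=ledger, config=cfg)
        rows.append(
            {
                "situation": label,
                "n_beats": len(ledger.beat_times),
                "duration_s": rec.duration,
                "mean_hr_bpm": round(60.0 * (len(ledger.beat_times) - 1)
                                     / (ledger.beat_times[-1] - ledger.beat_times[0]), 1),
                "modulation_periods_s": ";".join(
                    f"{m.period:g}" for m in ledger.modulations
                ),
            }
        )
        print(f"situation {label}: {rows[-1]['n_beats']} beats, "
              f"mean HR {rows[-1]['mean_hr_bpm']} bpm")
    table = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    table.to_csv(ROOT / "results" / "01_recordings.csv", index=False)
    print(f"recordings under {out}")


if __name__ == "__main__":
    main()
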