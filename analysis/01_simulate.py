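#!/usr/bin/env python
"""Simulate the demo oddball cohort and write it to results/data/.

Two groups of six participants, three graded deviance conditions at 15%
deviants, 32 scalp channels at 128 Hz, blink and bad-channel artifacts on.
Each participant/condition epoch set goes to an HDF5 file; behavioral
identification vectors and the montage are written alongside.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from erpdecode.containers import save_epochs
from erpdecode.synth import SynthConfig, simulate_cohort

BASE = Path(__file__).resolve().parent.parent
OUT = BASE / "results" / "data"          # text: configs, behavior, index
EPOCHS = BASE / "scratch" / "data"       # binary epoch containers
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    EPOCHS.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(
        n_channels=32, sampling_rate=128.0, trial_count=160, seed=SEED
    )
    cfg.to_json(OUT / "synth_config.json")
    cfg.montage().save(OUT / "montage.txt")
    cohort = simulate_cohort(cfg, {"native": 6, "nonnative": 6})
    rows = []
    for p in cohort:
        for cond, ep in p.epochs.items():
            save_epochs(EPOCHS / f"{p.participant}_{cond}.h5", ep)
            rows.append(
                {
                    "participant": p.participant,
                    "group": p.group,
                    "condition": cond,
                    "n_trials": ep.n_trials,
                    "n_deviants": int(np.sum(ep.trial_class == "deviant")),
                }
            )
        pd.DataFrame(
            {"step": np.arange(1, 8), "p_deviant_category": p.behavior}
        ).to_csv(OUT / f"{p.participant}_behavior.csv", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "cohort_index.csv", index=False)
    print(f"wrote {len(cohort)} participants x {len(cfg.conditions)} conditions")
    print(
        "deviant fraction:",
        round(table.n_deviants.sum() / table.n_trials.sum(), 3),
    )


if __name__ == "__main__":
    main()
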