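#!/usr/bin/env python
"""Within-participant decoding, AUC maps and multi-trial curves.

Per participant and condition: stratified 10-fold logistic decoding with
nested regularization search, MMN-window amplitude of the difference
wave, and binomial significance.  Held-out decisions from the largest
deviance condition feed the accuracy-versus-N evidence curves.
"""

from pathlib import Path

import pandas as pd

from erpdecode.containers import load_epochs
from erpdecode.decode import binomial_threshold, crossval_within
from erpdecode.discriminability import auc_map
from erpdecode.evidence import per_participant_curves
from erpdecode.interpret import mmn_amplitude

BASE = Path(__file__).resolve().parent.parent
IN = BASE / "scratch" / "preprocessed"
OUT = BASE / "results" / "within"
AUC_DIR = BASE / "scratch" / "auc"  # full channel x time maps (large)
LARGEST = "19ms"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    AUC_DIR.mkdir(parents=True, exist_ok=True)
    rows, decisions = [], []
    for path in sorted(IN.glob("*_*ms.h5")):
        ep = load_epochs(path)
        res = crossval_within(ep, k=10, inner_folds=5, seed=0)
        rows.append(
            {
                "participant": ep.participant,
                "group": ep.group,
                "condition": ep.condition,
                "rate": res.mean_accuracy,
                "n_trials": ep.n_trials,
                "threshold_05": binomial_threshold(ep.n_trials, 0.05),
                "mmn_amplitude_uv": mmn_amplitude(ep),
            }
        )
        amap = auc_map(ep)
        amap.to_frame().to_csv(AUC_DIR / f"auc_{path.stem}.csv")
        rows[-1]["peak_auc"] = float(amap.scores.max())
        if ep.condition == LARGEST:
            decisions.extend(res.decisions)
    table = pd.DataFrame(rows)
    table["significant"] = table.rate >= table.threshold_05
    table.to_csv(OUT / "within_rates.csv", index=False)
    curves = pd.DataFrame(per_participant_curves(decisions)).T.sort_index()
    curves.index.name = "participant"
    curves.to_csv(OUT / "multi_trial_curves.csv")
    print("group-mean rate per condition:")
    print(table.groupby("condition").rate.mean().round(3).to_string())
    print("\nmean multi-trial accuracy (largest deviance):")
    print(curves.mean().round(3).to_string())


if __name__ == "__main__":
    main()
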