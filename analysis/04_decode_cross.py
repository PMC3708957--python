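#!/usr/bin/env python
"""Cross-participant generalization and classifier-weight interpretation.

Leave-one-participant-out decoding of the largest-deviance condition on
(a) all participants and (b) the native-analogue group only, then an SVD
of a model trained on the pooled data: leading topography, time course,
variance fraction, and its correlation with the grand-average difference
wave.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from erpdecode.containers import load_epochs
from erpdecode.decode import crossval_cross_participant, train_pooled
from erpdecode.discriminability import difference_wave
from erpdecode.interpret import correlate_component_timecourse, svd_weights

BASE = Path(__file__).resolve().parent.parent
IN = BASE / "scratch" / "preprocessed"
OUT = BASE / "results" / "cross"
LARGEST = "19ms"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = [
        load_epochs(p) for p in sorted(IN.glob(f"*_{LARGEST}.h5"))
    ]
    tpc = min(int((e.trial_class == "deviant").sum()) for e in cohort)
    rows = []
    res_all = crossval_cross_participant(cohort, tpc, seed=0)
    rows += [
        {"dataset": "cross_all", "participant": p, "rate": r}
        for p, r in zip(res_all.participant_ids, res_all.rates)
    ]
    native = [e for e in cohort if e.group == "native"]
    res_nat = crossval_cross_participant(native, tpc, seed=0)
    rows += [
        {"dataset": "cross_native", "participant": p, "rate": r}
        for p, r in zip(res_nat.participant_ids, res_nat.rates)
    ]
    pd.DataFrame(rows).to_csv(OUT / "cross_rates.csv", index=False)

    model = train_pooled(cohort, tpc, seed=0)
    comps = svd_weights(model)
    first = comps[0]
    pd.DataFrame(
        {"channel": list(model.channel_labels), "weight": first.topography}
    ).to_csv(OUT / "component1_topography.csv", index=False)
    pd.DataFrame(
        {"time_ms": model.times, "weight": first.time_course}
    ).to_csv(OUT / "component1_timecourse.csv", index=False)

    scalp = [
        i
        for i, l in enumerate(cohort[0].montage.labels)
        if l in model.channel_labels
    ]
    mean_dw = np.mean(
        [difference_wave(e)[scalp].mean(axis=0) for e in cohort], axis=0
    )
    r = correlate_component_timecourse(first.time_course, mean_dw)
    summary = pd.Series(
        {
            "cross_all_mean_rate": res_all.mean_rate,
            "cross_native_mean_rate": res_nat.mean_rate,
            "component1_variance_fraction": first.variance_fraction,
            "component1_vs_difference_wave_r": r,
        }
    )
    summary.to_csv(OUT / "summary.csv", header=False)
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
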