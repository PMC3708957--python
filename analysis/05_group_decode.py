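#!/usr/bin/env python
"""Decode group membership (native-language analogue) five ways.

Builds the five feature constructions — single-trial segments, fused
single-trial predictions, grand averages over all or the two
smaller-deviance conditions, and the 7-step behavioral vectors — and
scores each by leave-one-pair-out cross-validation with binomial
significance.
"""

from collections import defaultdict
from pathlib import Path

import pandas as pd

from erpdecode.containers import load_epochs
from erpdecode.groupdecode import FEATURE_SETS, decode_groups
from erpdecode.synth import Participant

BASE = Path(__file__).resolve().parent.parent
IN = BASE / "scratch" / "preprocessed"
DATA = BASE / "results" / "data"
OUT = BASE / "results" / "group"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    epochs_by_pid = defaultdict(dict)
    group_of = {}
    for path in sorted(IN.glob("*_*ms.h5")):
        ep = load_epochs(path)
        epochs_by_pid[ep.participant][ep.condition] = ep
        group_of[ep.participant] = ep.group
    participants = []
    for pid, eps in sorted(epochs_by_pid.items()):
        behavior = pd.read_csv(DATA / f"{pid}_behavior.csv")[
            "p_deviant_category"
        ].to_numpy()
        participants.append(
            Participant(pid, group_of[pid], 0, eps, behavior)
        )
    segments = min(
        int((ep.trial_class == "deviant").sum())
        for p in participants
        for ep in p.epochs.values()
    )
    results = decode_groups(
        participants, FEATURE_SETS, segments_per_participant=segments, seed=0
    )
    table = pd.DataFrame(
        [
            {
                "feature_set": name,
                "accuracy": r.accuracy,
                "n_observations": r.n_observations,
                "threshold_05": r.threshold_05,
                "significant": r.significant,
            }
            for name, r in results.items()
        ]
    )
    table.to_csv(OUT / "group_decoding.csv", index=False)
    print(table.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
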