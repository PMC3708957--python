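"""End-to-end experiment runner: synthesize -> preprocess -> decode ->
fuse -> interpret -> group-decode, from one JSON config and one master
seed, with every table written to an output directory and a manifest
recording seeds and software versions.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import EpochSet
from .decode import (
    binomial_threshold,
    crossval_cross_participant,
    crossval_within,
    train_pooled,
)
from .discriminability import auc_map, difference_wave
from .evidence import per_participant_curves
from .groupdecode import FEATURE_SETS, decode_groups
from .interpret import (
    mmn_amplitude,
    pearson,
    svd_weights,
)
from .preprocess import PreprocessConfig, run_preprocess
from .synth import Participant, SynthConfig, simulate_cohort

#: demo study conditions: a reduced-channel cohort that runs the full
#: chain in minutes while keeping the paradigm's structure (15% deviants,
#: three graded conditions, two groups, artifacts on).
DEMO_CONFIG = {
    "synth": {
        "n_channels": 32,
        "sampling_rate": 128.0,
        "trial_count": 160,
        "seed": 0,
    },
    "group_sizes": {"native": 6, "nonnative": 6},
    "preprocess": {"run_ica": True},
    "decode": {"k": 10, "inner_folds": 5, "trials_per_class": 12},
    "evidence": {"max_n": 7},
    "groupdecode": {"sets": list(FEATURE_SETS), "segments": 12},
    "seed": 0,
}


def _validate(config: dict) -> dict:
    cfg = json.loads(json.dumps(DEMO_CONFIG))  # deep copy of defaults
    for key, val in (config or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(cfg[key], dict):
            unknown = set(val) - set(SynthConfig.__dataclass_fields__) if key == "synth" else set()
            if unknown:
                raise ValueError(f"unknown synth options: {sorted(unknown)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_experiment(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run every stage and write the consolidated report bundle.

    Returns a dict of the headline tables (also written to ``out_dir``).
    Identical config and seed give identical outputs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)
    cfg = _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg["seed"])

    synth_cfg = SynthConfig(**{**cfg["synth"], "seed": master_seed})
    prep_cfg = PreprocessConfig(**cfg["preprocess"])
    cohort = simulate_cohort(synth_cfg, cfg["group_sizes"])

    # ---- preprocessing ---------------------------------------------------
    prepped: list[Participant] = []
    reports = {}
    for p in cohort:
        windowed = {}
        for cond, ep in p.epochs.items():
            w, rep = run_preprocess(ep, prep_cfg)
            windowed[cond] = w
            reports[f"{p.participant}_{cond}"] = {
                "stage_counts": rep.stage_counts,
                "mean_repairs_per_epoch": rep.mean_repairs_per_epoch,
                "removed_components": rep.removed_components,
                "rejected_epochs": rep.rejected_epochs,
            }
        prepped.append(
            Participant(p.participant, p.group, p.seed, windowed, p.behavior)
        )
    with open(out / "preprocess_reports.json", "w") as fh:
        json.dump(reports, fh, indent=2)

    conditions = synth_cfg.conditions
    groups = synth_cfg.groups

    # ---- discriminability maps and difference waves ---------------------
    for group in groups:
        for cond in conditions:
            eps = [p.epochs[cond] for p in prepped if p.group == group]
            pooled = _pool_epochs(eps)
            amap = auc_map(pooled)
            amap.to_frame().to_csv(out / f"auc_map_{group}_{cond}.csv")
            dw = difference_wave(pooled)
            pd.DataFrame(
                dw, index=list(pooled.montage.labels), columns=pooled.times
            ).to_csv(out / f"difference_wave_{group}_{cond}.csv")

    # ---- within-participant decoding ------------------------------------
    rows = []
    decisions_by_pid = {}
    for p in prepped:
        for cond in conditions:
            ep = p.epochs[cond]
            res = crossval_within(
                ep,
                k=cfg["decode"]["k"],
                inner_folds=cfg["decode"]["inner_folds"],
                seed=master_seed,
            )
            n = ep.n_trials
            rows.append(
                {
                    "participant": p.participant,
                    "group": p.group,
                    "condition": cond,
                    "rate": res.mean_accuracy,
                    "n_trials": n,
                    "threshold_05": binomial_threshold(n, 0.05),
                    "significant": res.mean_accuracy
                    >= binomial_threshold(n, 0.05),
                    "mmn_amplitude_uv": mmn_amplitude(ep),
                }
            )
            if cond == conditions[-1]:  # largest-deviance condition
                decisions_by_pid[p.participant] = res.decisions
    within = pd.DataFrame(rows)
    within.to_csv(out / "within_participant_rates.csv", index=False)

    # ---- multi-trial evidence curves ------------------------------------
    all_dec = [d for ds in decisions_by_pid.values() for d in ds]
    max_n = int(cfg["evidence"]["max_n"])
    curves = per_participant_curves(all_dec, range(1, max_n + 1))
    curve_df = pd.DataFrame(curves).T.sort_index()
    curve_df.index.name = "participant"
    curve_df.to_csv(out / "multi_trial_curves.csv")

    # ---- cross-participant decoding -------------------------------------
    tpc = int(cfg["decode"]["trials_per_class"])
    last = conditions[-1]
    cross_rows = []
    eps_all = [p.epochs[last] for p in prepped]
    res_all = crossval_cross_participant(eps_all, tpc, seed=master_seed)
    for pid, rate in zip(res_all.participant_ids, res_all.rates):
        cross_rows.append(
            {"dataset": "cross_all", "participant": pid, "rate": rate}
        )
    native = [p.epochs[last] for p in prepped if p.group == groups[0]]
    if len(native) >= 3:
        res_native = crossval_cross_participant(native, tpc, seed=master_seed)
        for pid, rate in zip(res_native.participant_ids, res_native.rates):
            cross_rows.append(
                {"dataset": "cross_native", "participant": pid, "rate": rate}
            )
    cross = pd.DataFrame(cross_rows)
    cross.to_csv(out / "cross_participant_rates.csv", index=False)

    # ---- weight interpretation ------------------------------------------
    pooled_model = train_pooled(eps_all, tpc, seed=master_seed)
    comps = svd_weights(pooled_model)
    first = comps[0]
    pd.DataFrame(
        {
            "channel": list(pooled_model.channel_labels),
            "topography": first.topography,
        }
    ).to_csv(out / "svd_component1_topography.csv", index=False)
    pd.DataFrame(
        {"time_ms": pooled_model.times, "time_course": first.time_course}
    ).to_csv(out / "svd_component1_timecourse.csv", index=False)

    # rate vs MMN-amplitude coupling over participant-condition pairs
    corr_rate_mmn = pearson(
        within["rate"].to_numpy(), within["mmn_amplitude_uv"].to_numpy()
    )
    interpret_summary = {
        "svd_component1_variance_fraction": first.variance_fraction,
        "rate_vs_mmn_amplitude_r": corr_rate_mmn,
    }
    with open(out / "interpret_summary.json", "w") as fh:
        json.dump(interpret_summary, fh, indent=2)

    # ---- group decoding ---------------------------------------------------
    gd = decode_groups(
        prepped,
        tuple(cfg["groupdecode"]["sets"]),
        segments_per_participant=int(cfg["groupdecode"]["segments"]),
        seed=master_seed,
    )
    gd_df = pd.DataFrame(
        [
            {
                "feature_set": name,
                "accuracy": r.accuracy,
                "n_observations": r.n_observations,
                "threshold_05": r.threshold_05,
                "significant": r.significant,
            }
            for name, r in gd.items()
        ]
    )
    gd_df.to_csv(out / "group_decoding.csv", index=False)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "master_seed": master_seed,
        "participant_seeds": {p.participant: p.seed for p in prepped},
        "config": cfg,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "within": within,
        "cross": cross,
        "curves": curve_df,
        "group_decoding": gd_df,
        "interpret": interpret_summary,
    }


def _pool_epochs(eps: list[EpochSet]) -> EpochSet:
    first = eps[0]
    return EpochSet(
        data=np.concatenate([e.data for e in eps], axis=0),
        times=first.times,
        sampling_rate=first.sampling_rate,
        trial_class=np.concatenate([e.trial_class for e in eps]),
        montage=first.montage,
        condition=first.condition,
        trial_order=np.arange(sum(e.n_trials for e in eps)),
    )
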