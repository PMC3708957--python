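"""Decoding group membership from ERP or behavioral features.

Five feature constructions are supported, mirroring the study's group
(native-language analogue) decoding analyses:

``single_trial``
    one observation per standard/deviant trial pair across all
    conditions: the channel-major flattening of the per-condition
    [standard | deviant] epochs concatenated along time (64 x 540 at the
    standard layout, 70 segments per participant).
``single_trial_combined``
    the held-out single-trial predictions of each participant fused into
    one decision per participant by the evidence sum rule.
``grand_average_A``
    per-participant grand-average standard and deviant ERPs concatenated
    over all conditions (64 x 540, one observation per participant).
``grand_average_B``
    per-participant grand-average *deviant* ERPs for the two
    smaller-deviance conditions only (64 x 180).
``behavioral``
    the 7-element identification-score vector.

Evaluation is leave-one-pair-out: each fold holds out one participant per
group (paired by sorted participant id), an eleven-fold procedure at the
standard cohort size.  The classifier is the same regularized logistic
regression used for stimulus decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CLASS_DEVIANT, CLASS_STANDARD
from .decode import (
    LAMBDA_GRID,
    _fit_dual,
    _grid_search_gram,
    binomial_threshold,
    total_variance,
)
from .montage import MASTOIDS

FEATURE_SETS = (
    "single_trial",
    "single_trial_combined",
    "grand_average_A",
    "grand_average_B",
    "behavioral",
)


@dataclass
class GroupFeatureSet:
    """Observations x features with participant and group provenance."""

    name: str
    X: np.ndarray
    participants: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if len(self.X) != len(self.participants) or len(self.X) != len(
            self.groups
        ):
            raise ValueError("provenance arrays must match observation count")

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups.tolist()))

    def labels(self) -> np.ndarray:
        """+1 for the first group in sorted order, -1 for the second."""
        names = self.group_names
        if len(names) != 2:
            raise ValueError("group decoding requires exactly 2 groups")
        return np.where(self.groups == names[0], 1, -1)


def _scalp_data(epochs) -> np.ndarray:
    keep = [
        i for i, l in enumerate(epochs.montage.labels) if l not in MASTOIDS
    ]
    return epochs.data[:, keep, :]


def _class_trials(epochs, cls) -> np.ndarray:
    idx = np.nonzero(epochs.trial_class == cls)[0]
    return idx[np.argsort(epochs.trial_order[idx])]


def build_feature_set(
    participants: list,
    name: str,
    segments_per_participant: int = 70,
) -> GroupFeatureSet:
    """Assemble one of the named feature constructions from a cohort.

    ``participants`` is a list of objects with ``participant``, ``group``,
    ``epochs`` (condition -> preprocessed, windowed EpochSet) and
    ``behavior`` attributes (the synthetic cohort container satisfies
    this).  ``single_trial_combined`` shares the single-trial features;
    its fusion happens at evaluation time.
    """
    if name not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {name!r}")
    rows, pids, groups = [], [], []

    if name in ("single_trial", "single_trial_combined"):
        for p in participants:
            per_cond = []
            for cond in sorted(p.epochs):
                ep = p.epochs[cond]
                data = _scalp_data(ep)
                std = _class_trials(ep, CLASS_STANDARD)
                dev = _class_trials(ep, CLASS_DEVIANT)
                n = min(len(std), len(dev), segments_per_participant)
                if n < 1:
                    raise ValueError(
                        f"participant {p.participant} lacks paired trials"
                    )
                # [standard | deviant] concatenated along time, per segment
                per_cond.append(
                    np.concatenate(
                        [data[std[:n]], data[dev[:n]]], axis=2
                    )
                )
            n_seg = min(c.shape[0] for c in per_cond)
            seg = np.concatenate([c[:n_seg] for c in per_cond], axis=2)
            rows.append(seg.reshape(n_seg, -1))
            pids.extend([p.participant] * n_seg)
            groups.extend([p.group] * n_seg)
        X = np.vstack(rows)

    elif name == "grand_average_A":
        for p in participants:
            blocks = []
            for cond in sorted(p.epochs):
                ep = p.epochs[cond]
                data = _scalp_data(ep)
                std = data[ep.trial_class == CLASS_STANDARD].mean(axis=0)
                dev = data[ep.trial_class == CLASS_DEVIANT].mean(axis=0)
                blocks.extend([std, dev])
            rows.append(np.concatenate(blocks, axis=1).ravel())
            pids.append(p.participant)
            groups.append(p.group)
        X = np.vstack(rows)

    elif name == "grand_average_B":
        for p in participants:
            conds = sorted(p.epochs)[:2]  # the two smaller-deviance conditions
            blocks = []
            for cond in conds:
                ep = p.epochs[cond]
                data = _scalp_data(ep)
                blocks.append(
                    data[ep.trial_class == CLASS_DEVIANT].mean(axis=0)
                )
            rows.append(np.concatenate(blocks, axis=1).ravel())
            pids.append(p.participant)
            groups.append(p.group)
        X = np.vstack(rows)

    else:  # behavioral
        for p in participants:
            if len(p.behavior) != 7:
                raise ValueError("behavioral vector must have 7 entries")
            rows.append(np.asarray(p.behavior, dtype=float))
            pids.append(p.participant)
            groups.append(p.group)
        X = np.vstack(rows)

    return GroupFeatureSet(
        name=name,
        X=X,
        participants=np.array(pids),
        groups=np.array(groups),
    )


@dataclass
class GroupDecodeResult:
    """Leave-pair-out outcome for one feature construction."""

    name: str
    fold_accuracies: list
    accuracy: float
    n_observations: int
    threshold_05: float
    participant_f: dict = field(default_factory=dict)  # pid -> summed f

    @property
    def significant(self) -> bool:
        return self.accuracy >= self.threshold_05


def leave_pair_out_cv(
    feature_set: GroupFeatureSet,
    grid: tuple[float, ...] = LAMBDA_GRID,
    n_nested_folds: int = 5,
    seed: int = 0,
    combine_per_participant: bool = False,
) -> GroupDecodeResult:
    """Leave-one-pair-out group decoding with nested lambda selection.

    Each fold holds out the k-th participant (by sorted id) of each
    group; no participant's observations ever appear in both train and
    test.  With ``combine_per_participant`` the held-out decision values
    are summed per participant (evidence fusion) and accuracy is scored
    over participants instead of observations.
    """
    y = feature_set.labels()
    names = feature_set.group_names
    by_group = {
        g: sorted(set(feature_set.participants[feature_set.groups == g]))
        for g in names
    }
    sizes = {g: len(v) for g, v in by_group.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"unequal group sizes: {sizes}")
    n_pairs = sizes[names[0]]
    pairs = list(zip(by_group[names[0]], by_group[names[1]]))

    X = feature_set.X
    K = X @ X.T
    pids = feature_set.participants
    rng = np.random.default_rng(seed)
    fold_acc = []
    f_by_pid: dict[str, float] = {}
    true_by_pid: dict[str, int] = {}
    n_test_obs = 0
    for held in pairs:
        te = np.isin(pids, held)
        tr = np.nonzero(~te)[0]
        te = np.nonzero(te)[0]
        train_pairs = [p for p in pairs if p != held]
        shuffled = list(train_pairs)
        rng.shuffle(shuffled)
        n_nest = min(n_nested_folds, len(train_pairs))
        nested = []
        for i in range(n_nest):
            held_ids = [pid for pair in shuffled[i::n_nest] for pid in pair]
            va = tr[np.isin(pids[tr], held_ids)]
            in_tr = tr[~np.isin(pids[tr], held_ids)]
            nested.append((in_tr, va))
        lam = _grid_search_gram(K, y, nested, total_variance(X[tr]), grid)
        alpha, b = _fit_dual(K[np.ix_(tr, tr)], y[tr], lam)
        f_te = K[np.ix_(te, tr)] @ alpha + b
        pred = np.where(f_te > 0, 1, -1)
        fold_acc.append(float(np.mean(pred == y[te])))
        n_test_obs += len(te)
        for i, f in zip(te, f_te):
            pid = pids[i]
            f_by_pid[pid] = f_by_pid.get(pid, 0.0) + float(f)
            true_by_pid[pid] = int(y[i])

    if combine_per_participant:
        correct = [
            (1 if f > 0 else -1) == true_by_pid[pid]
            for pid, f in f_by_pid.items()
        ]
        accuracy = float(np.mean(correct))
        n_obs = len(f_by_pid)
    else:
        # folds hold out one pair each with equal observation counts, so
        # the fold-accuracy mean equals accuracy over all held-out obs
        accuracy = float(np.mean(fold_acc))
        n_obs = n_test_obs
    return GroupDecodeResult(
        name=feature_set.name
        + ("_combined" if combine_per_participant else ""),
        fold_accuracies=fold_acc,
        accuracy=accuracy,
        n_observations=n_obs,
        threshold_05=binomial_threshold(n_obs, 0.05),
        participant_f=f_by_pid,
    )


def decode_groups(
    participants: list,
    sets: tuple[str, ...] = FEATURE_SETS,
    segments_per_participant: int = 70,
    seed: int = 0,
) -> dict[str, GroupDecodeResult]:
    """Run every requested feature construction; returns name -> result."""
    results: dict[str, GroupDecodeResult] = {}
    single_trial_set = None
    for name in sets:
        if name == "single_trial_combined":
            if single_trial_set is None:
                single_trial_set = build_feature_set(
                    participants, "single_trial", segments_per_participant
                )
            res = leave_pair_out_cv(
                single_trial_set, seed=seed, combine_per_participant=True
            )
            res.name = "single_trial_combined"
            results[name] = res
        else:
            fs = build_feature_set(
                participants, name, segments_per_participant
            )
            if name == "single_trial":
                single_trial_set = fs
            results[name] = leave_pair_out_cv(fs, seed=seed)
    return results
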