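"""Canned simulation studies over the pipeline.

Each function runs one self-contained study on synthetic cohorts at desk
scale — condition-grading recovery, chance-level calibration, Gaussian
evidence accumulation, classifier-weight parameter recovery — and returns
plain numbers.  They are shared by the test suite and the results script
so that both always measure the same computation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .decode import DecisionRecord, FeatureMatrix, crossval_within, train_pooled
from .evidence import multi_trial_curve, naive_bayes_product
from .interpret import svd_weights
from .preprocess import PreprocessConfig, run_preprocess
from .synth import SynthConfig, render_participant, simulate_cohort


def condition_grading_study(
    seed: int,
    n_replicates: int = 20,
    n_per_group: int = 11,
    n_channels: int = 8,
    trial_count: int = 150,
) -> dict:
    """Group-mean decoding rates per condition over cohort replicates.

    Each replicate simulates a fresh two-group cohort at the default
    graded gains (0.5 / 1.0 / 1.5), runs the artifact-free preprocessing
    chain and stratified 10-fold decoding per participant and condition,
    and records whether the group-mean rates increase strictly with the
    condition gain.
    """
    pc = PreprocessConfig(run_ica=False)
    cond_means = []
    increasing = 0
    for rep in range(n_replicates):
        cfg = SynthConfig(
            n_channels=n_channels,
            sampling_rate=128.0,
            trial_count=trial_count,
            artifact_rates={},
            seed=seed + rep,
        )
        cohort = simulate_cohort(
            cfg, {g: n_per_group for g in cfg.groups}
        )
        means = {}
        for cond in cfg.conditions:
            rates = [
                crossval_within(
                    run_preprocess(p.epochs[cond], pc)[0],
                    k=10,
                    inner_folds=2,
                    seed=seed + rep,
                ).mean_accuracy
                for p in cohort
            ]
            means[cond] = float(np.mean(rates))
        cond_means.append(means)
        ordered = [means[c] for c in cfg.conditions]
        if ordered[0] < ordered[1] < ordered[2]:
            increasing += 1
    avg = {
        c: float(np.mean([m[c] for m in cond_means]))
        for c in cond_means[0]
    }
    return {
        "n_replicates": n_replicates,
        "n_increasing": increasing,
        "mean_rates": avg,
    }


def chance_calibration_study(
    seed: int,
    n_repeats: int = 100,
    n_trials: int = 200,
    n_features: int = 20,
) -> dict:
    """10-fold decoding of pure-noise features under permuted labels.

    Counts how many repeats land inside the central 99% interval of
    Binomial(n_trials, 1/2)/n_trials, the no-information reference.
    """
    rng = np.random.default_rng(seed)
    lo, hi = stats.binom.interval(0.99, n_trials, 0.5)
    inside = 0
    accs = []
    for rep in range(n_repeats):
        X = rng.normal(size=(n_trials, n_features))
        y = np.array([1, -1] * (n_trials // 2))
        rng.shuffle(y)
        feats = FeatureMatrix(
            X=X,
            y=y,
            n_channels=1,
            n_samples=n_features,
            channel_labels=("C01",),
            times=np.arange(n_features, dtype=float),
        )
        res = crossval_within(feats, k=10, inner_folds=3, seed=seed + rep)
        accs.append(res.mean_accuracy)
        if lo <= res.mean_accuracy * n_trials <= hi:
            inside += 1
    return {
        "n_repeats": n_repeats,
        "n_inside_99": inside,
        "mean_accuracy": float(np.mean(accs)),
    }


def gaussian_accumulation_study(
    seed: int, d: float = 1.0, n_per_class: int = 70_000, max_n: int = 7
) -> dict:
    """Evidence fusion on the Gaussian decision-value model.

    Decision values are N(+d/2, 1) / N(-d/2, 1); the closed-form fused
    accuracy at group size N is Phi(sqrt(N) d / 2).
    """
    rng = np.random.default_rng(seed)
    recs = [
        DecisionRecord(f=float(f), true_label=1, order=i)
        for i, f in enumerate(rng.normal(d / 2, 1.0, n_per_class))
    ] + [
        DecisionRecord(f=float(f), true_label=-1, order=i)
        for i, f in enumerate(rng.normal(-d / 2, 1.0, n_per_class))
    ]
    curve = multi_trial_curve(recs, range(1, max_n + 1))
    expected = {
        N: float(stats.norm.cdf(np.sqrt(N) * d / 2.0)) for N in curve
    }
    max_err = max(abs(curve[N] - expected[N]) for N in curve)
    return {
        "curve": {int(N): float(v) for N, v in curve.items()},
        "expected": expected,
        "max_abs_error": float(max_err),
        "non_decreasing": all(
            b >= a - 1e-12
            for a, b in zip(list(curve.values()), list(curve.values())[1:])
        ),
    }


def fusion_identity_study(seed: int, n_groups: int = 10_000) -> dict:
    """Sum-of-decision-values fusion vs the probability-product form.

    Random groups of 2-7 decisions, plus groups stressing p near 0 and 1
    where the product form is fragile; reports the worst disagreement.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_groups):
        n = int(rng.integers(2, 8))
        f = rng.normal(scale=4.0, size=n)
        if rng.random() < 0.2:  # inject extremes
            f[0] = logit(1e-12)
            if n > 1:
                f[1] = logit(1 - 1e-12)
        p_sum = expit(np.sum(f))
        p_prod = naive_bayes_product(expit(f), expit(-f))
        worst = max(worst, abs(p_sum - p_prod))
    return {"n_groups": n_groups, "max_abs_error": float(worst)}


def weight_recovery_study(
    seed: int,
    n_participants: int = 6,
    n_channels: int = 16,
    trial_count: int = 300,
    noise_sd: float = 1.0,
) -> dict:
    """Parameter recovery: SVD of a pooled cross-participant classifier.

    A high-SNR cohort is decoded with one pooled model; the first SVD
    component of its weight matrix is correlated with the injected
    fronto-central topography and with the injected (window-cropped)
    component time course.
    """
    cfg = SynthConfig(
        n_channels=n_channels,
        sampling_rate=128.0,
        trial_count=trial_count,
        noise_sd=noise_sd,
        artifact_rates={},
        seed=seed,
    )
    pc = PreprocessConfig(run_ica=False)
    cohort = []
    for i in range(n_participants):
        ep = render_participant(
            cfg, "native", "19ms", seed + 10 + i, f"p{i:02d}"
        )
        cohort.append(run_preprocess(ep, pc)[0])
    tpc = min(
        int((e.trial_class == "deviant").sum()) for e in cohort
    )
    model = train_pooled(cohort, trials_per_class=tpc, seed=seed)
    first = svd_weights(model)[0]

    # the injected signal as it appears in the decode window: render one
    # noiseless participant through the identical chain and take the
    # difference wave (shared topography makes it rank one)
    cfg0 = SynthConfig(
        **{**cfg.__dict__, "noise_sd": 0.0, "trial_count": 40}
    )
    ep0 = render_participant(cfg0, "native", "19ms", seed + 1)
    w0 = run_preprocess(ep0, pc)[0]
    from .decode import make_features
    from .discriminability import difference_wave

    feats0 = make_features(w0)
    dw0 = difference_wave(w0)
    scalp = [
        i
        for i, l in enumerate(w0.montage.labels)
        if l in feats0.channel_labels
    ]
    u0, _, vt0 = np.linalg.svd(dw0[scalp], full_matrices=False)
    topo_true, tc_true = u0[:, 0], vt0[0]
    r_topo = float(np.corrcoef(first.topography, topo_true)[0, 1])
    r_time = float(np.corrcoef(first.time_course, tc_true)[0, 1])
    return {
        "variance_fraction": first.variance_fraction,
        "abs_r_topography": abs(r_topo),
        "abs_r_timecourse": abs(r_time),
    }
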