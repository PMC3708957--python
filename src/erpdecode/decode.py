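"""Quadratically regularized linear logistic-regression decoding.

A single linear classifier operates on the channel-major flattening of the
0-700 ms window (64 x 90 = 5760 features at the standard layout).  The
trainer minimizes

    sum_i log(1 + exp(-y_i (w.x_i + b))) + lambda ||w||^2

with the bias unpenalized.  Because the number of trials is far below the
feature count, the minimizer lies in the span of the training trials
(w = X^T alpha), so the optimization runs over the n-dimensional dual
coefficients with a precomputed Gram matrix; at the dual optimum the
primal penalized-loss gradient X^T(r + 2 lambda alpha) vanishes exactly.
This makes the six-point regularization grid search cheap, since the Gram
matrix is shared across folds and grid points.

The regularization grid is [.001 .01 .1 1 10 100] times the total data
variance (sum of per-feature variances of the training trials), making
the grid scale-invariant.  Within-participant evaluation uses stratified
10-fold cross-validation; cross-participant evaluation uses a double-
nested leave-one-participant-out scheme in which the held-out participant
never enters the regularization search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .containers import EpochSet
from .montage import MASTOIDS

LAMBDA_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)

LABEL_DEVIANT = 1
LABEL_STANDARD = -1


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Trials x features design with +/-1 labels and provenance.

    Columns are the channel-major flattening of channels x samples over
    scalp channels (reference leads excluded).  +1 marks deviant trials.
    """

    X: np.ndarray
    y: np.ndarray
    n_channels: int
    n_samples: int
    channel_labels: tuple[str, ...]
    times: np.ndarray
    participants: np.ndarray = None
    order: np.ndarray = None  # acquisition order, for consecutive grouping

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite features")
        if self.X.shape[1] != self.n_channels * self.n_samples:
            raise ValueError("column count must equal n_channels * n_samples")
        if len(self.y) != len(self.X):
            raise ValueError("labels length must equal rows")
        if self.participants is None:
            self.participants = np.array([""] * len(self.X))
        if self.order is None:
            self.order = np.arange(len(self.X))


def make_features(epochs: EpochSet) -> FeatureMatrix:
    """Flatten a windowed EpochSet into a FeatureMatrix (scalp channels)."""
    keep = [
        i for i, l in enumerate(epochs.montage.labels) if l not in MASTOIDS
    ]
    data = epochs.data[:, keep, :]
    n_tr, n_ch, n_t = data.shape
    y = np.where(epochs.is_deviant(), LABEL_DEVIANT, LABEL_STANDARD)
    return FeatureMatrix(
        X=data.reshape(n_tr, n_ch * n_t),
        y=y,
        n_channels=n_ch,
        n_samples=n_t,
        channel_labels=tuple(epochs.montage.labels[i] for i in keep),
        times=epochs.times.copy(),
        participants=np.array([epochs.participant] * n_tr),
        order=epochs.trial_order.copy(),
    )


def concat_features(parts: list[FeatureMatrix]) -> FeatureMatrix:
    first = parts[0]
    return FeatureMatrix(
        X=np.vstack([p.X for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        n_channels=first.n_channels,
        n_samples=first.n_samples,
        channel_labels=first.channel_labels,
        times=first.times,
        participants=np.concatenate([p.participants for p in parts]),
        order=np.concatenate([p.order for p in parts]),
    )


def total_variance(X: np.ndarray) -> float:
    """Sum of per-feature variances: the grid's scale reference."""
    return float(X.var(axis=0).sum())


# ---------------------------------------------------------------------------
# model and records
# ---------------------------------------------------------------------------

@dataclass
class LinearModel:
    """Spatio-temporal weights (channels x samples), bias, lambda."""

    W: np.ndarray
    b: float
    lam: float
    channel_labels: tuple[str, ...] = ()
    times: np.ndarray = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.W)) or not np.isfinite(self.b):
            raise ValueError("model has non-finite entries")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def w(self) -> np.ndarray:
        return self.W.ravel()

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(deviant | x) through the logistic link."""
        return expit(self.decision_values(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Sign decision at f = 0; exact ties resolve to standard."""
        return np.where(self.decision_values(X) > 0, LABEL_DEVIANT, LABEL_STANDARD)


@dataclass
class DecisionRecord:
    """One held-out trial's decision value and class probability."""

    f: float
    true_label: int
    participant: str = ""
    order: int = 0

    @property
    def p(self) -> float:
        return float(expit(self.f))


# ---------------------------------------------------------------------------
# training (dual / primal)
# ---------------------------------------------------------------------------

def penalized_loss_grad(
    w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, np.ndarray, float]:
    """Primal objective and its gradient (for tests and primal solves)."""
    f = X @ w + b
    z = y * f
    loss = np.logaddexp(0.0, -z).sum() + lam * (w @ w)
    r = -y * expit(-z)
    return loss, X.T @ r + 2.0 * lam * w, float(r.sum())


def _fit_dual(
    K: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Minimize the penalized logistic loss over dual coefficients.

    Damped Newton iterations from zero; the stopping rule is on the
    *primal* gradient, whose squared norm v^T K v (v = r + 2 lambda alpha)
    is available in the dual without forming X.  Returns (alpha, b) with
    w = X^T alpha.  Falls back to L-BFGS for large trial counts where the
    Newton solve would dominate.
    """
    n = len(y)
    if n > 1200:
        return _fit_dual_lbfgs(K, y, lam)
    a = np.zeros(n)
    b = 0.0
    f = np.zeros(n)

    def loss_at(f_val, a_val):
        return np.logaddexp(0.0, -y * f_val).sum() + lam * (a_val @ (K @ a_val))

    loss = loss_at(f, a)
    for _ in range(100):
        z = y * f
        r = -y * expit(-z)
        v = r + 2.0 * lam * a
        Kv = K @ v
        primal_sq = float(v @ Kv)
        gb = float(r.sum())
        if primal_sq < tol**2 and abs(gb) < tol:
            break
        s = expit(z) * expit(-z)  # logistic curvature weights
        # Hessian blocks in (a, b); Newton step solves H d = -g
        KS = K * s[None, :]
        H = np.empty((n + 1, n + 1))
        H[:n, :n] = KS @ K + 2.0 * lam * K
        H[:n, n] = K @ s
        H[n, :n] = H[:n, n]
        H[n, n] = s.sum()
        H[np.diag_indices(n + 1)] += 1e-10 * max(1.0, np.trace(H) / (n + 1))
        g = np.concatenate([Kv, [gb]])
        try:
            d = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            return _fit_dual_lbfgs(K, y, lam)
        step = 1.0
        for _ in range(40):
            a_new = a + step * d[:n]
            b_new = b + step * d[n]
            f_new = K @ a_new + b_new
            loss_new = loss_at(f_new, a_new)
            if loss_new <= loss + 1e-4 * step * (g @ d):
                break
            step *= 0.5
        a, b, f, loss = a_new, float(b_new), f_new, loss_new
    return a, b


def _fit_dual_lbfgs(
    K: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    n = len(y)

    def obj(theta):
        a, b = theta[:n], theta[n]
        Ka = K @ a
        z = y * (Ka + b)
        r = -y * expit(-z)
        loss = np.logaddexp(0.0, -z).sum() + lam * (a @ Ka)
        grad_a = K @ (r + 2.0 * lam * a)
        return loss, np.concatenate([grad_a, [r.sum()]])

    res = optimize.minimize(
        obj,
        np.zeros(n + 1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.x[:n], float(res.x[n])


def _fit_primal(
    X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    d = X.shape[1]

    def obj(theta):
        w, b = theta[:d], theta[d]
        loss, gw, gb = penalized_loss_grad(w, b, X, y, lam)
        return loss, np.concatenate([gw, [gb]])

    res = optimize.minimize(
        obj,
        np.zeros(d + 1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.x[:d], float(res.x[d])


def train(features: FeatureMatrix, lam: float) -> LinearModel:
    """Fit the regularized logistic model; deterministic (starts at 0).

    Uses the dual parametrization when trials < features, the primal
    otherwise; both give the same unique minimizer.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    X, y = features.X, features.y
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    if X.shape[0] < X.shape[1]:
        K = X @ X.T
        alpha, b = _fit_dual(K, y, lam)
        w = X.T @ alpha
    else:
        w, b = _fit_primal(X, y, lam)
    return LinearModel(
        W=w.reshape(features.n_channels, features.n_samples),
        b=b,
        lam=lam,
        channel_labels=features.channel_labels,
        times=features.times,
    )


# ---------------------------------------------------------------------------
# lambda grid search
# ---------------------------------------------------------------------------

def _grid_search_gram(
    K: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    tot_var: float,
    grid: tuple[float, ...] = LAMBDA_GRID,
) -> float:
    """Pick lambda = argmax mean validation accuracy; ties -> larger."""
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    if len(folds) == 0:
        raise ValueError("need at least one validation fold")
    accs = np.zeros(len(grid))
    for tr, va in folds:
        K_tr = K[np.ix_(tr, tr)]
        K_va = K[np.ix_(va, tr)]
        for gi, factor in enumerate(grid):
            alpha, b = _fit_dual(K_tr, y[tr], factor * tot_var)
            pred = np.where(K_va @ alpha + b > 0, LABEL_DEVIANT, LABEL_STANDARD)
            accs[gi] += np.mean(pred == y[va])
    best = int(np.flatnonzero(accs == accs.max())[-1])  # ties -> larger lambda
    return grid[best] * tot_var


def grid_search_lambda(
    features: FeatureMatrix,
    n_folds: int = 5,
    grid: tuple[float, ...] = LAMBDA_GRID,
    seed: int = 0,
) -> float:
    """Grid search over lambda/total-variance factors with stratified CV."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    X, y = features.X, features.y
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(tr, va) for tr, va in skf.split(X, y)]
    return _grid_search_gram(X @ X.T, y, folds, total_variance(X), grid)


# ---------------------------------------------------------------------------
# within-participant cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold accuracies plus all held-out decision records."""

    fold_accuracies: list
    decisions: list  # DecisionRecord
    lambdas: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def crossval_within(
    epochs_or_features,
    k: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    grid: tuple[float, ...] = LAMBDA_GRID,
) -> CVResult:
    """Stratified k-fold decoding with a nested lambda search per fold.

    Each outer training set runs its own stratified ``inner_folds``-fold
    grid search (the outer test fold never influences lambda), then a
    model at the selected lambda predicts the outer test fold.  All
    held-out decision values are retained for evidence accumulation.
    """
    feats = (
        epochs_or_features
        if isinstance(epochs_or_features, FeatureMatrix)
        else make_features(epochs_or_features)
    )
    X, y = feats.X, feats.y
    counts = np.bincount((y == LABEL_DEVIANT).astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} trials per class")
    K = X @ X.T
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    result = CVResult(fold_accuracies=[], decisions=[])
    for tr, te in outer.split(X, y):
        inner = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=seed + 1
        )
        inner_folds_idx = [
            (tr[i], tr[v]) for i, v in inner.split(tr, y[tr])
        ]
        tot_var = total_variance(X[tr])
        lam = _grid_search_gram(K, y, inner_folds_idx, tot_var, grid)
        alpha, b = _fit_dual(K[np.ix_(tr, tr)], y[tr], lam)
        f_te = K[np.ix_(te, tr)] @ alpha + b
        pred = np.where(f_te > 0, LABEL_DEVIANT, LABEL_STANDARD)
        result.fold_accuracies.append(float(np.mean(pred == y[te])))
        result.lambdas.append(lam)
        for i, f in zip(te, f_te):
            result.decisions.append(
                DecisionRecord(
                    f=float(f),
                    true_label=int(y[i]),
                    participant=str(feats.participants[i]),
                    order=int(feats.order[i]),
                )
            )
    return result


# ---------------------------------------------------------------------------
# cross-participant cross-validation
# ---------------------------------------------------------------------------

def first_trials_per_class(
    feats: FeatureMatrix, trials_per_class: int
) -> FeatureMatrix:
    """The first ``trials_per_class`` consecutive trials of each class."""
    keep = []
    for label in (LABEL_STANDARD, LABEL_DEVIANT):
        idx = np.nonzero(feats.y == label)[0]
        idx = idx[np.argsort(feats.order[idx])]
        if len(idx) < trials_per_class:
            raise ValueError(
                f"participant {feats.participants[0]!r} has only "
                f"{len(idx)} trials of class {label}"
            )
        keep.extend(idx[:trials_per_class].tolist())
    keep = np.array(sorted(keep))
    return FeatureMatrix(
        X=feats.X[keep],
        y=feats.y[keep],
        n_channels=feats.n_channels,
        n_samples=feats.n_samples,
        channel_labels=feats.channel_labels,
        times=feats.times,
        participants=feats.participants[keep],
        order=feats.order[keep],
    )


def _participant_folds(
    participants: np.ndarray, groups: list[list[str]]
) -> list[tuple[np.ndarray, np.ndarray]]:
    folds = []
    for held in groups:
        te = np.isin(participants, held)
        folds.append((np.nonzero(~te)[0], np.nonzero(te)[0]))
    return folds


@dataclass
class CrossParticipantResult:
    """Leave-one-participant-out rates and held-out decisions."""

    participant_ids: list
    rates: list
    lambdas: list
    decisions: list

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.rates))


def crossval_cross_participant(
    cohort: list[EpochSet],
    trials_per_class: int = 70,
    n_nested_folds: int = 5,
    grid: tuple[float, ...] = LAMBDA_GRID,
    seed: int = 0,
) -> CrossParticipantResult:
    """Double-nested leave-one-participant-out generalization decoding.

    Outer loop: each participant in turn is the test set.  Inner loop:
    lambda is selected by grouped cross-validation over the *training*
    participants only (the test participant is excluded from the nested
    analysis entirely).  Each participant contributes its first
    ``trials_per_class`` consecutive trials per class.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 participants")
    parts = [
        first_trials_per_class(make_features(e), trials_per_class)
        for e in cohort
    ]
    feats = concat_features(parts)
    X, y, pids = feats.X, feats.y, feats.participants
    unique_ids = [p.participants[0] for p in parts]
    K = X @ X.T
    rng = np.random.default_rng(seed)
    result = CrossParticipantResult([], [], [], [])
    for test_pid in unique_ids:
        train_ids = [p for p in unique_ids if p != test_pid]
        tr = np.nonzero(pids != test_pid)[0]
        te = np.nonzero(pids == test_pid)[0]
        # nested grouped folds over training participants only
        shuffled = list(train_ids)
        rng.shuffle(shuffled)
        n_nest = min(n_nested_folds, len(train_ids))
        nested_groups = [shuffled[i::n_nest] for i in range(n_nest)]
        nested = []
        for held in nested_groups:
            va = tr[np.isin(pids[tr], held)]
            in_tr = tr[~np.isin(pids[tr], held)]
            nested.append((in_tr, va))
        lam = _grid_search_gram(K, y, nested, total_variance(X[tr]), grid)
        alpha, b = _fit_dual(K[np.ix_(tr, tr)], y[tr], lam)
        f_te = K[np.ix_(te, tr)] @ alpha + b
        pred = np.where(f_te > 0, LABEL_DEVIANT, LABEL_STANDARD)
        result.participant_ids.append(test_pid)
        result.rates.append(float(np.mean(pred == y[te])))
        result.lambdas.append(lam)
        for i, f in zip(te, f_te):
            result.decisions.append(
                DecisionRecord(
                    f=float(f),
                    true_label=int(y[i]),
                    participant=test_pid,
                    order=int(feats.order[i]),
                )
            )
    return result


def train_pooled(
    cohort: list[EpochSet],
    trials_per_class: int = 70,
    n_folds: int = 5,
    grid: tuple[float, ...] = LAMBDA_GRID,
    seed: int = 0,
) -> LinearModel:
    """One model on the pooled cohort (for weight interpretation).

    Lambda is selected by grouped leave-participants-out folds over the
    pooled data, then the model is refit on everything.
    """
    parts = [
        first_trials_per_class(make_features(e), trials_per_class)
        for e in cohort
    ]
    feats = concat_features(parts)
    unique_ids = [p.participants[0] for p in parts]
    rng = np.random.default_rng(seed)
    shuffled = list(unique_ids)
    rng.shuffle(shuffled)
    n_folds = min(n_folds, len(unique_ids))
    folds = _participant_folds(
        feats.participants, [shuffled[i::n_folds] for i in range(n_folds)]
    )
    K = feats.X @ feats.X.T
    lam = _grid_search_gram(K, feats.y, folds, total_variance(feats.X), grid)
    alpha, b = _fit_dual(K, feats.y, lam)
    w = feats.X.T @ alpha
    return LinearModel(
        W=w.reshape(feats.n_channels, feats.n_samples),
        b=b,
        lam=lam,
        channel_labels=feats.channel_labels,
        times=feats.times,
    )


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def binomial_threshold(
    n_trials: int, alpha: float, chance: float = 0.5
) -> float:
    """Minimum accuracy significantly above chance at level alpha.

    The smallest a = k/n with P(Binomial(n, chance) >= k) <= alpha under
    the exact CDF.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    k = np.arange(n_trials + 1)
    tail = stats.binom.sf(k - 1, n_trials, chance)  # P(X >= k)
    ok = np.nonzero(tail <= alpha)[0]
    if ok.size == 0:
        return float("nan")  # unreachable at any accuracy
    return float(ok[0]) / n_trials
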