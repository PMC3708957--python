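"""Multi-trial evidence accumulation for logistic decisions.

Under independence, the naive-Bayes combination of single-trial class
probabilities p_i is

    p = prod p_i / (prod p_i + prod (1 - p_i)),

and because each p_i is a logistic function of its decision value f_i this
reduces to the logistic of the *sum* of decision values — numerically
stable where the product form under/overflows.  Decisions are combined in
non-overlapping groups of N consecutive trials of the same true class, and
accuracy-versus-N curves summarize the gain from extra trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .decode import LABEL_DEVIANT, LABEL_STANDARD, DecisionRecord


@dataclass
class CombinationResult:
    """One group of N consecutive decisions fused into a single one."""

    N: int
    f_sum: float
    true_label: int
    orders: tuple

    @property
    def p_combined(self) -> float:
        return float(expit(self.f_sum))

    @property
    def predicted_label(self) -> int:
        return LABEL_DEVIANT if self.f_sum > 0 else LABEL_STANDARD


def naive_bayes_product(p: np.ndarray, q: np.ndarray | None = None) -> float:
    """The product form of the combination (reference formula).

    Kept as the direct expression of the probability-product rule; the
    sum-of-decision-values path in :func:`combine` is the numerically
    stable equivalent.  ``q`` is the per-trial non-target probability;
    pass it explicitly (e.g. ``expit(-f)``) to evaluate the product form
    at full precision when p is within rounding of 1.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p if q is None else np.asarray(q, dtype=float)
    num = np.prod(p)
    den = num + np.prod(q)
    return float(num / den) if den > 0 else 0.5


def combine(records: list[DecisionRecord], N: int) -> list[CombinationResult]:
    """Fuse non-overlapping groups of N consecutive same-class decisions.

    Records must be in acquisition order and share one true class; a
    trailing remainder shorter than N is dropped.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > len(records):
        raise ValueError("N exceeds the number of records")
    labels = {r.true_label for r in records}
    if len(labels) > 1:
        raise ValueError("records in a combination group must share a class")
    out = []
    for start in range(0, len(records) - N + 1, N):
        group = records[start : start + N]
        out.append(
            CombinationResult(
                N=N,
                f_sum=float(sum(r.f for r in group)),
                true_label=group[0].true_label,
                orders=tuple(r.order for r in group),
            )
        )
    return out


def multi_trial_curve(
    decisions: list[DecisionRecord], n_range=range(1, 8)
) -> dict[int, float]:
    """Accuracy of the fused decision per group size N.

    Decisions are split by true class, ordered by acquisition, grouped in
    non-overlapping runs of N, and scored by the sign of the summed
    decision value.  Classes with fewer than N decisions raise.
    """
    by_class = {}
    for label in (LABEL_STANDARD, LABEL_DEVIANT):
        recs = sorted(
            (r for r in decisions if r.true_label == label),
            key=lambda r: (r.participant, r.order),
        )
        by_class[label] = recs
    curve = {}
    for N in n_range:
        correct = 0
        count = 0
        for label, recs in by_class.items():
            if len(recs) < N:
                raise ValueError(f"fewer than N={N} decisions for class {label}")
            for res in combine(recs, N):
                correct += res.predicted_label == label
                count += 1
        curve[int(N)] = correct / count
    return curve


def per_participant_curves(
    decisions: list[DecisionRecord], n_range=range(1, 8)
) -> dict[str, dict[int, float]]:
    """Accuracy-versus-N curve separately for each participant."""
    pids = sorted({r.participant for r in decisions})
    return {
        pid: multi_trial_curve(
            [r for r in decisions if r.participant == pid], n_range
        )
        for pid in pids
    }
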