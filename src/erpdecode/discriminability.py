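"""Spatio-temporal class separability: AUC maps and difference waves.

Each channel/time point's single-feature separability between deviant and
standard trials is summarized by the area under the ROC curve in its
Mann-Whitney formulation: P(deviant value > standard value) + half the tie
probability, over all trial pairs.  0.5 is the no-discrimination line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import EpochSet


@dataclass
class AUCMap:
    """Channel x time AUC scores in [0, 1] with axis labels."""

    scores: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("AUC scores must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.scores, index=list(self.channel_labels), columns=self.times
        )


def _split_classes(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    dev = epochs.data[epochs.is_deviant()]
    std = epochs.data[~epochs.is_deviant()]
    if len(dev) == 0 or len(std) == 0:
        raise ValueError("both classes must be present")
    return dev, std


def auc_map(epochs: EpochSet) -> AUCMap:
    """Mann-Whitney AUC per channel/time (deviant as positive class).

    Computed from the rank-sum statistic with midrank tie handling, which
    equals the pairwise count P(dev > std) + 0.5 P(dev = std).
    """
    dev, std = _split_classes(epochs)
    n_d, n_s = len(dev), len(std)
    n_tr, n_ch, n_t = epochs.data.shape
    flat = epochs.data.reshape(n_tr, -1)
    ranks = stats.rankdata(flat, axis=0, method="average")
    rank_sum_dev = ranks[epochs.is_deviant()].sum(axis=0)
    u = rank_sum_dev - n_d * (n_d + 1) / 2.0
    scores = (u / (n_d * n_s)).reshape(n_ch, n_t)
    return AUCMap(scores, epochs.times.copy(), epochs.montage.labels)


def difference_wave(epochs: EpochSet) -> np.ndarray:
    """Grand mean deviant minus grand mean standard, channels x samples."""
    dev, std = _split_classes(epochs)
    return dev.mean(axis=0) - std.mean(axis=0)
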