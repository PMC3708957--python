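"""Classifier-weight decomposition and links to ERP/behavioral measures.

The spatio-temporal weight matrix of a linear decoder factors, via SVD,
into ranked spatial topographies and time courses; on oddball decoders the
leading component typically carries an MMN-like fronto-central negativity
whose time course tracks the deviant-minus-standard difference wave.
Scalar couplings between decoding rates and ERP amplitudes or behavioral
scores are plain Pearson correlations over participant-condition pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .decode import LinearModel
from .montage import FRONTOCENTRAL


@dataclass
class WeightComponent:
    """One SVD component of the weight matrix, sign-normalized."""

    topography: np.ndarray  # per-channel, unit norm
    time_course: np.ndarray  # per-sample, unit norm
    singular_value: float
    variance_fraction: float


def svd_weights(model: LinearModel) -> list[WeightComponent]:
    """Ranked SVD components of W with variance fractions.

    Components are ordered by singular value; fraction_k is
    sigma_k^2 / sum sigma^2.  The sign ambiguity is resolved so that each
    component's time-course extreme is negative (the deviance-related
    components of interest are negativities).
    """
    if not np.any(model.W):
        raise ValueError("weight matrix is zero")
    u, s, vt = np.linalg.svd(model.W, full_matrices=False)
    fractions = s**2 / np.sum(s**2)
    comps = []
    for k in range(len(s)):
        topo, tc = u[:, k].copy(), vt[k].copy()
        if tc[np.argmax(np.abs(tc))] > 0:
            topo, tc = -topo, -tc
        comps.append(
            WeightComponent(
                topography=topo,
                time_course=tc,
                singular_value=float(s[k]),
                variance_fraction=float(fractions[k]),
            )
        )
    return comps


def reconstruct_weights(components: list[WeightComponent]) -> np.ndarray:
    """Rebuild W from components (decomposition sanity check)."""
    return sum(
        c.singular_value * np.outer(c.topography, c.time_course)
        for c in components
    )


def pearson(x, y) -> float:
    """Pearson correlation with explicit zero-variance error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance series")
    return float(np.corrcoef(x, y)[0, 1])


def correlate_component_timecourse(
    time_course: np.ndarray, mean_difference_wave: np.ndarray
) -> float:
    """Pearson r between a component time course and a difference wave."""
    return pearson(time_course, mean_difference_wave)


def performance_scalar_correlation(rates, scalars) -> float:
    """Pearson r between decoding rates and per-participant scalars.

    Pairs are pooled over participants and conditions (e.g. decoding rate
    vs mean MMN-window amplitude, or vs behavioral identification score).
    """
    return pearson(rates, scalars)


def mmn_amplitude(
    epochs: EpochSet,
    channels: tuple[str, ...] = FRONTOCENTRAL,
    search_window: tuple[float, float] = (200.0, 400.0),
    mean_window_ms: float = 50.0,
) -> float:
    """Mean MMN amplitude of the difference wave, in microvolts.

    The difference wave is averaged over the fronto-central electrode
    set, its minimum located within the 200-400 ms search window, and the
    amplitude taken as the mean over a 50 ms window centred on that peak.
    Falls back to all channels when the montage lacks the standard labels
    (small synthetic layouts).
    """
    from .discriminability import difference_wave

    diff = difference_wave(epochs)
    labels = epochs.montage.labels
    present = [c for c in channels if c in labels]
    if present:
        idx = epochs.montage.indices(present)
        wave = diff[idx].mean(axis=0)
    else:
        wave = diff.mean(axis=0)
    t = epochs.times
    search = (t >= search_window[0]) & (t <= search_window[1])
    if not search.any():
        raise ValueError("search window outside epoch")
    sub = np.nonzero(search)[0]
    peak = sub[np.argmin(wave[sub])]
    half = mean_window_ms / 2.0
    win = (t >= t[peak] - half) & (t <= t[peak] + half)
    return float(wave[win].mean())
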