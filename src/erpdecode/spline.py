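"""Perrin spherical-spline interpolation of scalp potentials.

Bad channels are reconstructed from the remaining electrodes by fitting a
smoothing spline on the unit sphere (Perrin's method): the interpolant is
a constant plus a weighted sum of the kernel

    g(cos theta) = (1/4pi) * sum_{n=1}^{N} (2n+1) / (n(n+1))^m * P_n(cos theta)

over the good electrodes, with the weights constrained to sum to zero and
ridge-stabilized by a small stiffness term on the diagonal.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre

from .montage import Montage

DEFAULT_ORDER_M = 4
DEFAULT_STIFFNESS = 1e-5
DEFAULT_N_TERMS = 50


def spline_kernel(
    cos_theta: np.ndarray,
    order_m: int = DEFAULT_ORDER_M,
    n_terms: int = DEFAULT_N_TERMS,
) -> np.ndarray:
    """Evaluate the spherical-spline kernel g at the given cos(angles)."""
    n = np.arange(1, n_terms + 1, dtype=float)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1)) ** order_m
    return legendre.legval(np.clip(cos_theta, -1.0, 1.0), coef) / (4 * np.pi)


def interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    order_m: int = DEFAULT_ORDER_M,
    stiffness: float = DEFAULT_STIFFNESS,
    n_terms: int = DEFAULT_N_TERMS,
) -> np.ndarray:
    """Linear map taking good-channel potentials to bad-channel estimates.

    Solves the constrained spline system once; the returned
    (n_bad, n_good) matrix applies to any number of time samples.
    """
    good_pos = np.asarray(good_pos, dtype=float)
    bad_pos = np.asarray(bad_pos, dtype=float)
    k = len(good_pos)
    if k < 4:
        raise ValueError("need at least 4 good channels for spline repair")
    gram = spline_kernel(good_pos @ good_pos.T, order_m, n_terms)
    if np.linalg.matrix_rank(good_pos @ good_pos.T) < 2:
        raise ValueError("degenerate montage: electrodes are collinear")
    system = np.zeros((k + 1, k + 1))
    system[:k, :k] = gram + stiffness * np.eye(k)
    system[:k, k] = 1.0
    system[k, :k] = 1.0
    # rhs maps each good-channel unit potential: solve for [C; c0] columns
    rhs = np.vstack([np.eye(k), np.zeros((1, k))])
    sol = np.linalg.solve(system, rhs)
    c, c0 = sol[:k], sol[k]
    g_bad = spline_kernel(bad_pos @ good_pos.T, order_m, n_terms)
    return g_bad @ c + c0[None, :]


def spline_interpolate(
    epoch: np.ndarray,
    bad: set | list,
    montage: Montage,
    order_m: int = DEFAULT_ORDER_M,
    stiffness: float = DEFAULT_STIFFNESS,
    n_terms: int = DEFAULT_N_TERMS,
) -> np.ndarray:
    """Replace bad-channel rows of one (channels x samples) epoch.

    Good channels pass through unchanged; each bad channel is replaced by
    the spherical-spline estimate from the good channels at every sample.
    """
    bad_idx = np.array(sorted(bad), dtype=int)
    if bad_idx.size == 0:
        return epoch.copy()
    n_ch = epoch.shape[0]
    if len(bad_idx) >= n_ch - 3:
        raise ValueError("too many bad channels to interpolate")
    good_idx = np.setdiff1d(np.arange(n_ch), bad_idx)
    coincident = np.linalg.norm(
        montage.positions[:, None] - montage.positions[None, :], axis=-1
    )
    np.fill_diagonal(coincident, np.inf)
    if coincident.min() < 1e-9:
        raise ValueError("degenerate montage: coincident electrodes")
    mat = interpolation_matrix(
        montage.positions[good_idx],
        montage.positions[bad_idx],
        order_m,
        stiffness,
        n_terms,
    )
    repaired = epoch.copy()
    repaired[bad_idx] = mat @ epoch[good_idx]
    return repaired
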