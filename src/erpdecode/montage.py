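"""Electrode montages: labelled unit-sphere positions.

Scalp potentials are interpolated on the unit sphere (Perrin splines), so
every montage used in this package stores positions normalized to unit
length.  The standard 64-channel layout is taken from the BioSemi 10-20
positions shipped with MNE; arbitrary channel counts (used by small test
fixtures) are laid out on an upper-hemisphere Fibonacci spiral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: labels of the two mastoid reference leads appended to every montage
MASTOIDS = ("M1", "M2")

#: fronto-central electrode set used for MMN amplitude measures
FRONTOCENTRAL = ("F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2")


@dataclass(frozen=True)
class Montage:
    """Channel labels with 3-D unit-vector positions.

    Invariants: labels are unique and ``|positions[i]| = 1`` for every
    channel (enforced at construction).
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 3)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.labels)} labels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must be unit vectors (|p| = 1 ± 1e-6)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(l) for l in labels], dtype=int)

    def subset(self, labels) -> "Montage":
        idx = self.indices(labels)
        return Montage(tuple(self.labels[i] for i in idx), self.positions[idx])

    def save(self, path) -> None:
        """Write a 4-column text file: label x y z."""
        with open(path, "w") as fh:
            for lab, p in zip(self.labels, self.positions):
                fh.write(f"{lab}\t{p[0]:.9f}\t{p[1]:.9f}\t{p[2]:.9f}\n")

    @classmethod
    def load(cls, path) -> "Montage":
        labels, pos = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split()
            labels.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
        return cls(tuple(labels), np.asarray(pos))


# approximate 10-20 mastoid positions on the unit sphere (left/right,
# low and posterior-lateral)
_MASTOID_POS = np.array(
    [
        [-0.80, -0.40, -0.45],
        [0.80, -0.40, -0.45],
    ]
)
_MASTOID_POS /= np.linalg.norm(_MASTOID_POS, axis=1, keepdims=True)


def _fibonacci_cap(n: int, z_min: float = 0.0) -> np.ndarray:
    """n roughly uniform points on the spherical cap z >= z_min."""
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def biosemi64_montage(include_mastoids: bool = True) -> Montage:
    """The standard BioSemi 64-channel 10-20 layout plus mastoid leads."""
    import mne

    std = mne.channels.make_standard_montage("biosemi64")
    ch_pos = std.get_positions()["ch_pos"]
    labels = list(ch_pos)
    pos = np.array([ch_pos[l] for l in labels])
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    if include_mastoids:
        labels += list(MASTOIDS)
        pos = np.vstack([pos, _MASTOID_POS])
    return Montage(tuple(labels), pos)


def generic_montage(n_scalp: int, include_mastoids: bool = True) -> Montage:
    """A synthetic upper-hemisphere layout for arbitrary channel counts.

    Used by small simulation fixtures where the full 10-20 set is
    unnecessarily large.  Channels are named C01..Cnn.
    """
    if n_scalp < 4:
        raise ValueError("need at least 4 scalp channels")
    pos = _fibonacci_cap(n_scalp, z_min=0.05)
    labels = [f"C{i + 1:02d}" for i in range(n_scalp)]
    if include_mastoids:
        labels += list(MASTOIDS)
        pos = np.vstack([pos, _MASTOID_POS])
    return Montage(tuple(labels), pos)


def make_montage(n_scalp: int, include_mastoids: bool = True) -> Montage:
    """Standard BioSemi layout for 64 scalp channels, generic otherwise."""
    if n_scalp == 64:
        return biosemi64_montage(include_mastoids)
    return generic_montage(n_scalp, include_mastoids)


def scalp_indices(montage: Montage) -> np.ndarray:
    """Indices of non-reference (scalp) channels."""
    return np.array(
        [i for i, l in enumerate(montage.labels) if l not in MASTOIDS], dtype=int
    )
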