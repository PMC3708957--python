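"""In-memory containers and on-disk formats for epoched and continuous EEG.

``EpochSet`` is the package's working container: a trials x channels x
samples array in microvolts with a millisecond time axis and per-trial
metadata (class label, condition, participant, group).  Epoch sets are
persisted to a plain HDF5 layout (datasets ``data``, ``times``, string
datasets for labels, scalar attrs); continuous recordings can be exported
to EDF for interoperability with standard EEG readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage

CLASS_STANDARD = "standard"
CLASS_DEVIANT = "deviant"


@dataclass
class EpochSet:
    """Epoched multi-channel EEG with per-trial metadata.

    data
        (n_trials, n_channels, n_samples) array, microvolts.
    times
        millisecond axis relative to stimulus onset, strictly increasing
        and uniformly spaced at 1000/sampling_rate.
    trial_class
        per-trial label, ``standard`` or ``deviant``.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    trial_class: np.ndarray
    montage: Montage
    condition: str = ""
    participant: str = ""
    group: str = ""
    trial_order: np.ndarray = field(default=None)  # acquisition index per trial

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.trial_class = np.asarray(self.trial_class)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if self.times.shape != (n_samples,):
            raise ValueError("times length must equal n_samples")
        dt = np.diff(self.times)
        if n_samples > 1:
            if not np.all(dt > 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.sampling_rate, rtol=1e-6):
                raise ValueError("times must be uniform at 1000/sampling_rate ms")
        if self.trial_class.shape != (n_trials,):
            raise ValueError("trial_class length must equal n_trials")
        if self.montage.n_channels != n_channels:
            raise ValueError("montage size must match channel count")
        if self.trial_order is None:
            self.trial_order = np.arange(n_trials)
        else:
            self.trial_order = np.asarray(self.trial_order, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def is_deviant(self) -> np.ndarray:
        return self.trial_class == CLASS_DEVIANT

    def select_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx],
            trial_class=self.trial_class[idx],
            trial_order=self.trial_order[idx],
        )

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            trial_class=self.trial_class.copy(),
            trial_order=self.trial_order.copy(),
        )


@dataclass
class Recording:
    """Continuous multi-channel recording with stimulus events.

    events are (sample_index, code) pairs sorted by sample index; codes
    are small integers (1 = standard, 2 = deviant by convention).
    """

    data: np.ndarray  # (n_channels, n_samples), microvolts
    sampling_rate: float
    events: np.ndarray  # (n_events, 2) int
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.events.size:
            if np.any(np.diff(self.events[:, 0]) < 0):
                raise ValueError("events must be sorted by sample index")
            if self.events[:, 0].max() >= self.data.shape[1]:
                raise ValueError("event index beyond end of recording")


# ---------------------------------------------------------------------------
# HDF5 epoch container
# ---------------------------------------------------------------------------

def save_epochs(path, epochs: EpochSet) -> None:
    """Write an EpochSet to the package's HDF5 epoch layout."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times", data=epochs.times)
        f.create_dataset(
            "trial_class",
            data=np.asarray(epochs.trial_class, dtype="S"),
        )
        f.create_dataset("trial_order", data=epochs.trial_order)
        f.create_dataset(
            "channel_labels", data=np.asarray(epochs.montage.labels, dtype="S")
        )
        f.create_dataset("channel_positions", data=epochs.montage.positions)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["condition"] = epochs.condition
        f.attrs["participant"] = epochs.participant
        f.attrs["group"] = epochs.group


def load_epochs(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        montage = Montage(
            tuple(l.decode() for l in f["channel_labels"][()]),
            f["channel_positions"][()],
        )
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            trial_class=np.array([c.decode() for c in f["trial_class"][()]]),
            montage=montage,
            condition=str(f.attrs["condition"]),
            participant=str(f.attrs["participant"]),
            group=str(f.attrs["group"]),
            trial_order=f["trial_order"][()],
        )


# ---------------------------------------------------------------------------
# EDF export (continuous recordings)
# ---------------------------------------------------------------------------

def write_edf(path, rec: Recording) -> None:
    """Write a Recording as a plain EDF file plus a stimulus channel.

    The writer emits standard EDF: ASCII headers and 16-bit little-endian
    samples, one data record per second.  Events are encoded in an extra
    ``STI`` channel carrying the event code at the event sample (readable
    by any EDF tool; ``mne.io.read_raw_edf`` round-trips it).
    """
    n_ch, n_samp = rec.data.shape
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))

    sti = np.zeros(n_samp)
    for s, code in rec.events:
        sti[s] = code
    signals = np.vstack([rec.data, sti[None, :]])
    labels = list(rec.montage.labels) + ["STI"]
    n_sig = n_ch + 1

    # pad to whole data records of one second
    n_records = int(np.ceil(n_samp / fs))
    pad = n_records * fs - n_samp
    if pad:
        signals = np.pad(signals, ((0, 0), (0, pad)))

    phys_min = np.floor(signals.min(axis=1))
    phys_max = np.ceil(signals.max(axis=1))
    phys_max = np.where(phys_max <= phys_min, phys_min + 1, phys_max)
    dig_min, dig_max = -32768.0, 32767.0
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((signals - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def a(text, width):  # ASCII fixed-width field
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            a("0", 8),
            a("X X X X", 80),
            a("synthetic recording", 80),
            a("01.01.00", 8),
            a("00.00.00", 8),
            a(256 * (n_sig + 1), 8),
            a("", 44),
            a(n_records, 8),
            a(1, 8),  # record duration, seconds
            a(n_sig, 4),
        ]
    )
    fields = [
        (labels, 16),
        (["AgAgCl electrode"] * n_ch + ["stim"], 80),
        (["uV"] * n_ch + [""], 8),
        ([f"{v:g}" for v in phys_min], 8),
        ([f"{v:g}" for v in phys_max], 8),
        ([f"{dig_min:g}"] * n_sig, 8),
        ([f"{dig_max:g}"] * n_sig, 8),
        ([""] * n_sig, 80),
        ([str(fs)] * n_sig, 8),
        ([""] * n_sig, 32),
    ]
    sig_header = b"".join(
        b"".join(a(v, width) for v in values) for values, width in fields
    )

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path) -> tuple[np.ndarray, float, np.ndarray, list[str]]:
    """Read back an exported EDF via MNE: (data uV, rate, events, labels)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    raw_data = raw.get_data()
    fs = float(raw.info["sfreq"])
    if "STI" in labels:
        i = labels.index("STI")
        # the stim channel is dimensionless (no uV -> V conversion applied)
        sti = np.rint(raw_data[i]).astype(int)
        keep = [j for j in range(len(labels)) if j != i]
        onsets = np.nonzero(sti)[0]
        events = np.column_stack([onsets, sti[onsets]])
        return raw_data[keep] * 1e6, fs, events, [labels[j] for j in keep]
    return raw_data * 1e6, fs, np.empty((0, 2), int), labels
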