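"""Synthetic passive-oddball EEG cohorts with known ground truth.

The generator emulates a 64-channel passive oddball recording: 15% of
trials carry a rare deviant stimulus, and deviant epochs contain graded
enhancements of three negative ERP components (an N1-interval effect, an
MMN-like N2-interval effect, and a late RON-like negativity), all with
fronto-central topographies.  Component amplitudes scale multiplicatively
with a per-condition gain (the deviance-magnitude analogue of a VOT
continuum) and a per-group gain (the native-language analogue), which is
the ground-truth effect structure every downstream stage is tested
against.

Background activity is spatially correlated Gaussian noise with a 1/f
temporal spectrum; blink-like artifacts and transiently bad channels are
injected at configurable rates so the preprocessing rules have something
to find.  Everything is deterministic given the configured seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import CLASS_DEVIANT, CLASS_STANDARD, EpochSet, Recording
from .montage import MASTOIDS, Montage, make_montage, scalp_indices


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentTemplate:
    """One ERP component: fixed topography, Gaussian time course.

    topography is one weight per scalp channel with max |w| = 1; amplitude
    is the signed peak value in microvolts at gain 1.  latency/width are
    the Gaussian mean/SD in milliseconds.
    """

    name: str
    topography: np.ndarray
    latency: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        topo = np.asarray(self.topography, dtype=float)
        if topo.ndim != 1:
            raise ValueError("topography must be a vector")
        m = np.abs(topo).max()
        if not np.isclose(m, 1.0, atol=1e-9) and m > 0:
            raise ValueError("topography must be scaled to max |w| = 1")
        if self.width <= 0:
            raise ValueError("width must be positive")
        object.__setattr__(self, "topography", topo)

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((times_ms - self.latency) / self.width) ** 2)

    def render(self, times_ms: np.ndarray, gain: float = 1.0) -> np.ndarray:
        """(channels x samples) contribution at the given gain."""
        return (
            gain
            * self.amplitude
            * np.outer(self.topography, self.waveform(times_ms))
        )


@dataclass
class SynthConfig:
    """Study conditions for one synthetic oddball cohort.

    Defaults emulate the recorded paradigm: 64 scalp channels plus two
    mastoid leads, 15% deviants, 1200 ms trials epoched at -200..1000 ms,
    three deviance conditions with graded gains and two groups with the
    larger responses in the native-analogue group.
    """

    n_channels: int = 64
    sampling_rate: float = 128.0
    epoch_window: tuple[float, float] = (-200.0, 1000.0)
    deviant_prob: float = 0.15
    trial_count: int = 200
    condition_gain: dict = field(
        default_factory=lambda: {"63ms": 0.5, "41ms": 1.0, "19ms": 1.5}
    )
    group_gain: dict = field(
        default_factory=lambda: {"native": 1.0, "nonnative": 0.7}
    )
    template_spec: list = None  # list of dicts; None -> standard three
    noise_sd: float = 2.5
    noise_spatial_scale: float = 0.6  # chord-distance scale on unit sphere
    artifact_rates: dict = field(
        default_factory=lambda: {"blink": 0.05, "bad_channel": 0.02}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deviant_prob < 1.0:
            raise ValueError("deviant_prob must be in [0, 1)")
        if any(g < 0 for g in self.condition_gain.values()):
            raise ValueError("condition gains must be >= 0")
        if any(g < 0 for g in self.group_gain.values()):
            raise ValueError("group gains must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def conditions(self) -> list[str]:
        return list(self.condition_gain)

    @property
    def groups(self) -> list[str]:
        return list(self.group_gain)

    def montage(self) -> Montage:
        return make_montage(self.n_channels)

    def times_ms(self) -> np.ndarray:
        """Epoch time axis: half-open [start, end) at the sampling rate."""
        start, end = self.epoch_window
        dt = 1000.0 / self.sampling_rate
        n = int(round((end - start) / dt))
        return start + dt * np.arange(n)

    def templates(self, montage: Montage) -> list[ComponentTemplate]:
        spec = self.template_spec or DEFAULT_TEMPLATE_SPEC
        return [make_template(montage, **kw) for kw in spec]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SynthConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["epoch_window"] = tuple(d["epoch_window"])
        return cls(**d)


#: the three deviance-related negativities: N1-interval, MMN-like N2,
#: late RON-like.  Amplitudes (uV, at gain 1) sit in the 0.5-5 uV range
#: typical of passive-oddball negativities; relative sizes are
#: config-exposed because only their ordering is qualitatively known.
DEFAULT_TEMPLATE_SPEC = [
    {"name": "N1", "latency": 100.0, "width": 30.0, "amplitude": -2.0},
    {"name": "MMN", "latency": 250.0, "width": 50.0, "amplitude": -4.0},
    {"name": "RON", "latency": 550.0, "width": 70.0, "amplitude": -2.5},
]

# unit direction of the fronto-central topography peak (just anterior of Cz)
_FRONTOCENTRAL_DIR = np.array([0.0, 0.45, 0.893])
_FRONTOCENTRAL_DIR /= np.linalg.norm(_FRONTOCENTRAL_DIR)


def frontocentral_topography(montage: Montage, scale: float = 0.7) -> np.ndarray:
    """Smooth topography peaking at fronto-central midline, zero on mastoids.

    Weight falls off as a Gaussian in chord distance from the peak
    direction; normalized to max weight 1.
    """
    d = np.linalg.norm(montage.positions - _FRONTOCENTRAL_DIR, axis=1)
    topo = np.exp(-0.5 * (d / scale) ** 2)
    for m in MASTOIDS:
        if m in montage.labels:
            topo[montage.index(m)] = 0.0
    return topo / np.abs(topo).max()


def make_template(
    montage: Montage,
    name: str,
    latency: float,
    width: float,
    amplitude: float,
    topography: np.ndarray | None = None,
) -> ComponentTemplate:
    if topography is None:
        topography = frontocentral_topography(montage)
    return ComponentTemplate(name, topography, latency, width, amplitude)


# ---------------------------------------------------------------------------
# oddball sequence
# ---------------------------------------------------------------------------

def generate_oddball_sequence(
    n_trials: int, deviant_prob: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Pseudorandom oddball label sequence.

    Constraints: the first trial is a standard and no two deviants are
    adjacent.  Conditional on the previous trial being a standard, a
    deviant follows with probability p/(1-p), which makes the stationary
    deviant fraction equal to ``deviant_prob``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= deviant_prob < 0.5:
        raise ValueError(
            "deviant_prob must be in [0, 0.5): the no-adjacent-deviants "
            "constraint cannot reach rates of 0.5 or more"
        )
    rng = np.random.default_rng(seed)
    q = deviant_prob / (1.0 - deviant_prob)
    labels = np.empty(n_trials, dtype=object)
    labels[0] = CLASS_STANDARD
    u = rng.random(n_trials)
    for i in range(1, n_trials):
        if labels[i - 1] == CLASS_DEVIANT:
            labels[i] = CLASS_STANDARD
        else:
            labels[i] = CLASS_DEVIANT if u[i] < q else CLASS_STANDARD
    return labels.astype(str)


# ---------------------------------------------------------------------------
# noise and artifacts
# ---------------------------------------------------------------------------

def _spatial_mixing(montage: Montage, scale: float) -> np.ndarray:
    """Mixing matrix giving Gaussian spatial correlation over the scalp."""
    d = np.linalg.norm(
        montage.positions[:, None, :] - montage.positions[None, :, :], axis=-1
    )
    k = np.exp(-0.5 * (d / scale) ** 2)
    # normalize rows so mixing preserves per-channel variance scale
    return k / np.sqrt((k**2).sum(axis=1, keepdims=True))


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float
) -> np.ndarray:
    """Unit-variance noise with ~1/f power spectrum per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # flat below 1 Hz
    spec *= shaping
    colored = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = colored.std()
    return colored / sd if sd > 0 else colored


def _blink_artifact(
    montage: Montage, times_ms: np.ndarray, onset_ms: float, amplitude: float
) -> np.ndarray:
    """Blink-like transient: large frontal pulse, ~150 ms half-width."""
    frontal_dir = np.array([0.0, 0.97, 0.26])
    d = np.linalg.norm(montage.positions - frontal_dir, axis=1)
    topo = np.exp(-0.5 * (d / 0.5) ** 2)
    topo /= topo.max()
    pulse = np.exp(-0.5 * ((times_ms - onset_ms) / 75.0) ** 2)
    return amplitude * np.outer(topo, pulse)


# ---------------------------------------------------------------------------
# participant rendering
# ---------------------------------------------------------------------------

def render_participant(
    config: SynthConfig,
    group: str,
    condition: str,
    participant_seed: int,
    participant: str = "",
) -> EpochSet:
    """Render one participant's epochs for one measurement condition.

    Deviant epochs receive every template scaled by
    ``amplitude * condition_gain * group_gain``; standard epochs carry
    noise only (deviance-related components are modelled as pure
    enhancements).  Trials abut exactly (1200 ms ISI equals the epoch
    length), so epochs are rendered directly on the -200..1000 ms grid.
    """
    if group not in config.group_gain:
        raise KeyError(f"unknown group {group!r}")
    if condition not in config.condition_gain:
        raise KeyError(f"unknown condition {condition!r}")
    montage = config.montage()
    times = config.times_ms()
    for t in config.templates(montage):
        if not times[0] <= t.latency <= times[-1]:
            raise ValueError(
                f"template {t.name!r} latency {t.latency} ms outside epoch window"
            )
    rng = np.random.default_rng(participant_seed)
    labels = generate_oddball_sequence(
        config.trial_count, config.deviant_prob, rng
    )
    scalp = scalp_indices(montage)
    gain = config.condition_gain[condition] * config.group_gain[group]

    # templates are defined over the full montage (mastoid weights zero)
    signal = np.zeros((montage.n_channels, len(times)))
    for t in config.templates(montage):
        signal += t.render(times, gain)

    data = np.zeros((config.trial_count, montage.n_channels, len(times)))
    if config.noise_sd > 0:
        noise = _one_over_f_noise(
            rng,
            montage.n_channels,
            config.trial_count * len(times),
            config.sampling_rate,
        )
        mix = _spatial_mixing(montage, config.noise_spatial_scale)
        noise = config.noise_sd * (mix @ noise)
        data += noise.reshape(
            montage.n_channels, config.trial_count, len(times)
        ).transpose(1, 0, 2)
    data[labels == CLASS_DEVIANT] += signal

    blink_rate = config.artifact_rates.get("blink", 0.0)
    bad_rate = config.artifact_rates.get("bad_channel", 0.0)
    for i in range(config.trial_count):
        if blink_rate and rng.random() < blink_rate:
            onset = rng.uniform(times[0] + 100, times[-1] - 100)
            data[i] += _blink_artifact(montage, times, onset, 120.0)
        if bad_rate and rng.random() < bad_rate:
            ch = rng.integers(0, len(scalp))
            kind = rng.random()
            if kind < 0.5:  # mains-like contamination
                data[i, scalp[ch]] += 200.0 * np.sin(
                    2 * np.pi * 50.0 * times / 1000.0
                )
            else:  # electrode drift: offset far beyond +/-25 mV
                data[i, scalp[ch]] += 30000.0

    return EpochSet(
        data=data,
        times=times,
        sampling_rate=config.sampling_rate,
        trial_class=labels,
        montage=montage,
        condition=condition,
        participant=participant,
        group=group,
    )


def to_recording(epochs: EpochSet) -> Recording:
    """Concatenate abutting epochs into a continuous Recording.

    Stimulus onset events (1 = standard, 2 = deviant) are placed at each
    epoch's t = 0 sample.
    """
    n_trials, n_ch, n_samp = epochs.data.shape
    data = epochs.data.transpose(1, 0, 2).reshape(n_ch, n_trials * n_samp)
    onset = int(np.argmin(np.abs(epochs.times)))
    codes = np.where(epochs.trial_class == CLASS_DEVIANT, 2, 1)
    events = np.column_stack(
        [onset + n_samp * np.arange(n_trials), codes]
    )
    return Recording(
        data=data,
        sampling_rate=epochs.sampling_rate,
        events=events,
        montage=epochs.montage,
    )


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

#: identification-curve boundary (continuum step units) per group: the
#: native-analogue group hears the mid-continuum stimulus as the deviant
#: category, the non-native group's boundary sits later.
DEFAULT_BOUNDARY = {"native": 3.6, "nonnative": 4.6}
DEFAULT_SLOPE = 0.7


def render_behavioral_vector(
    group: str,
    seed: int | np.random.Generator,
    boundary: dict | None = None,
    slope: float = DEFAULT_SLOPE,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Mean identification scores over a 7-step continuum, in [0, 1].

    A logistic curve in continuum step with a group-dependent boundary,
    plus bounded response noise.
    """
    boundary = boundary or DEFAULT_BOUNDARY
    if group not in boundary:
        raise KeyError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    steps = np.arange(1, 8, dtype=float)
    curve = 1.0 / (1.0 + np.exp((steps - boundary[group]) / slope))
    if noise_sd > 0:
        curve = curve + rng.normal(0.0, noise_sd, size=7)
    return np.clip(curve, 0.0, 1.0)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Participant:
    """One synthetic participant: epochs per condition plus behavior."""

    participant: str
    group: str
    seed: int
    epochs: dict  # condition -> EpochSet
    behavior: np.ndarray


def participant_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-participant seeds spawned from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_cohort(
    config: SynthConfig,
    group_sizes: dict | None = None,
) -> list[Participant]:
    """Render a full cohort: every participant in every condition.

    Participant ids are ``<group><k>`` and per-participant seeds are
    spawned deterministically from ``config.seed``.
    """
    group_sizes = group_sizes or {g: 11 for g in config.groups}
    n_total = sum(group_sizes.values())
    seeds = participant_seeds(config.seed, n_total)
    cohort: list[Participant] = []
    i = 0
    for group, size in group_sizes.items():
        for k in range(size):
            pid = f"{group}{k + 1:02d}"
            seed = seeds[i]
            i += 1
            epochs = {
                cond: render_participant(
                    config, group, cond, seed + j, participant=pid
                )
                for j, cond in enumerate(config.conditions)
            }
            behavior = render_behavioral_vector(group, seed + 1000)
            cohort.append(Participant(pid, group, seed, epochs, behavior))
    return cohort
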