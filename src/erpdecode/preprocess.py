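"""Rule-based preprocessing from raw epochs to classifier-ready windows.

The chain mirrors standard passive-oddball practice: per-epoch bad-channel
detection (mains-band power, amplifier offset) and spherical-spline repair,
polyphase resampling to 128 Hz, infomax-ICA artifact-component removal by
a deterministic variance rule, baseline-relative amplitude rejection at
+/-75 uV, zero-phase 1-25 Hz band-pass, re-referencing to the mastoid
average, baseline correction over the 100 ms before stimulus onset, and
finally pairing each deviant with its immediately preceding surviving
standard and cropping to the 0-700 ms decoding window (90 samples at
128 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import CLASS_DEVIANT, CLASS_STANDARD, EpochSet
from .montage import MASTOIDS, Montage
from .spline import spline_interpolate


# ---------------------------------------------------------------------------
# configuration and report
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    """Thresholds and stage parameters, at recorded-paradigm defaults.

    ``line_power_limit`` is integrated 48-52 Hz periodogram power in uV^2
    (calibrated so clean simulated epochs flag <1% of channels);
    ``offset_limit_mv`` is the +/-25 mV amplifier-offset rule.
    """

    line_power_limit: float = 5000.0
    offset_limit_mv: float = 25.0
    target_rate: float = 128.0
    run_ica: bool = True
    variance_floor: float = 0.01
    threshold_scale: float = 1.0
    ica_seed: int = 0
    ica_max_samples: int = 4000
    ica_max_iter: int = 200
    amplitude_limit: float = 75.0
    baseline_window: tuple[float, float] = (-100.0, 0.0)
    band: tuple[float, float] = (1.0, 25.0)
    decode_window: tuple[float, float] = (0.0, 700.0)
    reference_channels: tuple[str, ...] = MASTOIDS

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class PreprocessReport:
    """What each stage did: repairs, removed components, rejections."""

    repaired_channels: list = field(default_factory=list)  # per-epoch lists
    removed_components: list = field(default_factory=list)
    component_variance_fractions: dict = field(default_factory=dict)
    rejected_epochs: list = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)

    @property
    def mean_repairs_per_epoch(self) -> float:
        if not self.repaired_channels:
            return 0.0
        return float(np.mean([len(r) for r in self.repaired_channels]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "repaired_channels": self.repaired_channels,
                    "removed_components": self.removed_components,
                    "component_variance_fractions": self.component_variance_fractions,
                    "rejected_epochs": self.rejected_epochs,
                    "stage_counts": self.stage_counts,
                    "mean_repairs_per_epoch": self.mean_repairs_per_epoch,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# individual operations
# ---------------------------------------------------------------------------

def detect_bad_channels(
    epoch: np.ndarray,
    sampling_rate: float,
    line_power_limit: float = 5000.0,
    offset_limit_mv: float = 25.0,
) -> set[int]:
    """Channels failing the mains-power or amplifier-offset rule.

    A channel is flagged iff its integrated periodogram power in the
    48-52 Hz band exceeds ``line_power_limit`` or the absolute mean
    amplitude exceeds ``offset_limit_mv`` (millivolts; data are uV).
    """
    if sampling_rate < 104.0:
        raise ValueError(
            "sampling rate too low to observe the 50 Hz band (need >= 104 Hz)"
        )
    freqs, psd = sps.periodogram(epoch, fs=sampling_rate, axis=-1)
    band = (freqs >= 48.0) & (freqs <= 52.0)
    df = freqs[1] - freqs[0]
    band_power = psd[:, band].sum(axis=-1) * df
    offsets_uv = np.abs(np.nanmean(epoch, axis=-1))
    flagged = (band_power > line_power_limit) | (
        offsets_uv > offset_limit_mv * 1000.0
    )
    return set(np.nonzero(flagged)[0].tolist())


def repair_epochs(
    epochs: EpochSet, config: PreprocessConfig, report: PreprocessReport
) -> EpochSet:
    """Detect and spline-repair bad channels independently per epoch."""
    out = epochs.copy()
    for i in range(out.n_trials):
        bad = detect_bad_channels(
            out.data[i],
            out.sampling_rate,
            config.line_power_limit,
            config.offset_limit_mv,
        )
        report.repaired_channels.append(sorted(bad))
        if bad:
            out.data[i] = spline_interpolate(out.data[i], bad, out.montage)
    return out


def resample(epochs: EpochSet, target_rate: float) -> EpochSet:
    """Anti-aliased polyphase resampling of every epoch.

    Output length follows the polyphase convention ceil(n * up / down);
    the time axis keeps its origin and is re-spaced at the new rate.
    """
    if target_rate > epochs.sampling_rate:
        raise ValueError("target rate must not exceed the source rate")
    if np.isclose(target_rate, epochs.sampling_rate):
        return epochs.copy()
    ratio = Fraction(target_rate / epochs.sampling_rate).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    data = sps.resample_poly(epochs.data, up, down, axis=-1)
    dt = 1000.0 / target_rate
    times = epochs.times[0] + dt * np.arange(data.shape[-1])
    return EpochSet(
        data=data,
        times=times,
        sampling_rate=target_rate,
        trial_class=epochs.trial_class.copy(),
        montage=epochs.montage,
        condition=epochs.condition,
        participant=epochs.participant,
        group=epochs.group,
        trial_order=epochs.trial_order.copy(),
    )


def select_artifact_components(
    unmixed: np.ndarray,
    variance_floor: float = 0.01,
    threshold_scale: float = 1.0,
) -> tuple[set[int], dict[int, float]]:
    """Deterministic artifact-component selection by variance accounting.

    ``unmixed`` holds per-epoch component activations
    (epochs x components x samples), scaled so activation variance equals
    the variance each component accounts for in channel space (unit-norm
    mixing columns).  Candidates are components whose overall variance
    fraction exceeds ``variance_floor``; of those, the ones whose mean
    per-epoch variance strictly exceeds ``threshold_scale`` times the
    candidate average are selected.  Returns (selected ids, variance
    fraction per candidate).
    """
    n_epochs, n_comp, _ = unmixed.shape
    flat = unmixed.transpose(1, 0, 2).reshape(n_comp, -1)
    overall_var = flat.var(axis=1)
    total = overall_var.sum()
    fractions = overall_var / total if total > 0 else np.zeros(n_comp)
    candidates = np.nonzero(fractions > variance_floor)[0]
    if candidates.size == 0:
        return set(), {}
    per_epoch_var = unmixed.var(axis=2)  # (epochs, components)
    mean_var = per_epoch_var[:, candidates].mean(axis=0)
    threshold = threshold_scale * mean_var.mean()
    selected = candidates[mean_var > threshold]
    return (
        set(int(c) for c in selected),
        {int(c): float(fractions[c]) for c in candidates},
    )


def ica_remove_artifacts(
    epochs: EpochSet, config: PreprocessConfig, report: PreprocessReport
) -> EpochSet:
    """Infomax ICA on concatenated epochs; remove rule-selected components.

    The unmixing matrix is estimated once per participant: the
    concatenated epochs are centred and PCA-whitened, infomax runs on an
    evenly subsampled segment (estimation does not need every sample),
    and the resulting unmixing is composed with the whitener.
    Activations are rescaled to unit-norm mixing columns so the variance
    rule works in channel-space units, and the cleaned data are
    reprojected onto the measurement channels.
    """
    from mne.preprocessing import infomax

    n_trials, n_ch, n_samp = epochs.data.shape
    concat = epochs.data.transpose(1, 0, 2).reshape(n_ch, -1)
    mean = concat.mean(axis=1, keepdims=True)
    centred = concat - mean
    cov = centred @ centred.T / centred.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12 * evals.max())
    whitener = (evecs / np.sqrt(evals)) @ evecs.T  # symmetric ZCA whitener
    white = whitener @ centred
    step = max(1, white.shape[1] // config.ica_max_samples)
    fit_data = white[:, ::step]
    u_white = infomax(
        fit_data.T,
        random_state=config.ica_seed,
        max_iter=config.ica_max_iter,
        verbose="error",
    )
    unmixing = u_white @ whitener
    mixing = np.linalg.pinv(unmixing)
    # move mixing-column norms into the activations
    norms = np.linalg.norm(mixing, axis=0)
    norms[norms == 0] = 1.0
    mixing_n = mixing / norms
    acts = (unmixing @ centred) * norms[:, None]
    acts_e = acts.reshape(n_ch, n_trials, n_samp).transpose(1, 0, 2)
    selected, fractions = select_artifact_components(
        acts_e, config.variance_floor, config.threshold_scale
    )
    report.removed_components = sorted(selected)
    report.component_variance_fractions = fractions
    if selected:
        keep = np.setdiff1d(np.arange(n_ch), sorted(selected))
        cleaned = mixing_n[:, keep] @ acts[keep] + mean
    else:
        cleaned = mixing_n @ acts + mean
    out = epochs.copy()
    out.data = cleaned.reshape(n_ch, n_trials, n_samp).transpose(1, 0, 2)
    return out


def _baseline_mask(epochs: EpochSet, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (epochs.times >= lo) & (epochs.times < hi)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    return mask


def reject_epochs(
    epochs: EpochSet,
    amplitude_limit: float = 75.0,
    baseline_window: tuple[float, float] = (-100.0, 0.0),
) -> tuple[EpochSet, list[int]]:
    """Drop epochs whose activity strays beyond the limit from baseline.

    An epoch is rejected iff any channel/sample deviates from that
    channel's mean over the baseline window by more than
    ``amplitude_limit`` uV.
    """
    mask = _baseline_mask(epochs, baseline_window)
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    dev = np.abs(epochs.data - base).max(axis=(1, 2))
    bad = np.nonzero(dev > amplitude_limit)[0]
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad)
    return epochs.select_trials(keep), bad.tolist()


def bandpass_rereference_baseline(
    epochs: EpochSet,
    band: tuple[float, float] = (1.0, 25.0),
    reference_channels: tuple[str, ...] = MASTOIDS,
    baseline_window: tuple[float, float] = (-100.0, 0.0),
) -> EpochSet:
    """Zero-phase band-pass, mastoid-average re-reference, baseline-correct.

    The band-pass is a 4th-order Butterworth applied forward-backward;
    the average of the two mastoid leads is subtracted from every channel
    (making the mastoid average identically zero, so re-referencing is
    idempotent); each channel then has its baseline-window mean removed.
    """
    missing = [c for c in reference_channels if c not in epochs.montage.labels]
    if missing:
        raise ValueError(f"missing reference channels: {missing}")
    sos = sps.butter(
        4, band, btype="bandpass", fs=epochs.sampling_rate, output="sos"
    )
    out = epochs.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=-1)
    ref_idx = epochs.montage.indices(reference_channels)
    ref = out.data[:, ref_idx, :].mean(axis=1, keepdims=True)
    out.data = out.data - ref
    mask = _baseline_mask(out, baseline_window)
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def window_sample_count(
    window: tuple[float, float], sampling_rate: float
) -> int:
    """Samples in a half-open decode window: round(len * fs / 1000).

    0-700 ms at 128 Hz gives round(89.6) = 90 samples (0..703.125 ms
    half-open), the dimensionality the decoder expects.
    """
    return int(round((window[1] - window[0]) * sampling_rate / 1000.0))


def pair_and_window(
    epochs: EpochSet, window: tuple[float, float] = (0.0, 700.0)
) -> EpochSet:
    """Keep deviants with their immediately preceding surviving standards.

    Pairing is by acquisition order: a deviant survives only if the trial
    acquired immediately before it is a surviving standard, and a standard
    survives only as some deviant's predecessor — giving exact class
    balance.  Data are cropped to the half-open decode window.
    """
    if not (epochs.trial_class == CLASS_DEVIANT).any():
        raise ValueError("no deviant trials present")
    order_of = {o: i for i, o in enumerate(epochs.trial_order)}
    keep: list[int] = []
    for i in np.nonzero(epochs.trial_class == CLASS_DEVIANT)[0]:
        j = order_of.get(epochs.trial_order[i] - 1)
        if j is not None and epochs.trial_class[j] == CLASS_STANDARD:
            keep.extend([j, int(i)])
    keep = sorted(keep)

    start = np.searchsorted(epochs.times, window[0] - 1e-9)
    n_keep = window_sample_count(window, epochs.sampling_rate)
    if start + n_keep > epochs.n_samples:
        raise ValueError("decode window extends past the epoch")
    sel = epochs.select_trials(keep)
    sel.data = sel.data[:, :, start : start + n_keep]
    sel.times = epochs.times[start : start + n_keep]
    return sel


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def run_preprocess(
    epochs: EpochSet, config: PreprocessConfig | None = None
) -> tuple[EpochSet, PreprocessReport]:
    """Run the full chain in the documented stage order.

    repair -> resample -> ICA removal + reprojection -> epoch rejection ->
    band-pass -> mastoid re-reference -> baseline -> pair/window.
    """
    config = config or PreprocessConfig()
    report = PreprocessReport()
    report.stage_counts["input"] = epochs.n_trials

    out = repair_epochs(epochs, config, report)
    out = resample(out, config.target_rate)
    report.stage_counts["resampled"] = out.n_trials
    if config.run_ica:
        out = ica_remove_artifacts(out, config, report)
    out, rejected = reject_epochs(
        out, config.amplitude_limit, config.baseline_window
    )
    report.rejected_epochs = [int(epochs.trial_order[r]) for r in rejected]
    report.stage_counts["after_rejection"] = out.n_trials
    out = bandpass_rereference_baseline(
        out, config.band, config.reference_channels, config.baseline_window
    )
    out = pair_and_window(out, config.decode_window)
    report.stage_counts["paired"] = out.n_trials
    return out, report
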