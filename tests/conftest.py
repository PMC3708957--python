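import numpy as np
import pytest

from erpdecode.containers import EpochSet
from erpdecode.montage import generic_montage
from erpdecode.synth import SynthConfig, render_participant


@pytest.fixture(scope="session")
def small_montage():
    """8 scalp channels + mastoids on a synthetic upper-hemisphere layout."""
    return generic_montage(8)


@pytest.fixture(scope="session")
def quiet_config():
    """Small artifact-free configuration for fast deterministic renders."""
    return SynthConfig(
        n_channels=8,
        sampling_rate=128.0,
        trial_count=80,
        noise_sd=3.0,
        artifact_rates={},
        seed=7,
    )


@pytest.fixture(scope="session")
def quiet_epochs(quiet_config):
    return render_participant(quiet_config, "native", "19ms", 11, "native01")


def make_epochs(
    data, sampling_rate=128.0, classes=None, montage=None, t0=-200.0, **kw
):
    """EpochSet around a raw array with sensible defaults for tests."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    if montage is None:
        montage = generic_montage(n_ch - 2)
    if classes is None:
        classes = np.array(
            ["standard", "deviant"] * (n_trials // 2 + 1)
        )[:n_trials]
    times = t0 + 1000.0 / sampling_rate * np.arange(n_samp)
    return EpochSet(
        data=data,
        times=times,
        sampling_rate=sampling_rate,
        trial_class=np.asarray(classes),
        montage=montage,
        **kw,
    )
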