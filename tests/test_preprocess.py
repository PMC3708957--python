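"""Preprocessing rules: channel badness, resampling, ICA selection,
rejection, filtering/referencing and deviant-standard pairing."""

import numpy as np
import pytest
from scipy import signal as sps

from erpdecode.containers import CLASS_DEVIANT, CLASS_STANDARD
from erpdecode.preprocess import (
    PreprocessConfig,
    bandpass_rereference_baseline,
    detect_bad_channels,
    pair_and_window,
    reject_epochs,
    resample,
    run_preprocess,
    select_artifact_components,
    window_sample_count,
)
from erpdecode.synth import SynthConfig, render_participant

from conftest import make_epochs


class TestDetectBadChannels:
    fs = 512.0

    def _clean(self, rng, n_ch=8, n_samp=512):
        return 3.0 * rng.standard_normal((n_ch, n_samp))

    def test_clean_epoch_unflagged(self):
        epoch = self._clean(np.random.default_rng(0))
        assert detect_bad_channels(epoch, self.fs) == set()

    def test_mains_contamination_flagged(self):
        rng = np.random.default_rng(1)
        epoch = self._clean(rng)
        t = np.arange(epoch.shape[1]) / self.fs
        epoch[3] += 200.0 * np.sin(2 * np.pi * 50.0 * t)
        # independent band-power check: the sinusoid alone carries
        # ~A^2/2 = 20000 uV^2, far over the 5000 uV^2 default
        freqs, psd = sps.periodogram(epoch[3], fs=self.fs)
        band_power = psd[(freqs >= 48) & (freqs <= 52)].sum() * (
            freqs[1] - freqs[0]
        )
        assert band_power > 5000.0
        assert detect_bad_channels(epoch, self.fs) == {3}

    def test_offset_rule(self):
        epoch = self._clean(np.random.default_rng(2))
        epoch[5] += 30_000.0  # +30 mV
        assert detect_bad_channels(epoch, self.fs) == {5}

    def test_unobservable_band_rejected(self):
        with pytest.raises(ValueError, match="50 Hz"):
            detect_bad_channels(np.zeros((4, 100)), sampling_rate=100.0)


class TestResample:
    def test_sinusoid_amplitude_preserved(self):
        fs = 512.0
        t = np.arange(int(1.2 * fs)) / fs
        wave = np.sin(2 * np.pi * 5.0 * t)
        ep = make_epochs(
            np.tile(wave, (4, 10, 1)), sampling_rate=fs
        )
        out = resample(ep, 128.0)
        # compare against the analytic sinusoid on the new grid
        t_new = (out.times - out.times[0]) / 1000.0
        expected = np.sin(2 * np.pi * 5.0 * t_new)
        mid = slice(10, -10)  # ignore polyphase edge effects
        amp = np.abs(out.data[0, 0, mid]).max()
        assert abs(amp - 1.0) < 0.01
        err = np.abs(out.data[0, 0, mid] - expected[mid]).max()
        assert err < 0.02

    def test_identity_when_rates_match(self, quiet_epochs):
        out = resample(quiet_epochs, quiet_epochs.sampling_rate)
        np.testing.assert_array_equal(out.data, quiet_epochs.data)

    def test_1200ms_epoch_sample_count(self):
        fs = 512.0
        ep = make_epochs(
            np.zeros((2, 6, int(1.2 * fs))), sampling_rate=fs
        )
        out = resample(ep, 128.0)
        assert out.n_samples in (153, 154)
        assert out.n_trials == ep.n_trials


class TestArtifactComponentSelection:
    def test_identical_variances_select_nothing(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 4, 100))
        x /= x.std(axis=(0, 2), keepdims=True)  # equalize exactly? no: near
        # construct exactly identical per-component series
        x = np.tile(x[:, :1, :], (1, 4, 1))
        selected, _ = select_artifact_components(x)
        assert selected == set()

    def test_dominant_blink_component_selected(self):
        rng = np.random.default_rng(4)
        n_epochs, n_comp, n_samp = 20, 10, 64
        x = rng.standard_normal((n_epochs, n_comp, n_samp))
        x[:, 2, :] *= 4.0  # one component with ~30%+ of total variance
        selected, fractions = select_artifact_components(x)
        assert selected == {2}
        # independent variance accounting
        flat = x.transpose(1, 0, 2).reshape(n_comp, -1)
        v = flat.var(axis=1)
        assert fractions[2] == pytest.approx(v[2] / v.sum())

    def test_variance_floor_of_one_selects_nothing(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((5, 6, 50))
        selected, fractions = select_artifact_components(
            x, variance_floor=1.0
        )
        assert selected == set() and fractions == {}


class TestRejectEpochs:
    def test_zero_epochs_kept(self):
        ep = make_epochs(np.zeros((5, 6, 128)))
        out, rejected = reject_epochs(ep)
        assert rejected == [] and out.n_trials == 5

    def test_excursion_rejected_exactly(self):
        data = np.zeros((6, 6, 128))
        data[2, 1, 100] = 80.0
        ep = make_epochs(data)
        out, rejected = reject_epochs(ep, amplitude_limit=75.0)
        assert rejected == [2]
        assert out.n_trials == 5

    def test_constant_offset_is_baseline_relative(self):
        data = np.full((3, 6, 128), 100.0)  # +100 uV everywhere
        ep = make_epochs(data)
        out, rejected = reject_epochs(ep, amplitude_limit=75.0)
        assert rejected == []


class TestFilterReferenceBaseline:
    def test_baseline_zero_and_mastoid_zero(self, quiet_epochs):
        out = bandpass_rereference_baseline(quiet_epochs)
        mask = (out.times >= -100.0) & (out.times < 0.0)
        base = out.data[:, :, mask].mean(axis=2)
        assert np.abs(base).max() < 1e-9
        m_idx = out.montage.indices(("M1", "M2"))
        np.testing.assert_allclose(
            out.data[:, m_idx, :].mean(axis=1), 0.0, atol=1e-9
        )

    def test_mains_attenuated_20db(self):
        fs = 512.0
        t = np.arange(int(1.2 * fs)) / fs
        wave = np.sin(2 * np.pi * 50.0 * t)
        ep = make_epochs(np.tile(wave, (2, 6, 1)), sampling_rate=fs)
        out = bandpass_rereference_baseline(ep)
        # analytic response: forward-backward 4th-order Butterworth gives
        # |H|^2 at 50 Hz; steady-state attenuation must exceed 20 dB
        sos = sps.butter(4, (1, 25), btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[50.0], fs=fs)
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db > 20.0
        # and the filtered data's mid-epoch RMS reflects it (edges excluded)
        mid = slice(100, -100)
        rms_out = np.sqrt(np.mean(out.data[0, 0, mid] ** 2))
        assert rms_out < 0.1 * np.sqrt(0.5)

    def test_rereference_idempotent(self, quiet_epochs):
        once = bandpass_rereference_baseline(quiet_epochs)
        m_idx = once.montage.indices(("M1", "M2"))
        ref = once.data[:, m_idx, :].mean(axis=1, keepdims=True)
        again = once.data - ref
        np.testing.assert_allclose(again, once.data, atol=1e-9)

    def test_missing_reference_channels(self):
        from erpdecode.montage import generic_montage

        ep = make_epochs(
            np.zeros((2, 6, 128)),
            montage=generic_montage(6, include_mastoids=False),
        )
        with pytest.raises(ValueError, match="reference"):
            bandpass_rereference_baseline(ep)


class TestPairAndWindow:
    def _epochs(self, classes):
        n = len(classes)
        data = np.zeros((n, 6, 154))
        return make_epochs(data, classes=np.array(classes))

    def test_balanced_pairing(self):
        classes = ["standard", "standard", "deviant"] * 15
        out = pair_and_window(self._epochs(classes))
        assert out.n_trials == 30
        assert (out.trial_class == CLASS_DEVIANT).sum() == 15
        assert (out.trial_class == CLASS_STANDARD).sum() == 15

    def test_rejected_predecessor_drops_deviant(self):
        ep = self._epochs(
            ["standard", "standard", "deviant", "standard", "deviant"]
        )
        survivors = ep.select_trials([0, 2, 3, 4])  # standard 1 was rejected
        out = pair_and_window(survivors)
        # deviant at order 2 lost its predecessor; pair (3, 4) remains
        assert sorted(out.trial_order.tolist()) == [3, 4]

    def test_90_samples_at_128hz(self):
        classes = ["standard", "deviant"] * 10
        out = pair_and_window(self._epochs(classes))
        assert out.n_samples == 90
        assert window_sample_count((0.0, 700.0), 128.0) == 90
        assert out.times[0] >= 0.0

    def test_no_deviants_raises(self):
        with pytest.raises(ValueError, match="deviant"):
            pair_and_window(self._epochs(["standard"] * 5))


class TestFullChain:
    def test_artifact_free_data_passes_untouched(self, quiet_config):
        ep = render_participant(quiet_config, "native", "19ms", 13)
        out, report = run_preprocess(ep, PreprocessConfig(run_ica=False))
        assert report.mean_repairs_per_epoch == 0.0
        assert report.rejected_epochs == []
        counts = list(report.stage_counts.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert (out.trial_class == CLASS_DEVIANT).sum() == (
            out.trial_class == CLASS_STANDARD
        ).sum()
        assert out.n_samples == 90

    def test_chain_with_ica_removes_blink(self, quiet_config):
        cfg = SynthConfig(
            **{
                **quiet_config.__dict__,
                "artifact_rates": {"blink": 0.3, "bad_channel": 0.0},
                "trial_count": 60,
            }
        )
        ep = render_participant(cfg, "native", "19ms", 17)
        out, report = run_preprocess(ep, PreprocessConfig(run_ica=True))
        # the blink component is far above the candidate-average variance
        assert len(report.removed_components) >= 1
        # with blinks removed, few epochs should fail the +/-75 uV rule
        assert len(report.rejected_epochs) <= 10
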