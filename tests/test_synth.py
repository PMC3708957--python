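"""Generator contracts: oddball sequences, signal injection, behavior."""

import numpy as np
import pytest
from scipy import stats

from erpdecode.containers import CLASS_DEVIANT, CLASS_STANDARD
from erpdecode.discriminability import difference_wave
from erpdecode.montage import scalp_indices
from erpdecode.synth import (
    SynthConfig,
    generate_oddball_sequence,
    render_behavioral_vector,
    render_participant,
    simulate_cohort,
    to_recording,
)


class TestOddballSequence:
    def test_zero_probability_gives_all_standards(self):
        labels = generate_oddball_sequence(100, 0.0, seed=5)
        assert np.all(labels == CLASS_STANDARD)

    @pytest.mark.parametrize("seed", [7, 1, 99])
    def test_no_adjacent_deviants_and_first_standard(self, seed):
        labels = generate_oddball_sequence(20, 0.15, seed=seed)
        assert labels[0] == CLASS_STANDARD
        adjacent = [
            labels[i] == labels[i + 1] == CLASS_DEVIANT
            for i in range(len(labels) - 1)
        ]
        assert not any(adjacent)

    def test_long_run_deviant_fraction(self):
        n = 100_000
        labels = generate_oddball_sequence(n, 0.15, seed=1)
        k = int(np.sum(labels == CLASS_DEVIANT))
        lo, hi = stats.binom.interval(0.99, n, 0.15)
        assert lo <= k <= hi

    def test_high_rates_rejected(self):
        with pytest.raises(ValueError):
            generate_oddball_sequence(100, 0.5, seed=0)


class TestRenderParticipant:
    def test_null_signal_and_noise_gives_zeros(self, quiet_config):
        cfg = SynthConfig(
            **{
                **quiet_config.__dict__,
                "noise_sd": 0.0,
                "template_spec": [
                    {"name": "flat", "latency": 100.0, "width": 30.0,
                     "amplitude": 0.0}
                ],
            }
        )
        ep = render_participant(cfg, "native", "19ms", 3)
        assert np.all(ep.data == 0)

    def test_noiseless_difference_equals_template(self, quiet_config):
        cfg = SynthConfig(**{**quiet_config.__dict__, "noise_sd": 0.0})
        ep = render_participant(cfg, "native", "19ms", 3)
        gain = cfg.condition_gain["19ms"] * cfg.group_gain["native"]
        expected = sum(
            t.render(cfg.times_ms(), gain) for t in cfg.templates(ep.montage)
        )
        np.testing.assert_allclose(difference_wave(ep), expected, atol=1e-12)

    def test_amplitude_doubling_doubles_difference(self, quiet_config):
        base = {**quiet_config.__dict__, "noise_sd": 0.0}
        spec = [
            {"name": "MMN", "latency": 250.0, "width": 50.0, "amplitude": -2.0}
        ]
        double = [dict(spec[0], amplitude=-4.0)]
        d1 = difference_wave(
            render_participant(
                SynthConfig(**{**base, "template_spec": spec}),
                "native", "19ms", 3,
            )
        )
        d2 = difference_wave(
            render_participant(
                SynthConfig(**{**base, "template_spec": double}),
                "native", "19ms", 3,
            )
        )
        np.testing.assert_allclose(d2, 2.0 * d1, atol=1e-12)

    def test_noisy_difference_recovers_template(self, quiet_config):
        # averaging ~n_trials*0.15 deviants shrinks the 1/f background;
        # the threshold reflects Monte-Carlo under that noise model
        cfg = SynthConfig(
            **{**quiet_config.__dict__, "noise_sd": 5.0, "trial_count": 600}
        )
        gain = cfg.condition_gain["19ms"] * cfg.group_gain["native"]
        rs = []
        for seed in (21, 22, 23):
            ep = render_participant(cfg, "native", "19ms", seed)
            expected = sum(
                t.render(cfg.times_ms(), gain)
                for t in cfg.templates(ep.montage)
            )
            dw = difference_wave(ep)
            rs.append(np.corrcoef(dw.ravel(), expected.ravel())[0, 1])
        assert np.mean(rs) > 0.75
        # and recovery sharpens with trial count
        cfg_small = SynthConfig(
            **{**quiet_config.__dict__, "noise_sd": 5.0, "trial_count": 80}
        )
        ep = render_participant(cfg_small, "native", "19ms", 21)
        expected = sum(
            t.render(cfg_small.times_ms(), gain)
            for t in cfg_small.templates(ep.montage)
        )
        r_small = np.corrcoef(
            difference_wave(ep).ravel(), expected.ravel()
        )[0, 1]
        assert r_small < np.mean(rs)

    def test_deterministic_given_seed(self, quiet_config):
        a = render_participant(quiet_config, "native", "41ms", 9)
        b = render_participant(quiet_config, "native", "41ms", 9)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.trial_class, b.trial_class)

    def test_condition_grading_scales_separation(self, quiet_config):
        cfg = SynthConfig(**{**quiet_config.__dict__, "noise_sd": 0.0})
        norms = []
        for cond in ("63ms", "41ms", "19ms"):
            ep = render_participant(cfg, "native", cond, 3)
            norms.append(np.linalg.norm(difference_wave(ep)))
        assert norms[0] < norms[1] < norms[2]

    def test_template_outside_window_rejected(self, quiet_config):
        cfg = SynthConfig(
            **{
                **quiet_config.__dict__,
                "template_spec": [
                    {"name": "late", "latency": 5000.0, "width": 30.0,
                     "amplitude": -1.0}
                ],
            }
        )
        with pytest.raises(ValueError, match="latency"):
            render_participant(cfg, "native", "19ms", 3)

    def test_recording_roundtrip_events(self, quiet_epochs):
        rec = to_recording(quiet_epochs)
        assert rec.events.shape[0] == quiet_epochs.n_trials
        codes = np.where(quiet_epochs.trial_class == CLASS_DEVIANT, 2, 1)
        np.testing.assert_array_equal(rec.events[:, 1], codes)
        assert np.all(np.diff(rec.events[:, 0]) > 0)


class TestBehavior:
    def test_noiseless_logistic_curve(self):
        v = render_behavioral_vector(
            "native", seed=0, boundary={"native": 4.0}, noise_sd=0.0
        )
        steps = np.arange(1, 8)
        expected = 1.0 / (1.0 + np.exp((steps - 4.0) / 0.7))
        np.testing.assert_allclose(v, expected, atol=1e-12)

    def test_values_bounded(self):
        for seed in range(10):
            v = render_behavioral_vector("nonnative", seed=seed, noise_sd=0.3)
            assert np.all(v >= 0.0) and np.all(v <= 1.0)

    def test_group_boundary_shift_largest_midcontinuum(self):
        a = render_behavioral_vector("native", 0, noise_sd=0.0)
        b = render_behavioral_vector("nonnative", 0, noise_sd=0.0)
        gap = np.abs(a - b)
        # the largest group difference sits between the two boundaries
        assert 2 <= np.argmax(gap) <= 4


def test_cohort_is_deterministic_and_complete():
    cfg = SynthConfig(
        n_channels=8, trial_count=40, artifact_rates={}, seed=5
    )
    a = simulate_cohort(cfg, {"native": 2, "nonnative": 2})
    b = simulate_cohort(cfg, {"native": 2, "nonnative": 2})
    assert [p.participant for p in a] == [p.participant for p in b]
    for pa, pb in zip(a, b):
        for cond in cfg.conditions:
            assert np.array_equal(pa.epochs[cond].data, pb.epochs[cond].data)
        np.testing.assert_array_equal(pa.behavior, pb.behavior)
    assert {p.group for p in a} == {"native", "nonnative"}
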