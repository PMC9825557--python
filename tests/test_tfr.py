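"""Time-frequency pipeline: preprocessing, spectrograms, robust averaging,
baseline rescaling and the within-subject factorial inference."""

import numpy as np
import pytest

from amygaze import synth, tfr
from amygaze.synth import LFP_FS, LfpEpoch
from amygaze.tfr import (HIGH_BAND, LOW_BAND, TimeFreqImage, baseline_rescale,
                         factorial_inference, preprocess, robust_average,
                         smooth_tf, spectrogram, time_grid)


def noise_epoch(seed=0, scale=1.0, side="Contra", emotion="fear"):
    rng = np.random.default_rng(seed)
    n = int(6 * LFP_FS)
    return LfpEpoch(samples=scale * synth.pink_noise(n, LFP_FS, rng),
                    recording_side=side, emotion=emotion)


class TestPreprocess:
    def test_identical_contacts_cancel(self):
        rng = np.random.default_rng(0)
        ch = rng.standard_normal(int(20 * LFP_FS))
        eps = preprocess(np.stack([ch, ch]), [8.0])
        assert np.allclose(eps[0].samples, 0.0)

    def test_epoch_length_and_highpass(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal(int(20 * LFP_FS)) + 40.0  # constant offset
        eps = preprocess(sig, [5.0, 10.0])
        assert len(eps) == 2
        assert len(eps[0].samples) == int(6 * LFP_FS)
        assert abs(eps[0].samples.mean()) < 0.1  # offset removed

    def test_events_near_edges_rejected(self):
        sig = np.zeros(int(10 * LFP_FS))
        with pytest.raises(ValueError, match="edge"):
            preprocess(sig, [1.0])

    def test_single_contact_requires_bipolar(self):
        with pytest.raises(ValueError, match="contacts"):
            preprocess(np.zeros((1, 1000)), [])


class TestSpectrogram:
    def test_pure_tone_concentrates_at_its_frequency(self):
        n = int(6 * LFP_FS)
        t = np.arange(n) / LFP_FS - 2.0
        for freq, band in ((20.0, LOW_BAND), (99.0, HIGH_BAND)):
            ep = LfpEpoch(samples=np.cos(2 * np.pi * freq * t))
            tf = spectrogram(ep, band)
            peak = tf.freqs[np.argmax(tf.values.mean(axis=1))]
            assert abs(peak - freq) <= band.freq_step + 1.5

    def test_zero_signal_gives_zero_power(self):
        ep = LfpEpoch(samples=np.zeros(int(6 * LFP_FS)))
        assert np.all(spectrogram(ep, LOW_BAND).values == 0.0)

    def test_shared_grid_at_25ms_steps(self):
        times = time_grid(HIGH_BAND)
        steps = np.diff(times)
        np.testing.assert_allclose(steps, 0.025)
        a = spectrogram(noise_epoch(1), HIGH_BAND)
        b = spectrogram(noise_epoch(2), HIGH_BAND)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.freqs, b.freqs)

    def test_band_beyond_nyquist_rejected(self):
        ep = LfpEpoch(samples=np.zeros(int(6 * LFP_FS)), fs=256.0)
        with pytest.raises(ValueError, match="Nyquist"):
            spectrogram(ep, HIGH_BAND)

    def test_power_scales_quadratically_percent_change_invariant(self):
        ep1 = noise_epoch(3)
        ep2 = LfpEpoch(samples=3.0 * ep1.samples, recording_side="Contra",
                       emotion="fear")
        tf1 = spectrogram(ep1, HIGH_BAND)
        tf2 = spectrogram(ep2, HIGH_BAND)
        np.testing.assert_allclose(tf2.values, 9.0 * tf1.values, rtol=1e-9)
        np.testing.assert_allclose(baseline_rescale(tf2).values,
                                   baseline_rescale(tf1).values, rtol=1e-6)


class TestRobustAverage:
    def test_identical_trials_reduce_to_arithmetic_mean(self):
        img = np.random.default_rng(0).random((5, 6)) + 1.0
        mean, weights = robust_average([img] * 4)
        np.testing.assert_allclose(mean, img)
        assert np.all(weights > 0.99)

    def test_outlier_trial_downweighted(self, rng):
        clean = rng.standard_normal((20, 4, 4)) ** 2 + 1.0
        stack = np.concatenate([clean, 100.0 * clean[:1]])
        robust, weights = robust_average(stack)
        arith = stack.mean(axis=0)
        target = clean.mean(axis=0)
        closer = np.abs(robust - target) < np.abs(arith - target)
        assert closer.mean() > 0.9
        assert weights[-1].mean() < 0.1

    def test_inliers_keep_full_weight(self, rng):
        stack = 1.0 + 0.01 * rng.standard_normal((10, 3, 3))
        _, weights = robust_average(stack)
        assert weights.min() > 0.3 and weights.mean() > 0.8

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            robust_average([np.ones((2, 2))] * 2)


class TestBaseline:
    def grid_image(self, values):
        times = time_grid(HIGH_BAND)
        freqs = HIGH_BAND.freqs
        return TimeFreqImage(values=np.broadcast_to(values, (len(freqs),
                                                             len(times))).copy(),
                             freqs=freqs, times=times, band="high")

    def test_flat_power_rescales_to_zero(self):
        img = baseline_rescale(self.grid_image(5.0))
        np.testing.assert_allclose(img.values, 0.0)

    def test_doubling_reads_plus_hundred_percent(self):
        tf = self.grid_image(1.0)
        tf.values[:, tf.times >= 0] = 2.0
        img = baseline_rescale(tf)
        np.testing.assert_allclose(img.values[:, tf.times >= 0.1], 100.0)
        np.testing.assert_allclose(img.values[:, tf.times <= -0.8], 0.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            baseline_rescale(self.grid_image(0.0))

    def test_smoothing_preserves_grid(self):
        img = smooth_tf(self.grid_image(1.0), (4.0, 2.0))
        assert img.values.shape == (len(HIGH_BAND.freqs), len(time_grid(HIGH_BAND)))


class TestSpectralFlatness:
    def test_white_noise_power_flat_across_frequency(self, rng):
        n = int(6 * LFP_FS)
        times = time_grid(HIGH_BAND, -0.8, 0.6)
        power = np.zeros((len(HIGH_BAND.freqs), len(times)))
        n_trials = 200
        for _ in range(n_trials):
            ep = LfpEpoch(samples=rng.standard_normal(n))
            power += spectrogram(ep, HIGH_BAND, times=times).values
        per_freq = power.mean(axis=1) / n_trials
        rel_dev = np.abs(per_freq / per_freq.mean() - 1.0)
        assert rel_dev.max() < 0.10


class TestFactorialInference:
    def test_f_map_nonnegative_and_masked(self, truth):
        epochs = synth.synth_lfp_cohort(4, 4, truth, seed=1)
        times = time_grid(HIGH_BAND, -0.8, 0.6)
        images = tfr.condition_images(epochs, HIGH_BAND, times=times)
        sm = factorial_inference(images, HIGH_BAND, n_perm=100, seed=1)
        assert (sm.stat >= 0).all()
        ref = images[0][("Contra", "fear")]
        outside = (ref.times < 0) | (ref.times > 0.4)
        assert np.isnan(sm.p_fwe[:, outside]).all()

    def test_missing_cell_rejected(self, truth):
        epochs = synth.synth_lfp_cohort(3, 4, truth, seed=2)
        epochs = [ep for ep in epochs if not (ep.participant == 0 and
                                              ep.emotion == "fear" and
                                              ep.recording_side == "Ipsi")]
        times = time_grid(HIGH_BAND, -0.8, 0.6)
        images = tfr.condition_images(epochs, HIGH_BAND, times=times)
        with pytest.raises(ValueError, match="cells"):
            factorial_inference(images, HIGH_BAND, n_perm=50)

    def test_marginal_traces_shapes(self, truth):
        epochs = synth.synth_lfp_cohort(3, 4, truth, seed=3)
        times = time_grid(HIGH_BAND, -0.8, 0.6)
        images = tfr.condition_images(epochs, HIGH_BAND, times=times)
        traces = tfr.marginal_traces(images, 99.0)
        assert set(traces) == set(tfr.CELLS_2X2)
        for tr in traces.values():
            assert tr["mean"].shape == tr["se"].shape == tr["times"].shape
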