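import numpy as np
import pytest

from conftest import brute_force_mad_outliers, make_raw

import megfalff.preprocess as pp
from megfalff.preprocess import (CANONICAL_BANDS, BandDefinition, bandpass,
                                 decompose_and_flag, detect_bad_epochs,
                                 downsample, epoch, remove_components,
                                 remove_line_noise)


def _sine(freq, fs, dur, n_ch=2, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return make_raw(np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1)), fs)


class TestDownsample:
    def test_sample_count(self):
        rec = make_raw(np.random.default_rng(0).standard_normal((3, 180_000)), 1000.0)
        out = downsample(rec, 200.0)
        assert out.n_samples == 36_000
        assert out.fs == 200.0

    def test_passband_amplitude_preserved(self):
        out = downsample(_sine(10.0, 1000.0, 10.0), 200.0)
        ratio = out.data[0].std() / (1.0 / np.sqrt(2))
        assert abs(ratio - 1.0) < 0.01

    def test_aliasing_band_attenuated(self):
        """130-Hz content must be gone after decimation to 200 Hz (>=40 dB)."""
        out = downsample(_sine(130.0, 1000.0, 10.0), 200.0)
        # measure away from the filter's edge transients
        assert out.data[0, 50:-50].std() <= 0.01 * (1.0 / np.sqrt(2))

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample(_sine(10.0, 1000.0, 1.0), 300.0)


class TestLineFilter:
    def test_line_component_removed(self):
        rec = _sine(60.0, 1000.0, 10.0)
        out = remove_line_noise(rec, 60.0)
        assert np.sqrt(np.mean(out.data**2)) <= 0.03 * np.sqrt(np.mean(rec.data**2))

    def test_out_of_notch_content_untouched(self):
        rec = _sine(45.0, 1000.0, 10.0)
        out = remove_line_noise(rec, 60.0)
        assert np.allclose(out.data, rec.data, atol=0.01 * rec.data.std())

    def test_neighbouring_frequency_barely_changed(self):
        rec = _sine(61.0, 1000.0, 10.0)
        out = remove_line_noise(rec, 60.0)
        assert abs(out.data[0].std() / rec.data[0].std() - 1.0) < 0.05

    def test_dc_unchanged(self):
        rec = make_raw(np.full((2, 4000), 3.7), 1000.0)
        out = remove_line_noise(rec, 60.0)
        assert np.allclose(out.data, rec.data, atol=1e-9)

    def test_line_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            remove_line_noise(_sine(10.0, 100.0, 2.0), 60.0)


class TestBandpass:
    def test_gamma_passband(self):
        out = bandpass(_sine(45.0, 200.0, 10.0), CANONICAL_BANDS["gamma"])
        assert out.data[0].std() >= 0.95 * (1.0 / np.sqrt(2))

    def test_gamma_stopband(self):
        out = bandpass(_sine(10.0, 200.0, 10.0), CANONICAL_BANDS["gamma"])
        assert out.data[0].std() <= 0.01 * (1.0 / np.sqrt(2))

    def test_zero_phase(self):
        data = np.zeros((1, 2000))
        data[0, 1000] = 1.0
        out = bandpass(make_raw(data, 200.0), CANONICAL_BANDS["alpha"])
        assert abs(int(np.argmax(np.abs(out.data[0]))) - 1000) <= 1

    def test_cascade_squares_magnitude_response(self):
        """Filtering twice equals one pass with the squared magnitude response."""
        band = CANONICAL_BANDS["beta"]
        for f in (14.0, 30.0, 35.0):
            rec = _sine(f, 200.0, 20.0)
            once = bandpass(rec, band).data[0, 1000:-1000].std()
            twice = bandpass(bandpass(rec, band), band).data[0, 1000:-1000].std()
            base = rec.data[0, 1000:-1000].std()
            assert twice / base == pytest.approx((once / base) ** 2, rel=0.02)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_sine(10.0, 100.0, 2.0), BandDefinition("gamma", 30.0, 60.0))


class TestEpoching:
    def test_counts(self):
        rec = make_raw(np.zeros((2, 36_000)), 200.0)
        assert epoch(rec, 2000.0).data.shape == (2, 90, 400)

    def test_remainder_dropped(self):
        rec = make_raw(np.zeros((2, 36_200)), 200.0)  # 181 s
        assert epoch(rec, 2000.0).n_epochs == 90

    def test_too_short_rejected(self):
        rec = make_raw(np.zeros((2, 380)), 200.0)  # 1.9 s
        with pytest.raises(ValueError):
            epoch(rec, 2000.0)
        with pytest.raises(ValueError):
            epoch(make_raw(np.zeros((2, 4000)), 200.0), -5.0)


class TestBadEpochDetection:
    def _from_g(self, g):
        data = np.asarray(g, float).reshape(1, -1, 1)
        return pp.EpochedBandData(data=data, band=None, fs=0.5, epoch_ms=2000.0)

    def test_identical_epochs_clean(self):
        assert detect_bad_epochs(self._from_g(np.ones(10))).size == 0

    def test_single_large_outlier(self):
        g = np.array([1.0] * 9 + [100.0])
        with pytest.warns(UserWarning):
            flagged = detect_bad_epochs(self._from_g(g))
        assert flagged.tolist() == [9]

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2023)
        for _ in range(200):
            g = np.abs(rng.standard_normal(rng.integers(5, 60))) + 0.1
            if rng.random() < 0.5:
                g[rng.integers(len(g))] *= rng.uniform(5, 50)
            expect = brute_force_mad_outliers(g)
            got = detect_bad_epochs(self._from_g(g))
            assert np.array_equal(got, expect)

    def test_simulated_bursts_flagged_exactly(self, sim_subject):
        rec = pp.trim(pp.remove_line_noise(
            pp.downsample(sim_subject, 200.0), 60.0), 2.0)
        bb = epoch(rec, 2000.0)
        assert detect_bad_epochs(bb).tolist() == \
            sim_subject.truth["bad_epochs"].tolist()

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            detect_bad_epochs(self._from_g(np.ones(2)))


class TestICA:
    def test_blink_component_flagged_as_eog(self, sim_subject):
        rec = pp.trim(pp.remove_line_noise(
            pp.downsample(sim_subject, 200.0), 60.0), 2.0)
        d = decompose_and_flag(rec, n_components=12)
        assert d.eog_correlated.any()

    def test_white_noise_components_not_kurtosis_flagged(self):
        rng = np.random.default_rng(11)
        rec = make_raw(rng.standard_normal((8, 8000)), 200.0,
                       eog=rng.standard_normal((2, 8000)))
        d = decompose_and_flag(rec, n_components=8)
        assert not d.high_kurtosis.any()
        assert not d.eog_correlated.any()

    def test_reconstruction_identity(self, sim_subject):
        rec = pp.trim(pp.downsample(sim_subject, 200.0), 2.0)
        d = decompose_and_flag(rec, n_components=12)
        assert np.allclose(d.reconstruct(), rec.data,
                           atol=1e-9 * np.abs(rec.data).max())

    def test_blink_locked_average_reduced(self, sim_subject, short_scenario):
        """Removing flagged components kills >=80% of the blink-locked response."""
        rec = pp.trim(pp.remove_line_noise(
            pp.downsample(sim_subject, 200.0), 60.0), 2.0)
        d = decompose_and_flag(rec, n_components=12)
        clean = remove_components(rec, d)
        onsets = sim_subject.truth["blink_onsets"] - short_scenario.trim
        onsets = onsets[(onsets > 0.5) & (onsets < rec.duration - 1.5)]
        front = int(np.argmax(rec.sensor_array.positions[:, 1]))

        def locked(data):
            segs = [data[front, int(o * 200):int(o * 200) + 200] for o in onsets]
            return np.ptp(np.mean(segs, axis=0))

        assert locked(clean.data) <= 0.2 * locked(rec.data)

    def test_remove_nothing_is_identity(self, sim_subject):
        rec = pp.trim(pp.downsample(sim_subject, 200.0), 2.0)
        d = decompose_and_flag(rec, n_components=12)
        out = remove_components(rec, d, flags=np.zeros(d.n_components, bool))
        assert np.array_equal(out.data, rec.data)

    def test_all_flagged_refused(self, sim_subject):
        rec = pp.trim(pp.downsample(sim_subject, 200.0), 2.0)
        d = decompose_and_flag(rec, n_components=4)
        with pytest.raises(ValueError):
            remove_components(rec, d, flags=np.ones(d.n_components, bool))

    def test_artifact_removal_recovers_brain_signal(self):
        """Rank-1 artifact + rank-1 brain source: removing the artifact
        component leaves sensor data correlating >= 0.99 with the brain part."""
        rng = np.random.default_rng(5)
        n = 12_000
        brain = rng.laplace(size=n)
        blink = np.zeros(n)
        blink[rng.integers(0, n - 100, size=40)] = 1.0
        blink = np.convolve(blink, np.hanning(80), mode="same") * 8
        mix_brain = rng.standard_normal(6)
        mix_blink = rng.standard_normal(6)
        data = np.outer(mix_brain, brain) + np.outer(mix_blink, blink)
        rec = make_raw(data, 200.0, eog=np.vstack([blink, 0.3 * blink]))
        d = decompose_and_flag(rec, n_components=2)
        assert d.eog_correlated.sum() == 1
        clean = remove_components(rec, d, flags=d.eog_correlated)
        brain_only = np.outer(mix_brain, brain)
        ch = int(np.argmax(np.abs(mix_brain)))
        r = np.corrcoef(clean.data[ch], brain_only[ch])[0, 1]
        assert r >= 0.99

    def test_constant_eog_warns(self):
        rng = np.random.default_rng(3)
        rec = make_raw(rng.standard_normal((6, 4000)), 200.0,
                       eog=np.zeros((2, 4000)))
        with pytest.warns(UserWarning):
            decompose_and_flag(rec, n_components=4)
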