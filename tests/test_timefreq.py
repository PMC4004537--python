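import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import betabind as bb
from betabind.timefreq import (DEFAULT_BASELINE, Band, MorletTFR,
                               WaveletFamily, morlet_kernel)


class TestResolutionLaw:
    def test_printed_coefficients(self):
        wf, wt = bb.wavelet_fwhm(20.0, 10.0)
        assert round(wf / 20.0, 3) == 0.235
        assert abs(wt * 20.0 - 3.74) <= 0.01  # printed value is truncated
        wf10, wt10 = bb.wavelet_fwhm(10.0, 10.0)
        assert wt10 == pytest.approx(0.374, abs=1e-3)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.5, max_value=50.0))
    def test_scale_invariance(self, f):
        wf1, wt1 = bb.wavelet_fwhm(f, 10.0)
        wf2, wt2 = bb.wavelet_fwhm(2 * f, 10.0)
        assert wf2 / wf1 == pytest.approx(2.0)
        assert wt2 / wt1 == pytest.approx(0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bb.wavelet_fwhm(-1.0, 10.0)
        with pytest.raises(ValueError):
            bb.wavelet_fwhm(10.0, 0.0)


class TestTFPower:
    def test_sinusoid_peak_and_spectral_width(self):
        fs = 250.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 20.0 * t)[None, None, :]
        freqs = np.arange(15.0, 25.25, 0.25)
        tf = MorletTFR(m=10, freqs=freqs, fs=fs).transform(x)
        mid = tf.values.shape[-1] // 2
        prof = np.sqrt(tf.values[0, 0, :, mid])  # amplitude response
        assert freqs[prof.argmax()] == pytest.approx(20.0, abs=0.3)
        half = prof.max() / 2
        above = freqs[prof >= half]
        width = above.max() - above.min()
        assert width == pytest.approx(4.7, abs=0.5)  # Wf(20) = 0.235 * 20

    def test_zero_signal_and_power_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 3, 500))
        tfr = MorletTFR(m=10, freqs=[10.0, 20.0], fs=250.0)
        assert np.all(tfr.transform(np.zeros((1, 2, 400))).values == 0)
        p1 = tfr.transform(x).values
        p3 = tfr.transform(3.0 * x).values
        assert np.allclose(p3, 9.0 * p1, rtol=1e-6)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(1)
        fs = 256.0
        x = rng.standard_normal((2, 3, 512))
        freqs = [8.0, 13.0, 21.0]
        tf = MorletTFR(m=10, freqs=freqs, fs=fs).transform(x)
        for j, f in enumerate(freqs):
            k = morlet_kernel(f, 10.0, fs)
            for tr in range(2):
                for s in range(3):
                    direct = np.convolve(x[tr, s], k, mode="same") / fs
                    p = np.abs(direct) ** 2
                    got = tf.values[tr, s, j]
                    assert np.allclose(got, p, rtol=1e-9, atol=1e-12)

    def test_long_wavelets_dropped_with_warning(self, caplog):
        x = np.zeros((1, 1, 300))
        with caplog.at_level("WARNING", logger="betabind.timefreq"):
            tf = MorletTFR(m=10, freqs=[1.0, 30.0], fs=250.0).transform(x)
        assert list(tf.freqs) == [30.0]
        assert "dropping" in caplog.text

    def test_white_noise_power_is_flat_in_time_and_frequency(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((300, 1, 750))
        freqs = np.arange(10.0, 90.0, 10.0)
        tf = MorletTFR(m=10, freqs=freqs, fs=250.0).transform(x)
        mean_p = tf.values.mean(axis=0)[0]  # freqs x samples
        for j in range(len(freqs)):
            v = mean_p[j, tf.valid_mask[j]]
            assert v.std() / v.mean() < 0.10
        # energy normalization: expected power equals the flat PSD level
        centers = np.array([mean_p[j, tf.valid_mask[j]].mean()
                            for j in range(len(freqs))])
        assert centers.std() / centers.mean() < 0.05


class TestBaselineNormalization:
    @staticmethod
    def _tf_of(x, fs=250.0, freqs=(20.0,)):
        t0 = -1800.0
        times = t0 + np.arange(x.shape[-1]) * 1000.0 / fs
        tfr = MorletTFR(m=10, freqs=list(freqs), fs=fs)
        tf = tfr.transform(x)
        tf.times = times
        return tf

    def test_stationary_signal_gives_zero(self):
        # the trial-averaged normalized map of a stationary signal is flat
        # at zero (single-trial log values carry the usual negative
        # chi-square bias, so the average is taken before the log)
        rng = np.random.default_rng(3)
        x = rng.standard_normal((100, 1, 750))
        tf = self._tf_of(x).mean_over_trials()
        norm = bb.baseline_log2ratio(tf, DEFAULT_BASELINE)
        sel = norm.valid_mask[0]
        assert abs(np.nanmean(norm.values[0, 0, 0, sel])) < 0.05

    def test_power_doubling_gives_plus_one(self):
        rng = np.random.default_rng(4)
        fs = 250.0
        x = rng.standard_normal((400, 1, 750))
        post = np.arange(750) * 1000.0 / fs - 1800.0 >= 0
        x[:, :, post] *= np.sqrt(2.0)
        tf = self._tf_of(x).mean_over_trials()
        norm = bb.baseline_log2ratio(tf, DEFAULT_BASELINE)
        times = norm.times
        sel = norm.valid_mask[0] & (times >= 200) & (times <= 1000)
        assert np.nanmean(norm.values[0, 0, 0, sel]) == pytest.approx(1.0, abs=0.12)

    def test_generator_alpha_drop_is_negative(self, clean_session):
        _, ep = clean_session
        sub = ep.select(np.arange(40))
        tf = bb.tf_power(sub, WaveletFamily(freqs=np.array([10.0]), fs=ep.fs))
        norm = bb.baseline_log2ratio(tf, DEFAULT_BASELINE)
        op = ep.layout.region_sensors("occipito-parietal")
        sel = norm.valid_mask[0] & (norm.times >= 300) & (norm.times <= 1100)
        assert np.nanmean(norm.values[:, op][:, :, 0, sel]) < -0.3

    def test_double_normalization_rejected(self):
        x = np.random.default_rng(0).standard_normal((5, 1, 750))
        norm = bb.baseline_log2ratio(self._tf_of(x), DEFAULT_BASELINE)
        with pytest.raises(ValueError, match="already"):
            bb.baseline_log2ratio(norm, DEFAULT_BASELINE)


class TestBandAverage:
    def test_single_frequency_band_is_a_slice(self):
        x = np.random.default_rng(5).standard_normal((3, 2, 600))
        tf = MorletTFR(m=10, freqs=[15.0, 20.0, 25.0], fs=250.0).transform(x)
        ba = bb.band_average(tf, Band("x", 20.0, 20.0))
        j = tf.freq_index(20.0)
        ok = tf.valid_mask[j]
        assert np.allclose(ba[:, :, ok], tf.values[:, :, j, ok])

    def test_uniform_values_are_preserved(self):
        x = np.random.default_rng(6).standard_normal((2, 1, 600))
        tf = MorletTFR(m=10, freqs=np.arange(15.0, 26.0), fs=250.0).transform(x)
        tf.values = np.full_like(tf.values, 2.5)
        ba = bb.band_average(tf, bb.BETA_BAND)
        valid = np.isfinite(ba[0, 0])
        assert np.allclose(ba[0, 0, valid], 2.5)

    def test_empty_band_raises(self):
        x = np.zeros((1, 1, 600))
        tf = MorletTFR(m=10, freqs=[10.0], fs=250.0).transform(x)
        with pytest.raises(ValueError, match="no analysis frequency"):
            bb.band_average(tf, Band("none", 40.0, 50.0))


class TestIdentifyBand:
    def test_flat_noise_has_no_band(self, layout20):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((30, 20, 750)).astype(np.float32)
        times = -1800.0 + np.arange(750) * 4.0
        tf = MorletTFR(m=10, freqs=np.arange(5.0, 16.0), fs=250.0).transform(x)
        tf.times = times
        norm = bb.baseline_log2ratio(tf, DEFAULT_BASELINE)
        with pytest.raises(ValueError, match="no sustained band"):
            bb.identify_band(norm, "occipital", (0.0, 1100.0), "increase",
                             (5.0, 15.0), layout=layout20)

    def test_recovers_planted_alpha_and_gamma(self, clean_session):
        from betabind.pipeline import _identify_bands
        _, ep = clean_session
        bands = _identify_bands(ep, np.arange(4.0, 101.0), m=10.0)
        assert abs(bands["alpha"].f_lo - 8.0) <= 2.0
        assert abs(bands["alpha"].f_hi - 12.0) <= 2.0
        assert abs(bands["gamma"].f_lo - 55.0) <= 5.0
        assert abs(bands["gamma"].f_hi - 85.0) <= 5.0

    def test_scale_invariance(self, layout20):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((20, 20, 750))
        x += 3.0 * np.sin(2 * np.pi * 10.0 * np.arange(750) / 250.0)
        tf = MorletTFR(m=10, freqs=np.arange(5.0, 16.0), fs=250.0).transform(x)
        tf.times = -1800.0 + np.arange(750) * 4.0
        b1 = bb.identify_band(tf, "occipital", (-1500.0, -700.0), "increase",
                              (5.0, 15.0), layout=layout20)
        tf.values = tf.values * 37.0
        b2 = bb.identify_band(tf, "occipital", (-1500.0, -700.0), "increase",
                              (5.0, 15.0), layout=layout20)
        assert (b1.f_lo, b1.f_hi) == (b2.f_lo, b2.f_hi)


class TestShrinkBand:
    @pytest.mark.parametrize("band,expected", [
        ((15.0, 25.0), (17.0, 22.0)),
        ((8.0, 12.0), (9.0, 11.0)),
    ])
    def test_shrinks_by_wavelet_resolution(self, band, expected):
        out = bb.shrink_band(Band("b", *band), m=10.0)
        assert (out.f_lo, out.f_hi) == expected

    def test_too_narrow_band_collapses(self):
        with pytest.raises(ValueError, match="too narrow"):
            bb.shrink_band(Band("b", 19.0, 21.0), m=10.0)
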