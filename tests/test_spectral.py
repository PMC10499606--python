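"""Morlet decomposition, normalization, difference maps, band traces."""

import numpy as np
import pytest

import hypoconn as hc
from hypoconn.preprocess import TrialEpochs


def make_epochs(data, rate=250.0, conditions=None, t0=-1.0):
    n_ch, n_tr, n_t = data.shape
    return TrialEpochs(
        data=data, rate=rate, times=t0 + np.arange(n_t) / rate,
        conditions=conditions or ["sweet_fat"] * n_tr,
        trial_index=np.arange(1, n_tr + 1),
        channel_ids=[f"C{i}" for i in range(n_ch)],
    )


WSPEC = hc.WaveletSpec(f_min=3.0, f_max=100.0, voices_per_octave=12)


class TestMorletTFR:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        rate = 250.0
        t = np.arange(int(4 * rate)) / rate
        data = np.sin(2 * np.pi * 6.0 * t)[None, None, :]
        tf = hc.morlet_tfr(make_epochs(data, rate), WSPEC)
        mean_pow = tf.power[0, 0][:, tf.valid_mask.all(axis=0)].mean(axis=1)
        f_peak = tf.freqs[np.argmax(mean_pow)]
        assert 5.5 <= f_peak <= 6.5

    def test_two_tone_peaks_match_fft_oracle(self):
        # 6 + 80 Hz mixture: wavelet peak frequencies agree with an FFT
        # periodogram oracle within half a voice step
        rate = 500.0
        t = np.arange(int(8 * rate)) / rate
        x = np.sin(2 * np.pi * 6 * t) + 0.7 * np.sin(2 * np.pi * 80 * t)
        spec = hc.WaveletSpec(f_min=3.0, f_max=150.0, voices_per_octave=16)
        tf = hc.morlet_tfr(make_epochs(x[None, None, :], rate), spec)
        mean_pow = tf.power[0, 0][:, tf.valid_mask.all(axis=0)].mean(axis=1)

        ft = np.abs(np.fft.rfft(x)) ** 2
        fax = np.fft.rfftfreq(x.size, 1 / rate)
        oracle = [fax[np.argmax(ft * ((fax > 3) & (fax < 20)))],
                  fax[np.argmax(ft * (fax > 20))]]
        lo = mean_pow * (tf.freqs < 20)
        hi = mean_pow * (tf.freqs >= 20)
        step = 2 ** (0.5 / spec.voices_per_octave)
        assert tf.freqs[np.argmax(lo)] / oracle[0] <= step * 1.001
        assert oracle[0] / tf.freqs[np.argmax(lo)] <= step * 1.001
        assert tf.freqs[np.argmax(hi)] / oracle[1] <= step * 1.001
        assert oracle[1] / tf.freqs[np.argmax(hi)] <= step * 1.001

    def test_zero_input_zero_power(self):
        tf = hc.morlet_tfr(make_epochs(np.zeros((1, 2, 500))), WSPEC)
        np.testing.assert_allclose(tf.power, 0.0, atol=1e-20)

    def test_log_spacing_constant_ratio(self):
        ratios = WSPEC.frequencies()[1:] / WSPEC.frequencies()[:-1]
        np.testing.assert_allclose(ratios, 2 ** (1 / 12), rtol=1e-12)

    def test_f_max_at_nyquist_rejected(self):
        spec = hc.WaveletSpec(f_min=3.0, f_max=200.0)
        with pytest.raises(hc.ValidationError, match="Nyquist"):
            hc.morlet_tfr(make_epochs(np.zeros((1, 1, 100)), rate=250.0), spec)

    def test_matches_pywavelets_cmor_oracle(self):
        # independent route: pywt's complex Morlet cmor2.0-C with
        # C = ω0/2π is the same mother wavelet; power time courses at
        # matched frequencies must correlate almost perfectly
        import pywt

        rng = np.random.default_rng(5)
        rate = 250.0
        x = rng.standard_normal(int(4 * rate))
        spec = hc.WaveletSpec(f_min=4.0, f_max=40.0, voices_per_octave=8)
        tf = hc.morlet_tfr(make_epochs(x[None, None, :], rate), spec)

        C = spec.omega0 / (2 * np.pi)
        wav = pywt.ContinuousWavelet(f"cmor2.0-{C:.10f}")
        scales = pywt.frequency2scale(wav, tf.freqs / rate)
        coef, _ = pywt.cwt(x, scales, wav, sampling_period=1 / rate,
                           method="fft")
        oracle_power = np.abs(coef) ** 2
        # the two routes pad differently, so exclude a generous
        # 4-envelope-sd margin at each edge before comparing
        n_t = tf.times.size
        for fi in range(0, tf.freqs.size, 4):
            a = spec.omega0 / (2 * np.pi * tf.freqs[fi])
            m = int(np.ceil(4 * a * rate))
            core = slice(m, n_t - m)
            r = np.corrcoef(tf.power[0, 0, fi, core],
                            oracle_power[fi, core])[0, 1]
            # pywt samples the mother wavelet and estimates its centre
            # frequency numerically, so equivalence is near- but not
            # bit-exact
            assert r > 0.98


class TestNormalization:
    def _tf(self, data, rate=125.0, conditions=None):
        return hc.morlet_tfr(
            make_epochs(data, rate, conditions, t0=-2.0),
            hc.WaveletSpec(f_min=4.0, f_max=20.0, voices_per_octave=6),
        )

    def test_stationary_process_zero_mean_z(self, rng):
        data = rng.standard_normal((2, 20, 500))
        tfz = hc.prestim_z_normalize(self._tf(data), hc.ParadigmSpec())
        post = (tfz.times > 0) & tfz.valid_mask.all(axis=0)
        assert abs(tfz.power[:, :, :, post].mean()) < 0.2

    def test_z_is_exact_standardization(self, rng):
        # a voxel whose raw power equals μ + 2σ of its stratum maps to 2
        data = rng.standard_normal((1, 10, 500))
        tf = self._tf(data)
        tfz = hc.prestim_z_normalize(tf, hc.ParadigmSpec())
        win = (tf.times >= -1.0) & (tf.times < 0)
        fi, ti = 3, np.flatnonzero(tf.times > 0.5)[0]
        pool = tf.power[0, :, fi][:, win & tf.valid_mask[fi]]
        mu, sd = pool.mean(), pool.std()
        expect = (tf.power[0, 4, fi, ti] - mu) / sd
        assert tfz.power[0, 4, fi, ti] == pytest.approx(expect, rel=1e-9)

    def test_gain_invariance(self, rng):
        # scaling a channel's raw signal leaves its z-map unchanged
        data = rng.standard_normal((1, 8, 500))
        z1 = hc.prestim_z_normalize(self._tf(data), hc.ParadigmSpec())
        z2 = hc.prestim_z_normalize(self._tf(data * 7.3), hc.ParadigmSpec())
        np.testing.assert_allclose(z1.power, z2.power, rtol=1e-9, atol=1e-9)

    def test_condition_specific_equalizes_planted_baseline_offset(self, rng):
        # one condition carries 3× the baseline amplitude: condition-
        # specific normalization equalizes prestim z; whole-recording
        # normalization preserves the offset
        conds = ["sweet_fat"] * 10 + ["taste_neutral"] * 10
        data = rng.standard_normal((1, 20, 500))
        data[:, :10] *= 3.0
        tf = self._tf(data, conditions=conds)
        zc = hc.prestim_z_normalize(tf, hc.ParadigmSpec(), mode="condition_specific")
        zw = hc.prestim_z_normalize(tf, hc.ParadigmSpec(), mode="whole_recording")
        win = (tf.times >= -1.0) & (tf.times < 0) & tf.valid_mask.all(axis=0)
        gap_c = zc.power[0, :10][:, :, win].mean() - zc.power[0, 10:][:, :, win].mean()
        gap_w = zw.power[0, :10][:, :, win].mean() - zw.power[0, 10:][:, :, win].mean()
        assert abs(gap_c) < 0.3
        assert gap_w > 0.5


class TestDifferenceAndTraces:
    def test_identical_conditions_zero_map(self, rng):
        conds = ["sweet_fat", "taste_neutral"] * 5
        data = np.tile(rng.standard_normal((1, 1, 400)), (1, 10, 1))
        tf = hc.morlet_tfr(make_epochs(data, conditions=conds),
                           hc.WaveletSpec(f_min=4, f_max=20, voices_per_octave=6))
        d = hc.condition_difference_map(tf, "sweet_fat", "taste_neutral")
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_swapping_conditions_negates_map(self, small_task_dataset):
        rec, events, truth, para, spec = small_task_dataset
        eps = hc.epoch(rec, events, para).crop(-2, 3)
        tf = hc.prestim_z_normalize(
            hc.morlet_tfr(eps, hc.WaveletSpec(f_min=3, f_max=20,
                                              voices_per_octave=6), decim=4),
            para)
        d1 = hc.condition_difference_map(tf, "sweet_fat", "taste_neutral")
        d2 = hc.condition_difference_map(tf, "taste_neutral", "sweet_fat")
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_planted_effect_appears_in_difference_and_trace(self, small_task_dataset):
        rec, events, truth, para, spec = small_task_dataset
        eps = hc.epoch(rec, events, para).crop(-2, 3)
        tf = hc.prestim_z_normalize(
            hc.morlet_tfr(eps, hc.WaveletSpec(f_min=3, f_max=20,
                                              voices_per_octave=8), decim=2),
            para)
        d = hc.condition_difference_map(tf, "sweet_fat", "taste_neutral")
        mask = hc.planted_tf_mask(tf.freqs, tf.times, spec.band_hz, spec.window_s)
        mask &= tf.valid_mask
        inside = d[:, mask].mean()
        outside_t = (tf.times > 1.8) & tf.valid_mask.all(axis=0)
        outside = d[:, :, outside_t].mean()
        assert inside > 0.8  # planted ≈ 1.5 z
        assert abs(outside) < 0.4

        trace = hc.band_power_trace(tf, band_hz=spec.band_hz)
        rows = tf.trials_of("sweet_fat")
        t_in = (tf.times >= 0) & (tf.times <= 1)
        t_out = (tf.times >= 1.8) & tf.valid_mask.all(axis=0)
        assert trace[:, rows][:, :, t_in].mean() > trace[:, rows][:, :, t_out].mean() + 0.5

    def test_band_outside_axis_rejected(self, rng):
        tf = hc.morlet_tfr(make_epochs(rng.standard_normal((1, 2, 400))),
                           hc.WaveletSpec(f_min=4, f_max=20, voices_per_octave=6))
        with pytest.raises(hc.ValidationError, match="band"):
            hc.band_power_trace(tf, band_hz=(40.0, 50.0))
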