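import numpy as np
import pytest
from scipy.signal.windows import dpss as scipy_dpss

from ebg.preproc import EpochSet
from ebg.timefreq import (
    TimeFrequencyError,
    baseline_db,
    dpss_tapers,
    extract_oers,
    itpc,
    multitaper_tfr,
)

FS = 512.0


def make_epochs(data, tmin=-0.5, names=None, labels=None):
    data = np.asarray(data, dtype=float)
    t = tmin + np.arange(data.shape[-1]) / FS
    names = names or tuple(f"EBG{i + 1}" for i in range(data.shape[1]))
    labels = labels if labels is not None else np.array(
        ["Odor"] * data.shape[0])
    return EpochSet(data, t, FS, names, labels, np.arange(data.shape[0]))


def tone(freq, n=1025, phase=0.0):
    t = -0.5 + np.arange(n) / FS
    return np.cos(2 * np.pi * freq * t + phase)


class TestDpssTapers:
    @pytest.mark.parametrize("n_tapers", [1, 2, 3])
    def test_orthonormal_and_ordered(self, n_tapers):
        tp = dpss_tapers(128, n_tapers)
        assert tp.shape == (n_tapers, 128)
        assert np.allclose(tp @ tp.T, np.eye(n_tapers), atol=1e-10)

    def test_first_taper_concentration_nw2(self):
        _, ratios = scipy_dpss(256, 2.0, 2, return_ratios=True)
        tp = dpss_tapers(256, 2, nw=2.0)
        assert np.allclose(tp, scipy_dpss(256, 2.0, 2), atol=1e-12)
        assert ratios[0] > 0.99

    def test_too_many_tapers_rejected(self):
        with pytest.raises(TimeFrequencyError):
            dpss_tapers(4, 8)


class TestMultitaperTfr:
    def test_single_taper_tone_argmax_exact(self):
        ep = make_epochs(tone(60.0)[None, None, :])
        tfr = multitaper_tfr(ep, fstep=0.5, n_tapers=1)
        prof = np.nanmean(tfr.power[0, 0], axis=1)
        assert abs(tfr.freqs[np.nanargmax(prof)] - 60.0) <= 0.5

    def test_two_taper_tone_power_calibrated_at_matched_bin(self):
        # the default two-taper bank spreads a tone over its +/-25 Hz
        # half-bandwidth at 60 Hz (its response even peaks below the tone
        # frequency); the normalization contract is that the matched bin
        # reads the tone variance A^2/2
        ep = make_epochs(tone(60.0)[None, None, :])
        tfr = multitaper_tfr(ep, fmin=60, fmax=60, fstep=1.0)
        assert np.nanmean(tfr.power[0, 0]) == pytest.approx(0.5, rel=0.05)
        tfr_all = multitaper_tfr(ep, fstep=0.5)
        prof = np.nanmean(tfr_all.power[0, 0], axis=1)
        fmax = tfr_all.freqs[np.nanargmax(prof)]
        assert abs(fmax - 60.0) <= 25.0 * 60 / 60  # within the bank band

    def test_burst_localized_in_time_and_band(self):
        t = -0.5 + np.arange(1025) / FS
        env = np.zeros_like(t)
        m = (t >= 0.100) & (t <= 0.150)
        env[m] = np.hanning(m.sum())
        ep = make_epochs((env * np.cos(2 * np.pi * 60 * t))[None, None, :])
        tfr = multitaper_tfr(ep, fstep=0.5)
        rows = (tfr.freqs >= 55) & (tfr.freqs <= 65)
        prof = np.nanmean(tfr.power[0, 0][rows], axis=0)
        t_peak = tfr.times[np.nanargmax(prof)]
        assert 0.100 <= t_peak <= 0.150

    def test_zero_signal_zero_power(self):
        tfr = multitaper_tfr(make_epochs(np.zeros((1, 1, 1025))))
        assert np.nanmax(tfr.power) == 0.0

    def test_window_longer_than_epoch_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 40)))
        with pytest.raises(TimeFrequencyError):
            multitaper_tfr(ep)

    def test_window_length_follows_three_cycle_rule(self):
        # valid time range at frequency f shrinks by the 3/f window length
        ep = make_epochs(np.ones((1, 1, 1025)))
        tfr = multitaper_tfr(ep, fmin=30, fmax=90, fstep=30.0, decim=1)
        for fi, f in enumerate(tfr.freqs):
            valid = ~np.isnan(tfr.power[0, 0, fi])
            n_dropped = (~valid).sum()
            expected = int(round(3 / f * FS))
            assert abs(n_dropped - (expected - 1)) <= 1

    def test_frequency_domain_equals_direct_convolution(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512)
        f, L = 60.0, int(round(3 / 60 * FS))
        tapers = dpss_tapers(L, 2)
        t_win = (np.arange(L) - (L - 1) / 2) / FS
        carrier = np.exp(2j * np.pi * f * t_win)
        ep = make_epochs(x[None, None, :])
        tfr = multitaper_tfr(ep, fmin=f, fmax=f, fstep=1.0, decim=1,
                             keep_complex=True)
        # direct time-domain correlation oracle, taper-averaged
        direct = np.zeros(512, dtype=complex)
        for k in range(2):
            kern = (tapers[k] * carrier)[::-1].conj()
            direct += np.convolve(x, kern, mode="same")
        direct /= 2
        got = tfr.coefficients[0, 0, 0]
        valid = ~np.isnan(got)
        assert np.max(np.abs(got[valid] - direct[valid])) < 1e-8

    def test_white_noise_power_tracks_variance(self):
        # spectral calibration: corrected by the analytic taper response,
        # the mean band power of unit-variance white noise recovers sigma^2
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((12, 1, 1025)))
        tfr = multitaper_tfr(ep, fstep=2.0)
        ratios = []
        for fi, f in enumerate(tfr.freqs):
            L = max(int(round(3 / f * FS)), 3)
            tp = dpss_tapers(L, 2)
            pred = 2 * 2 / np.sum(tp.sum(axis=1) ** 2)  # E[P] for sigma=1
            ratios.append(np.nanmean(tfr.power[:, :, fi, :]) / pred)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.10)


class TestBaselineDb:
    def test_stationary_noise_time_average_near_zero(self):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng.standard_normal((8, 1, 1025)))
        db = baseline_db(multitaper_tfr(ep, fstep=5.0))
        # the time-mean of dB sits slightly below 0 (Jensen: E[log P] <
        # log E[P]; about -1.2 dB for the two-taper chi-square power
        # distribution) but stays near zero at every frequency
        prof = np.nanmean(db.power, axis=-1)
        assert np.abs(prof).max() < 2.0
        assert prof.max() <= 0.5

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 1, 1025))
        db1 = baseline_db(multitaper_tfr(make_epochs(x), fstep=5.0))
        db10 = baseline_db(multitaper_tfr(make_epochs(10 * x), fstep=5.0))
        assert np.allclose(db1.power, db10.power, atol=1e-9, equal_nan=True)

    def test_burst_conserves_linear_ratio_mean(self):
        t = -0.5 + np.arange(1025) / FS
        env = np.exp(-0.5 * ((t - 0.12) / 0.02) ** 2)
        x = (env * np.cos(2 * np.pi * 60 * t) +
             0.1 * np.random.default_rng(4).standard_normal(1025))
        tfr = multitaper_tfr(make_epochs(x[None, None, :]), fstep=2.0)
        db = baseline_db(tfr)
        ratio = 10 ** (db.power / 10)
        assert np.nanmean(ratio, axis=-1) == pytest.approx(1.0, rel=1e-6)
        row = np.argmin(np.abs(db.freqs - 60))
        assert np.nanmax(db.power[0, 0, row]) > 0

    def test_double_normalization_rejected(self):
        tfr = multitaper_tfr(make_epochs(np.random.default_rng(5)
                                         .standard_normal((1, 1, 1025))),
                             fstep=10.0)
        db = baseline_db(tfr)
        with pytest.raises(TimeFrequencyError):
            baseline_db(db)


class TestExtractOers:
    def test_zero_width_band_rejected(self, default_epochs):
        tfr = baseline_db(multitaper_tfr(default_epochs, fstep=2.0,
                                         picks=["EBG1"]))
        with pytest.raises(TimeFrequencyError):
            extract_oers(tfr, band=(60, 60))

    def test_window_outside_epoch_rejected(self, default_epochs):
        tfr = baseline_db(multitaper_tfr(default_epochs, fstep=2.0,
                                         picks=["EBG1"]))
        with pytest.raises(TimeFrequencyError):
            extract_oers(tfr, window=(2.0, 2.5))

    def test_odor_exceeds_air_at_default_snr(self, default_epochs):
        from ebg.pipeline import subject_oers

        odor, air = subject_oers(default_epochs)
        assert odor.power_db > air.power_db


class TestItpc:
    def test_identical_trials_give_unity(self):
        x = tone(60.0)[None, None, :].repeat(8, axis=0)
        tfr = multitaper_tfr(make_epochs(x), fmin=60, fmax=60, fstep=1,
                             keep_complex=True)
        v = itpc(tfr)
        assert np.nanmin(v) > 0.999

    def test_random_phase_null_scales_with_sqrt_n(self):
        rng = np.random.default_rng(6)
        n = 120
        vals = []
        for rep in range(4):
            x = np.stack([tone(60.0, phase=rng.uniform(0, 2 * np.pi))
                          for _ in range(n)])
            tfr = multitaper_tfr(make_epochs(x[:, None, :]), fmin=60,
                                 fmax=60, fstep=1, keep_complex=True)
            v = itpc(tfr)
            vals.append(np.nanmean(v[0, 0, 200:800]))
        expected = np.sqrt(np.pi / 4) / np.sqrt(n)
        assert np.mean(vals) == pytest.approx(expected, rel=0.6)
        assert np.mean(vals) < 0.25  # far below any phase-locked value

    def test_phase_locked_burst_peaks_near_onset(self, montage64, head_model):
        from ebg.montage import EBG_LABELS
        from ebg.preproc import preprocess
        from ebg.simulate import ScenarioConfig, generate_recording

        cfg = ScenarioConfig(n_trials=20, seed=8, ob_phase_jitter=0.1,
                             noise_scale=6.0)
        rec, _ = generate_recording(cfg, montage64, head_model)
        ep = preprocess(rec, reject=False).select_condition("Odor")
        tfr = multitaper_tfr(ep, fmin=55, fmax=65, fstep=2.5,
                             picks=list(EBG_LABELS), keep_complex=True)
        v = np.nanmean(itpc(tfr), axis=(0, 1))
        t_peak = tfr.times[np.nanargmax(v)]
        assert 0.05 <= t_peak <= 0.20

    def test_fewer_than_two_trials_rejected(self):
        tfr = multitaper_tfr(make_epochs(tone(60)[None, None, :]),
                             fmin=60, fmax=60, fstep=1, keep_complex=True)
        with pytest.raises(TimeFrequencyError):
            itpc(tfr)

    def test_complex_coefficients_required(self):
        tfr = multitaper_tfr(make_epochs(np.zeros((3, 1, 1025))))
        with pytest.raises(TimeFrequencyError):
            itpc(tfr)
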