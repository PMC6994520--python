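import numpy as np
import pandas as pd
import pytest
from scipy.signal import welch

from ebg.montage import EBG_LABELS
from ebg.preproc import (
    EpochSet,
    PreprocError,
    bandpass,
    detect_blink_trials,
    detect_muscle_trials,
    dft_notch,
    epoch,
    interpolate_bad_channels,
    preprocess,
    rereference_mastoids,
)
from ebg.simulate import RawRecording, ScenarioConfig, generate_recording, inject_artifacts


def _toy_raw(n_ch=3, n_samp=6000, fs=512.0, onsets=(1500, 4000)):
    rng = np.random.default_rng(0)
    data = rng.standard_normal((n_ch, n_samp))
    ev = pd.DataFrame({
        "onset_sample": list(onsets),
        "condition": ["Odor", "Air"][: len(onsets)],
        "trial_id": range(len(onsets)),
    })
    return RawRecording(data, fs, tuple(f"C{i}" for i in range(n_ch)), ev)


def _toy_epochs(data, fs=512.0, tmin=-0.5, labels=None, names=None):
    data = np.asarray(data, dtype=float)
    t = tmin + np.arange(data.shape[-1]) / fs
    labels = labels if labels is not None else np.array(
        ["Odor"] * data.shape[0])
    names = names or tuple(f"C{i}" for i in range(data.shape[1]))
    return EpochSet(data, t, fs, names, labels,
                    np.arange(data.shape[0]))


class TestEpoch:
    def test_window_arithmetic(self, default_session):
        _, rec, _ = default_session
        ep = epoch(rec)
        assert ep.data.shape == (40, rec.n_channels, 1025)
        assert ep.times[0] == pytest.approx(-0.5)
        assert ep.times[-1] == pytest.approx(1.5)

    def test_event_near_edge_named_in_error(self):
        raw = _toy_raw(onsets=(10, 4000))
        with pytest.raises(PreprocError, match="trial_id=0"):
            epoch(raw)

    def test_empty_events_warns_and_returns_empty(self):
        raw = _toy_raw(onsets=())
        with pytest.warns(UserWarning, match="empty"):
            ep = epoch(raw)
        assert ep.n_trials == 0


class TestReference:
    def test_rereference_is_idempotent(self, default_epochs):
        once = rereference_mastoids(default_epochs)
        twice = rereference_mastoids(once)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_common_offset_removed(self):
        ep = _toy_epochs(np.full((1, 4, 100), 100.0),
                         names=("A", "B", "M1", "M2"))
        out = rereference_mastoids(ep)
        assert np.allclose(out.data, 0.0)

    def test_generator_output_already_mastoid_referenced(self,
                                                         default_session):
        _, rec, _ = default_session
        ep = epoch(rec)
        out = rereference_mastoids(ep)
        assert np.allclose(out.data, ep.data, atol=1e-9)

    def test_missing_mastoid_label_rejected(self):
        ep = _toy_epochs(np.zeros((1, 2, 10)))
        with pytest.raises(PreprocError):
            rereference_mastoids(ep)


class TestBandpass:
    fs = 512.0

    def _tone(self, freq, seconds=4.0):
        t = np.arange(int(self.fs * seconds)) / self.fs
        return np.sin(2 * np.pi * freq * t)[None, None, :]

    def test_inband_tone_preserved(self):
        out = bandpass(_toy_epochs(self._tone(60.0)))
        x = out.data[0, 0, 500:-500]
        assert np.abs(x).max() == pytest.approx(1.0, rel=0.05)

    def test_drift_attenuated_20db(self):
        out = bandpass(_toy_epochs(self._tone(0.2, seconds=30.0)))
        x = out.data[0, 0]
        n = len(x)
        assert np.sqrt(np.mean(x[n // 4:-n // 4] ** 2)) < 0.1 / np.sqrt(2)

    def test_dc_removed(self):
        out = bandpass(_toy_epochs(np.full((1, 1, 2048), 7.0)))
        assert np.abs(out.data[0, 0, 500:-500]).max() < 0.05

    def test_edge_above_nyquist_rejected(self):
        with pytest.raises(PreprocError):
            bandpass(_toy_epochs(self._tone(10.0)), high=300.0)


class TestDftNotch:
    fs = 512.0

    def test_pure_line_removed_to_machine_precision(self):
        t = np.arange(1024) / self.fs  # exact integer number of 50 Hz cycles
        x = np.sin(2 * np.pi * 50.0 * t + 0.3)[None, None, :]
        out = dft_notch(_toy_epochs(x))
        assert np.sqrt(np.mean(out.data ** 2)) < 1e-8 * np.sqrt(np.mean(x ** 2))

    def test_other_integer_cycle_content_untouched(self):
        t = np.arange(1024) / self.fs
        x = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        out = dft_notch(_toy_epochs(x))
        assert np.max(np.abs(out.data - x)) < 1e-6

    def test_mixture_line_suppressed_neighbor_kept(self):
        t = np.arange(2048) / self.fs
        x = (np.sin(2 * np.pi * 50.0 * t) +
             0.5 * np.sin(2 * np.pi * 60.0 * t))[None, None, :]
        out = dft_notch(_toy_epochs(x))
        f, p_in = welch(x[0, 0], fs=self.fs, nperseg=2048)
        _, p_out = welch(out.data[0, 0], fs=self.fs, nperseg=2048)
        i50 = np.argmin(np.abs(f - 50))
        i60 = np.argmin(np.abs(f - 60))
        assert p_out[i50] < 1e-4 * p_in[i50]          # > 40 dB down
        assert p_out[i60] == pytest.approx(p_in[i60], rel=0.01)

    def test_line_above_nyquist_rejected(self):
        with pytest.raises(PreprocError):
            dft_notch(_toy_epochs(np.zeros((1, 1, 100))), line_freq=400.0)


class TestArtifactDetectors:
    def test_injected_artifacts_are_flagged(self, default_session,
                                            montage64):
        _, rec, _ = default_session
        rec2, art = inject_artifacts(rec, seed=6, n_blinks=5, n_muscle=4,
                                     montage=montage64)
        ep = rereference_mastoids(epoch(rec2))
        blink_mask = detect_blink_trials(ep)
        muscle_mask = detect_muscle_trials(ep)
        blink_trials = set(art[art.kind == "blink"].trial_id)
        muscle_trials = set(art[art.kind == "muscle"].trial_id)
        assert blink_trials <= set(np.nonzero(blink_mask)[0])
        assert muscle_trials <= set(np.nonzero(muscle_mask)[0])
        assert blink_mask.sum() >= 5

    def test_threshold_monotonicity(self, default_session, montage64):
        _, rec, _ = default_session
        rec2, _ = inject_artifacts(rec, seed=7, n_blinks=4, montage=montage64)
        ep = rereference_mastoids(epoch(rec2))
        at4 = set(np.nonzero(detect_blink_trials(ep, z_thresh=4))[0])
        at6 = set(np.nonzero(detect_blink_trials(ep, z_thresh=6))[0])
        assert at6 <= at4

    def test_infinite_threshold_flags_nothing(self, default_epochs):
        assert detect_muscle_trials(default_epochs, z_thresh=np.inf).sum() == 0

    def test_occipital_transient_outside_blink_scope(self, default_session,
                                                     montage64):
        _, rec, _ = default_session
        rec2 = rec.copy()
        oz = montage64.index("Oz")
        onset = int(rec.events.onset_sample.iloc[3])
        dur = int(0.35 * rec.fs)
        tt = np.arange(dur) / rec.fs
        rec2.data[oz, onset:onset + dur] += 400 * np.sin(np.pi * tt / tt[-1]) ** 2
        ep = rereference_mastoids(epoch(rec2))
        assert not detect_blink_trials(ep)[3]

    def test_zero_variance_channel_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 2, 1024))
        data[:, 1, :] = 0.0
        ep = _toy_epochs(data)
        with pytest.warns(UserWarning, match="zero-variance"):
            mask = detect_muscle_trials(ep)
        assert mask.shape == (4,)


class TestBadChannelInterpolation:
    def test_line_contaminated_channel_replaced(self, default_session,
                                                montage64):
        _, rec, _ = default_session
        rec2 = rec.copy()
        bad = montage64.index("Cz")
        t = np.arange(rec.n_samples) / rec.fs
        rec2.data[bad] += 200.0 * np.sin(2 * np.pi * 50.0 * t)
        ep = epoch(rec2)
        out, bad_list = interpolate_bad_channels(ep, montage64)
        assert bad_list == ["Cz"]
        # post-interpolation 50 Hz power comparable to neighbors
        tt = np.arange(ep.data.shape[-1]) / ep.fs
        basis = np.column_stack([np.sin(2 * np.pi * 50 * tt),
                                 np.cos(2 * np.pi * 50 * tt)])
        q, _ = np.linalg.qr(basis)
        power = ((np.einsum("tcs,sk->tck", out.data, q) ** 2)
                 .sum(-1).mean(0))
        med = np.median(power)
        assert power[bad] < 2 * med

    def test_clean_montage_yields_empty_bad_list(self, default_epochs,
                                                 montage64):
        _, bad_list = interpolate_bad_channels(default_epochs, montage64)
        assert bad_list == []

    def test_two_bad_channels_replaced_independently(self, default_session,
                                                     montage64):
        _, rec, _ = default_session
        rec2 = rec.copy()
        t = np.arange(rec.n_samples) / rec.fs
        for name in ("P3", "F4"):
            rec2.data[montage64.index(name)] += 150.0 * np.sin(
                2 * np.pi * 50.0 * t)
        ep = epoch(rec2)
        out, bad_list = interpolate_bad_channels(ep, montage64)
        assert sorted(bad_list) == ["F4", "P3"]

    def test_unusable_montage_aborts(self, montage64):
        # the z criterion flags a minority of channels by construction, so
        # exercise the >25%-bad guard by lowering the threshold
        rng = np.random.default_rng(1)
        n_ch = len(montage64)
        data = rng.standard_normal((2, n_ch, 1024))
        t = np.arange(1024) / 512.0
        gains = rng.uniform(0, 10, n_ch)
        data += (gains[:, None] * np.sin(2 * np.pi * 50 * t))[None, :, :]
        ep = _toy_epochs(data, names=montage64.labels)
        with pytest.raises(PreprocError, match="unusable"):
            interpolate_bad_channels(ep, montage64, z_thresh=0.2)


class TestFullChain:
    def test_rejection_masks_do_not_alter_data(self, default_session,
                                               montage64):
        _, rec, _ = default_session
        rec2, _ = inject_artifacts(rec, seed=8, n_blinks=3, montage=montage64)
        ep = preprocess(rec2, reject=True)
        ep_no = preprocess(rec2, reject=False)
        assert np.array_equal(ep.data, ep_no.data)

    def test_chain_preserves_oers_ground_truth_power(self, montage64,
                                                     head_model):
        # closure: after the full chain (reref, band-pass, notch) the
        # linear OERS-window power of the burst is recovered within 10%
        # of the noise-free ground-truth projection
        from ebg.timefreq import multitaper_tfr

        def window_power(ep):
            tfr = multitaper_tfr(ep, picks=list(EBG_LABELS), fmin=55,
                                 fmax=65, fstep=1.0)
            fm = (tfr.freqs >= 55) & (tfr.freqs <= 65)
            tm = (tfr.times >= 0.100) & (tfr.times <= 0.150)
            odor = tfr.labels == "Odor"
            return np.nanmean(tfr.power[np.ix_(np.nonzero(odor)[0],
                                               range(len(tfr.ch_names)),
                                               np.nonzero(fm)[0],
                                               np.nonzero(tm)[0])])

        base = dict(n_trials=6, seed=12)
        rec, _ = generate_recording(
            ScenarioConfig(**base, line_amplitude=4.0, noise_scale=2.0,
                           sensor_noise=0.2),
            montage64, head_model)
        twin, _ = generate_recording(
            ScenarioConfig(**base, noise_scale=0.0, sensor_noise=0.0,
                           line_amplitude=0.0, sniff_amplitude=0.0),
            montage64, head_model)
        cleaned = preprocess(rec, reject=False)
        truth = rereference_mastoids(epoch(twin))
        assert window_power(cleaned) == pytest.approx(window_power(truth),
                                                      rel=0.10)
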