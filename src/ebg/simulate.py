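"""Synthetic EBG/EEG recordings with known ground truth.

Every downstream stage of the package is exercised on recordings produced
here, emulating a sniff-triggered olfactory paradigm: 512 Hz sampling, 1-s
odor or clean-air presentations, a bilateral olfactory-bulb (OB) gamma burst
(~55-65 Hz, beginning ~100 ms after odor onset) on Odor trials, sniff-locked
~40 Hz activity around stimulus onset in both conditions, spatially
correlated 1/f background from random intracranial dipoles, 50 Hz line
noise, and optional blink/muscle artifacts.  A congenital-anosmia scenario
(no OB) simply forces the OB burst amplitude to zero.

All signal amplitudes are free parameters of the generator (sensor-level
odor-response SNR is not something the method itself prescribes); the
defaults are chosen to give a clearly measurable but noise-limited response
at the EBG electrodes (~2 uV burst peak against ~1 uV gamma-band
background).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .headmodel import (
    DipoleSource,
    ElectrodeMontage,
    ShellHeadModel,
    build_head_model,
    compute_leadfield,
)
from .montage import EBG_LABELS, MASTOID_LABELS, default_ebg_montage

__all__ = [
    "OB_LEFT", "OB_RIGHT",
    "ScenarioConfig", "RawRecording", "GroundTruth",
    "generate_recording", "inject_artifacts",
    "generate_reliability_sessions", "reliability_sds",
    "generate_habituation_session",
]

# Olfactory-bulb seed coordinates (RAS mm).
OB_LEFT = (-6.0, 30.0, -32.0)
OB_RIGHT = (6.0, 30.0, -32.0)
# Midline parietal source for the habituating cortical N1-P2/3 response.
CORTICAL_SOURCE = (0.0, -45.0, 45.0)


@dataclass
class RawRecording:
    """Continuous multichannel recording: channels x samples, microvolts."""

    data: np.ndarray
    fs: float
    ch_names: tuple[str, ...]
    events: pd.DataFrame  # columns: onset_sample, condition, trial_id

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawRecording":
        return RawRecording(self.data.copy(), self.fs, tuple(self.ch_names),
                            self.events.copy())


@dataclass
class GroundTruth:
    """What the generator actually put into a recording."""

    ob_positions: np.ndarray            # (2, 3): left/right OB
    ob_timecourses: np.ndarray          # (n_trials, n_epoch_samples) nA*m
    ob_amplitudes: np.ndarray           # per-trial peak moment, nA*m
    cortical_amplitudes: np.ndarray     # per-trial N1-P2 source scale
    epoch_times: np.ndarray             # s, relative to onset
    labels: np.ndarray                  # condition per trial
    artifacts: pd.DataFrame             # trial_id, kind, onset_sample
    seed: int = 0
    subject_effect: float = 0.0


@dataclass
class ScenarioConfig:
    """Generator parameters; the defaults define the study conditions."""

    n_trials: int = 20                 # per condition
    fs: float = 512.0
    epoch_window: tuple[float, float] = (-0.5, 1.5)
    # OB gamma burst on Odor trials
    ob_center_hz: float = 60.0
    ob_band_hz: tuple[float, float] = (55.0, 65.0)
    ob_onset_s: float = 0.100
    ob_duration_s: float = 0.050
    ob_amplitude: float = 40.0         # nA*m peak moment
    ob_phase_jitter: float = 0.5       # rad, partial phase locking
    ob_lateralization: str = "bilateral"  # "bilateral" | "left" | "right"
    odor_rise_s: float = 0.200         # olfactometer rise time (to 90%)
    # sniff-locked lower-gamma component, both conditions
    sniff_center_hz: float = 40.0
    sniff_window_s: tuple[float, float] = (-0.100, 0.100)
    sniff_amplitude: float = 6.0       # nA*m
    sniff_enabled: bool = True
    # background + nuisance
    noise_exponent: float = 1.0        # 1/f^alpha source spectra
    noise_scale: float = 15.0          # uV RMS per channel (pink, spatial)
    sensor_noise: float = 0.8          # uV RMS white per channel
    line_freq: float = 50.0
    line_amplitude: float = 4.0        # uV
    n_noise_dipoles: int = 24
    # artifacts (probability per trial)
    blink_rate: float = 0.0
    muscle_rate: float = 0.0
    # habituation scenario
    ob_slope: float = 0.0              # OB amplitude factor 1 + slope*trial
    cortical_decay: float = 0.0        # geometric decay per trial
    cortical_amplitude: float = 0.0    # nA*m; 0 disables the ERP source
    # misc
    anosmia: bool = False
    iti_s: float = 0.6                 # gap between consecutive epochs
    onset_jitter_s: float = 0.4        # uniform jitter added to the gap
    seed: int = 0

    def __post_init__(self) -> None:
        fmax = max(self.ob_band_hz[1], self.sniff_center_hz, self.line_freq)
        if self.fs <= 2 * fmax:
            raise ValueError(
                f"sampling rate {self.fs} Hz violates Nyquist for max "
                f"generated frequency {fmax} Hz")
        if not 0.0 <= self.cortical_decay < 1.0:
            raise ValueError("cortical_decay must be in [0, 1)")
        for name in ("blink_rate", "muscle_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("need at least one trial per condition")
        if self.ob_lateralization not in ("bilateral", "left", "right"):
            raise ValueError("ob_lateralization must be bilateral/left/right")


def _pink_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """Unit-RMS noise with power spectrum 1/f^alpha."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


def _hann_window(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Hann envelope supported on [t0, t1], zero elsewhere."""
    w = np.zeros_like(t)
    inside = (t >= t0) & (t <= t1)
    w[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - t0) / (t1 - t0)))
    return w


def _erp_waveform(t: np.ndarray) -> np.ndarray:
    """Unit-scale N1 (negative, ~380 ms) / P2-3 (positive, ~620 ms) shape."""
    n1 = -np.exp(-0.5 * ((t - 0.38) / 0.06) ** 2)
    p2 = 0.9 * np.exp(-0.5 * ((t - 0.62) / 0.10) ** 2)
    return n1 + p2


def generate_recording(
    config: ScenarioConfig,
    montage: ElectrodeMontage | None = None,
    head_model: ShellHeadModel | None = None,
    conditions: tuple[str, ...] = ("Odor", "Air"),
) -> tuple[RawRecording, GroundTruth]:
    """Simulate one continuous Odor/Air session.

    Odor trials carry the OB gamma burst (amplitude ramped by the
    olfactometer rise time); Air trials carry the sniff-locked component
    only; both share identical noise statistics.  Byte-identical output is
    guaranteed for identical config (the seed is part of the config).
    """
    if head_model is None:
        head_model = build_head_model()
    if montage is None:
        montage = default_ebg_montage(64, head_model)
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    tmin, tmax = config.epoch_window
    n_ep = int(round((tmax - tmin) * fs)) + 1
    t_ep = tmin + np.arange(n_ep) / fs

    # trial schedule: interleaved conditions, jittered onsets
    labels = np.array([c for c in conditions for _ in range(config.n_trials)])
    rng.shuffle(labels)
    n_total = len(labels)
    onsets = np.empty(n_total, dtype=int)
    cursor = int(round((-tmin + 0.1) * fs))
    for i in range(n_total):
        cursor += int(round(rng.uniform(0, config.onset_jitter_s) * fs))
        onsets[i] = cursor
        cursor += int(round((tmax - tmin + config.iti_s) * fs))
    n_samples = onsets[-1] + int(round((tmax + 0.2) * fs)) + 1

    n_ch = len(montage)
    data = np.zeros((n_ch, n_samples))

    # --- spatially correlated 1/f background from random brain dipoles ----
    if config.noise_scale > 0:
        limit = 0.9 * head_model.brain_radius
        pos = rng.standard_normal((config.n_noise_dipoles, 3))
        pos *= (limit * rng.uniform(0.2, 1.0, config.n_noise_dipoles) ** (1 / 3)
                / np.linalg.norm(pos, axis=1))[:, None]
        lf_noise = compute_leadfield(head_model, pos, montage, reference="none")
        mix = np.empty((n_ch, config.n_noise_dipoles))
        for i in range(config.n_noise_dipoles):
            ori = rng.standard_normal(3)
            ori /= np.linalg.norm(ori)
            mix[:, i] = lf_noise.for_source(i) @ ori
        src = np.stack([
            _pink_noise(rng, n_samples, fs, config.noise_exponent)
            for _ in range(config.n_noise_dipoles)])
        pink = mix @ src
        pink *= config.noise_scale / pink.std(axis=1).mean()
        data += pink
    if config.sensor_noise > 0:
        data += config.sensor_noise * rng.standard_normal(data.shape)

    # --- 50 Hz line noise, coherent across channels ----------------------
    if config.line_amplitude > 0:
        tt = np.arange(n_samples) / fs
        gains = rng.uniform(0.5, 1.5, n_ch)
        data += config.line_amplitude * gains[:, None] * np.sin(
            2 * np.pi * config.line_freq * tt + rng.uniform(0, 2 * np.pi))[None, :]

    # --- deterministic sources projected through the lead field ----------
    if config.ob_lateralization == "bilateral":
        ob_pos = np.array([OB_LEFT, OB_RIGHT])
    elif config.ob_lateralization == "left":
        ob_pos = np.array([OB_LEFT])
    else:
        ob_pos = np.array([OB_RIGHT])
    lf_ob = compute_leadfield(head_model, ob_pos, montage, reference="none")
    gain_ob = np.zeros(n_ch)
    for i, p in enumerate(ob_pos):
        d = p - np.asarray(head_model.center)
        gain_ob += lf_ob.for_source(i) @ (d / np.linalg.norm(d))  # radial

    rise = 1.0 - 0.1 ** (np.clip(t_ep, 0, None) / config.odor_rise_s)
    burst_env = _hann_window(t_ep, config.ob_onset_s,
                             config.ob_onset_s + config.ob_duration_s) * rise
    sniff_env = _hann_window(t_ep, *config.sniff_window_s)

    base_amp = 0.0 if config.anosmia else config.ob_amplitude
    ob_tc = np.zeros((n_total, n_ep))
    ob_amps = np.zeros(n_total)
    cort_amps = np.zeros(n_total)
    odor_counter = 0
    for i, (onset, lab) in enumerate(zip(onsets, labels)):
        sl = slice(onset + int(round(tmin * fs)),
                   onset + int(round(tmin * fs)) + n_ep)
        if lab == "Odor":
            amp = base_amp * max(0.0, 1 + config.ob_slope * odor_counter)
            phase = rng.uniform(-config.ob_phase_jitter, config.ob_phase_jitter)
            ob_tc[i] = amp * burst_env * np.cos(
                2 * np.pi * config.ob_center_hz * (t_ep - config.ob_onset_s) + phase)
            ob_amps[i] = amp
            odor_counter += 1
        if config.sniff_enabled:
            sniff = config.sniff_amplitude * sniff_env * np.cos(
                2 * np.pi * config.sniff_center_hz * t_ep + rng.uniform(0, 2 * np.pi))
            data[:, sl] += gain_ob[:, None] * sniff[None, :]
        data[:, sl] += gain_ob[:, None] * ob_tc[i][None, :]

    # --- habituating cortical ERP source ---------------------------------
    if config.cortical_amplitude > 0:
        lf_c = compute_leadfield(head_model, np.array([CORTICAL_SOURCE]),
                                 montage, reference="none")
        d = np.asarray(CORTICAL_SOURCE) - np.asarray(head_model.center)
        gain_c = lf_c.for_source(0) @ (d / np.linalg.norm(d))
        erp = _erp_waveform(t_ep)
        odor_counter = 0
        for i, (onset, lab) in enumerate(zip(onsets, labels)):
            if lab != "Odor":
                continue
            amp = config.cortical_amplitude * (1 - config.cortical_decay) ** odor_counter
            cort_amps[i] = amp
            sl = slice(onset + int(round(tmin * fs)),
                       onset + int(round(tmin * fs)) + n_ep)
            data[:, sl] += gain_c[:, None] * (amp * erp)[None, :]
            odor_counter += 1

    # reference the recording to the mastoid average, as acquired
    m_idx = [montage.index(l) for l in MASTOID_LABELS if l in montage.labels]
    if m_idx:
        data -= data[m_idx].mean(axis=0, keepdims=True)

    events = pd.DataFrame({
        "onset_sample": onsets,
        "condition": labels,
        "trial_id": np.arange(n_total),
    })
    rec = RawRecording(data, fs, montage.labels, events)
    gt = GroundTruth(
        ob_positions=ob_pos, ob_timecourses=ob_tc, ob_amplitudes=ob_amps,
        cortical_amplitudes=cort_amps, epoch_times=t_ep, labels=labels,
        artifacts=pd.DataFrame(columns=["trial_id", "kind", "onset_sample"]),
        seed=config.seed)

    if config.blink_rate > 0 or config.muscle_rate > 0:
        rec, art = inject_artifacts(
            rec, blink_rate=config.blink_rate, muscle_rate=config.muscle_rate,
            seed=int(rng.integers(2 ** 31)), montage=montage)
        gt.artifacts = art
    return rec, gt


def inject_artifacts(
    recording: RawRecording,
    blink_rate: float = 0.0,
    muscle_rate: float = 0.0,
    seed: int = 0,
    montage: ElectrodeMontage | None = None,
    blink_amplitude: float = 350.0,
    muscle_amplitude: float = 40.0,
    n_blinks: int | None = None,
    n_muscle: int | None = None,
) -> tuple[RawRecording, pd.DataFrame]:
    """Add blink and muscle artifacts at trial times.

    Blinks are slow (<= ~8 Hz content) high-amplitude transients with a
    frontal spatial profile strongest at the EBG electrodes; muscle events
    are 0.4-s high-frequency (55-100 Hz) noise bursts with a lateralized
    profile.  Amplitude defaults exceed the detection thresholds of the
    preprocessing stage by construction.  ``n_blinks``/``n_muscle`` place an
    exact number of artifacts on randomly chosen distinct trials instead of
    the per-trial rates.
    """
    rec = recording.copy()
    rng = np.random.default_rng(seed)
    fs = rec.fs
    if montage is None:
        montage = default_ebg_montage(64)

    # spatial profiles
    nas = montage.fiducials.get("Nasion")
    if nas is None:
        nas = np.array([0.0, 92.0, -10.0])
    dist_nas = np.linalg.norm(montage.positions - nas, axis=1)
    blink_profile = np.exp(-dist_nas / 40.0)

    rows = []
    trials = rec.events["trial_id"].to_numpy()
    onsets = rec.events["onset_sample"].to_numpy()

    def pick_trials(rate, count):
        if count is not None:
            count = min(count, len(trials))
            return rng.choice(len(trials), size=count, replace=False)
        return np.nonzero(rng.uniform(size=len(trials)) < rate)[0]

    # blinks
    dur = int(0.35 * fs)
    tt = np.arange(dur) / fs
    blink_shape = np.sin(np.pi * tt / tt[-1]) ** 2
    for i in pick_trials(blink_rate, n_blinks):
        start = onsets[i] + int(rng.uniform(-0.3, 0.8) * fs)
        start = int(np.clip(start, 0, rec.n_samples - dur))
        rec.data[:, start:start + dur] += (
            blink_amplitude * blink_profile[:, None] * blink_shape[None, :])
        rows.append((trials[i], "blink", start))

    # muscle bursts
    dur_m = int(0.4 * fs)
    from scipy.signal import butter, sosfiltfilt
    sos = butter(4, [55.0, min(100.0, 0.45 * fs)], "bandpass", fs=fs, output="sos")
    for i in pick_trials(muscle_rate, n_muscle):
        start = onsets[i] + int(rng.uniform(-0.3, 0.8) * fs)
        start = int(np.clip(start, 0, rec.n_samples - dur_m))
        center = montage.positions[rng.integers(len(montage))]
        dist = np.linalg.norm(montage.positions - center, axis=1)
        profile = np.exp(-dist / 50.0)
        burst = sosfiltfilt(sos, rng.standard_normal(dur_m))
        burst *= np.sin(np.pi * np.arange(dur_m) / dur_m) / burst.std()
        rec.data[:, start:start + dur_m] += (
            muscle_amplitude * profile[:, None] * burst[None, :])
        rows.append((trials[i], "muscle", start))

    art = pd.DataFrame(rows, columns=["trial_id", "kind", "onset_sample"])
    return rec, art


def reliability_sds(icc2k: float, k: int = 3, between_sd: float = 0.25) -> tuple[float, float]:
    """Between/within SDs realizing a target average-measures ICC(2,k).

    With no session effects, ICC(2,k) = sb^2 / (sb^2 + se^2 / k).
    """
    if not 0 < icc2k < 1:
        raise ValueError("target ICC must be in (0, 1)")
    se = between_sd * np.sqrt(k * (1 - icc2k) / icc2k)
    return between_sd, float(se)


def generate_reliability_sessions(
    n_subjects: int,
    n_sessions: int = 3,
    between_subject_sd: float = 0.25,
    within_subject_sd: float = 0.433,
    seed: int = 0,
    mean_power: float = 0.75,
    config: ScenarioConfig | None = None,
    return_recordings: bool = False,
):
    """Per-session OERS-power tables for a multi-day retest experiment.

    Subject-level true effects are drawn once and shared across sessions;
    session noise is independent.  The defaults give an average-measures
    ICC(2,3) of 0.5 around a mean power of 0.75 dB.  Returns a subjects x
    sessions DataFrame; with ``return_recordings=True`` also a list of
    (subject, session) recordings whose OB amplitude is scaled by the
    subject effect, for end-to-end runs.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    subj = between_subject_sd * rng.standard_normal(n_subjects)
    noise = within_subject_sd * rng.standard_normal((n_subjects, n_sessions))
    table = pd.DataFrame(
        mean_power + subj[:, None] + noise,
        index=[f"sub-{i + 1:02d}" for i in range(n_subjects)],
        columns=[f"ses-{j + 1}" for j in range(n_sessions)])
    if not return_recordings:
        return table, None
    base = config if config is not None else ScenarioConfig(n_trials=10)
    recordings = []
    for i in range(n_subjects):
        for j in range(n_sessions):
            amp = base.ob_amplitude * 10 ** (float(table.iloc[i, j] - mean_power) / 20)
            cfg = replace(base, ob_amplitude=max(amp, 0.0),
                          seed=int(rng.integers(2 ** 31)))
            rec, gt = generate_recording(cfg)
            gt.subject_effect = float(subj[i])
            recordings.append(((table.index[i], table.columns[j]), rec, gt))
    return table, recordings


def generate_habituation_session(
    n_trials: int = 32,
    ob_slope: float = 0.0,
    cortical_decay: float = 0.05,
    seed: int = 0,
    config: ScenarioConfig | None = None,
    rating_noise: float = 0.8,
    montage: ElectrodeMontage | None = None,
    head_model: ShellHeadModel | None = None,
) -> tuple[RawRecording, GroundTruth, pd.DataFrame]:
    """Odor-only session with rapid repetition and perceptual habituation.

    The OB burst amplitude follows ``1 + ob_slope * trial`` while the
    cortical N1-P2/3 source decays geometrically by ``cortical_decay`` per
    trial.  Breathing is through the mouth (no sniff-locked component).
    Perceived-intensity ratings (0-10) track the cortical source amplitude
    plus noise.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    base = config if config is not None else ScenarioConfig()
    cfg = replace(
        base, n_trials=n_trials, ob_slope=ob_slope,
        cortical_decay=cortical_decay, sniff_enabled=False,
        cortical_amplitude=(base.cortical_amplitude or 60.0), seed=seed)
    rec, gt = generate_recording(cfg, montage=montage, head_model=head_model,
                                 conditions=("Odor",))
    rng = np.random.default_rng(seed + 1)
    rel = gt.cortical_amplitudes / max(gt.cortical_amplitudes.max(), 1e-12)
    ratings = np.clip(8.0 * rel + rating_noise * rng.standard_normal(n_trials), 0, 10)
    ratings_df = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "intensity_rating": ratings,
    })
    return rec, gt, ratings_df
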