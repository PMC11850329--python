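"""Synthetic EEG/EOG/motion recordings with known ground truth.

Every stage of the offline pipeline (artifact removal, feature
extraction, onset detection, decoding, waveform and time-frequency
analysis) is exercised on recordings produced here.  A simulated run
emulates the statistical structure the analyses assume:

* movement-related cortical potentials (MRCPs) time-locked to each
  movement onset — a slow negativity building from about 2 s before the
  onset, peaking at the onset, followed by a positive rebound — with a
  contralateral central scalp distribution;
* alpha/beta oscillations showing event-related desynchronization (ERD)
  around each movement and a beta rebound after the movement ends;
* 1/f background noise;
* EOG activity (blinks, saccades) linearly coupled into the EEG;
* a 2-D finger-position trace whose speed profile has two peaks per
  movement (flexion and return, separated by a hold);
* cue-to-onset jitter: movements follow the cue by a Gaussian delay
  (mean 95 ms, SD 151 ms by default, truncated at three SDs).

EEG/EOG are sampled at 500 Hz, the motion trace at 30 Hz.  All
randomness flows from an explicit integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

from .channels import EEG_CHANNELS, EOG_CHANNELS
from .paradigm import CueSchedule

EEG_RATE = 500.0
MOTION_RATE = 30.0

__all__ = [
    "SubjectModel",
    "SyntheticRecording",
    "default_mrcp_waveform",
    "default_spatial_weights",
    "default_eog_coupling",
    "simulate_cued_run",
    "simulate_self_paced_timeline",
    "simulate_self_paced_run",
    "simulate_eye_calibration",
]


# ---------------------------------------------------------------------------
# templates and subject model
# ---------------------------------------------------------------------------

def default_mrcp_waveform(
    times: np.ndarray,
    peak_negativity: float = -5.0,
    rebound_amplitude: float = 3.0,
    rebound_peak_time: float = 0.6,
    lag: float = 0.0,
) -> np.ndarray:
    """MRCP template (microvolts) evaluated at ``times`` (s, 0 = onset).

    Monotone-cubic interpolation through the canonical landmarks: zero
    at -2 s, peak negativity at the onset, positive rebound peaking at
    ``rebound_peak_time``, back to zero by +2 s.  ``lag`` shifts the
    whole waveform later in time (used to emulate subjects whose
    cortical response lags the kinematic onset).
    """
    knots = np.array([-2.0, -1.6, 0.0, rebound_peak_time, 1.6, 2.0]) + lag
    vals = np.array([0.0, peak_negativity * 0.05, peak_negativity,
                     rebound_amplitude, rebound_amplitude * 0.05, 0.0])
    f = PchipInterpolator(knots, vals, extrapolate=False)
    out = f(np.asarray(times, dtype=float))
    return np.nan_to_num(out, nan=0.0)


_MOTOR_WEIGHTS = {
    "C1": 1.0, "Cz": 0.9, "C3": 0.8, "C2": 0.5, "C4": 0.25, "C5": 0.3,
    "FC1": 0.6, "FCz": 0.55, "FC3": 0.45, "FC2": 0.35, "FC4": 0.2,
    "CP1": 0.6, "CPz": 0.55, "CP3": 0.45, "CP2": 0.35, "CP4": 0.2,
    "F1": 0.15, "Fz": 0.15, "F3": 0.1, "P1": 0.15, "Pz": 0.15, "P3": 0.1,
}


def default_spatial_weights() -> np.ndarray:
    """Per-channel MRCP gains: maximal at C1/Cz/C3 (contralateral to a
    right-hand movement), decaying towards the periphery."""
    return np.array([_MOTOR_WEIGHTS.get(ch, 0.05) for ch in EEG_CHANNELS])


def default_eog_coupling(scale: float = 1.0) -> np.ndarray:
    """Volume-conduction matrix mapping the 4 EOG sources into the 60
    EEG channels: strongest frontally, decaying towards posterior rows."""
    row_gain = {"Fp": 0.35, "AF": 0.25, "F": 0.15, "FT": 0.08, "FC": 0.08,
                "T7": 0.04, "T8": 0.04, "C": 0.04, "TP": 0.03, "CP": 0.03,
                "P": 0.02, "PO": 0.02, "O": 0.02}

    def gain(ch: str) -> float:
        for prefix in ("Fp", "AF", "FT", "FC", "TP", "CP", "PO", "T7", "T8"):
            if ch.startswith(prefix):
                return row_gain[prefix]
        return row_gain.get(ch[0], 0.02)

    g = np.array([gain(ch) for ch in EEG_CHANNELS])
    # source mix: left/right canthi (horizontal), above/below eye (vertical)
    mix = np.array([0.8, -0.8, 1.0, -0.6])
    # mild left/right asymmetry so the matrix is not exactly rank one
    lateral = np.array([1.0 + (0.2 if "1" in ch or "3" in ch or "5" in ch or "7" in ch
                               else -0.2 if "2" in ch or "4" in ch or "6" in ch or "8" in ch
                               else 0.0) for ch in EEG_CHANNELS])
    coupling = np.outer(g, mix)
    coupling[:, 0] *= lateral
    coupling[:, 1] *= 2.0 - lateral
    return scale * coupling


@dataclass(frozen=True)
class SubjectModel:
    """Generative parameters of one simulated participant.

    ``mrcp_cued`` / ``mrcp_selfpaced`` are waveforms (microvolts)
    sampled on ``mrcp_times``; they may differ to emulate subjects whose
    cue-based and self-paced responses diverge.  ``spatial_weights``
    projects the waveform onto the 60 EEG channels.
    """

    mrcp_times: np.ndarray
    mrcp_cued: np.ndarray
    mrcp_selfpaced: np.ndarray
    spatial_weights: np.ndarray
    eog_coupling: np.ndarray
    erd_depth: float = 0.5
    noise_scale: float = 10.0          # 1/f background RMS, uV
    alpha_fraction: float = 0.2        # alpha amplitude relative to noise_scale
    beta_fraction: float = 0.2
    onset_jitter_mean: float = 0.095   # s, cue-to-onset delay
    onset_jitter_sd: float = 0.151
    movement_hold: float = 0.5         # s the flexion is held
    pulse_width: float = 0.25          # s, width of each speed pulse
    peak_speed: float = 1.0            # motion units/s
    motion_noise: float = 3e-4         # position tracking noise, units
    blink_rate: float = 8.0            # spontaneous blinks per minute
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.eog_coupling.shape != (len(EEG_CHANNELS), len(EOG_CHANNELS)):
            raise ValueError("eog_coupling must be 60 x 4")
        if self.mrcp_cued.shape != self.mrcp_times.shape:
            raise ValueError("mrcp_cued must match mrcp_times")
        if self.mrcp_selfpaced.shape != self.mrcp_times.shape:
            raise ValueError("mrcp_selfpaced must match mrcp_times")

    @classmethod
    def default(
        cls,
        seed: int = 0,
        mrcp_gain: float = 1.0,
        response_lag: float = 0.0,
        selfpaced_lag: float = 0.0,
        noise_scale: float = 10.0,
        eog_gain: float = 1.0,
        **overrides,
    ) -> "SubjectModel":
        """Nominal subject: identical cued and self-paced templates,
        default noise and coupling.

        ``response_lag`` delays both templates relative to the kinematic
        onset (a subject whose cortical response trails the movement);
        ``selfpaced_lag`` additionally delays only the self-paced one.
        """
        times = np.arange(-2.0, 2.0 + 1.0 / EEG_RATE, 1.0 / EEG_RATE)
        cued = mrcp_gain * default_mrcp_waveform(times, lag=response_lag)
        selfpaced = mrcp_gain * default_mrcp_waveform(
            times, lag=response_lag + selfpaced_lag)
        return cls(
            mrcp_times=times,
            mrcp_cued=cued,
            mrcp_selfpaced=selfpaced,
            spatial_weights=default_spatial_weights(),
            eog_coupling=default_eog_coupling(eog_gain),
            noise_scale=noise_scale,
            seed=seed,
            **overrides,
        )

    def with_(self, **kwargs) -> "SubjectModel":
        return replace(self, **kwargs)


@dataclass
class SyntheticRecording:
    """One simulated run: EEG/EOG at 500 Hz, finger position at 30 Hz,
    and a ground-truth event table (onset_s, kind)."""

    eeg: np.ndarray                   # (60, n_samples), uV
    eog: np.ndarray                   # (4, n_samples), uV
    motion_xy: np.ndarray             # (2, n_motion), position units
    events: pd.DataFrame              # columns onset_s, kind
    run_kind: str                     # cued | self_paced | eye_calibration
    eeg_rate: float = EEG_RATE
    motion_rate: float = MOTION_RATE
    channel_labels: tuple = field(default_factory=lambda: EEG_CHANNELS)
    eog_labels: tuple = field(default_factory=lambda: EOG_CHANNELS)

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.eeg.shape[0] != len(self.channel_labels):
            raise ValueError("EEG row count must match channel labels")

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate

    def event_times(self, kind: str) -> np.ndarray:
        return self.events.loc[self.events["kind"] == kind, "onset_s"].to_numpy()


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def _pink_noise(rng, n_channels: int, n_samples: int, rate: float,
                rms: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, normalized per channel to ``rms``."""
    if rms == 0.0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    # amplitude ~ f^-0.5 (power ~ 1/f), flattened below 0.1 Hz
    shaping[nonzero] = np.maximum(freqs[nonzero], 0.1) ** -0.5
    shaping[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n=n_samples, axis=1)
    scale = shaped.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return rms * shaped / scale


def _band_oscillation(rng, n_channels: int, n_samples: int, rate: float,
                      band: tuple, amplitude: float) -> np.ndarray:
    """Band-limited Gaussian oscillation with the given RMS amplitude."""
    if amplitude == 0.0 or n_samples < 100:
        return np.zeros((n_channels, n_samples))
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal((n_channels, n_samples)), axis=1)
    scale = x.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return amplitude * x / scale


def _add_gate(env: np.ndarray, rate: float, start: float, stop: float,
              depth: float, ramp: float = 0.3) -> None:
    """Add a smooth gate of the given depth over [start, stop] (s) in place."""
    n = len(env)
    t0 = int(round((start - ramp) * rate))
    t1 = int(round(start * rate))
    t2 = int(round(stop * rate))
    t3 = int(round((stop + ramp) * rate))
    for a, b, rising in ((t0, t1, True), (t2, t3, False)):
        a_c, b_c = max(a, 0), min(b, n)
        if b_c > a_c and b > a:
            x = (np.arange(a_c, b_c) - a) / (b - a)
            shape = 0.5 - 0.5 * np.cos(np.pi * x)
            env[a_c:b_c] += depth * (shape if rising else 1.0 - shape)
    a_c, b_c = max(t1, 0), min(t2, n)
    if b_c > a_c:
        env[a_c:b_c] += depth


def _motion_trace(onsets: np.ndarray, duration: float, subject: SubjectModel,
                  rng) -> np.ndarray:
    """Finger position (2, n) at 30 Hz: two raised-cosine speed pulses
    per movement (flexion and return) separated by the hold period."""
    n = int(round(duration * MOTION_RATE))
    t = np.arange(n) / MOTION_RATE
    w = subject.pulse_width
    speed = np.zeros(n)
    for onset in onsets:
        for start, sign in ((onset, 1.0),
                            (onset + w + subject.movement_hold, -1.0)):
            mask = (t >= start) & (t < start + w)
            phase = (t[mask] - start) / w
            speed[mask] += sign * subject.peak_speed * 0.5 * (1 - np.cos(2 * np.pi * phase))
    direction = np.array([0.6, 0.8])
    velocity = np.outer(direction, speed)
    pos = np.cumsum(velocity, axis=1) / MOTION_RATE
    pos += subject.motion_noise * rng.standard_normal(pos.shape)
    return pos


def _jittered_onsets(cue_times: np.ndarray, subject: SubjectModel,
                     rng) -> np.ndarray:
    """Movement onsets: cue + truncated Gaussian delay, kept ordered."""
    mu, sd = subject.onset_jitter_mean, subject.onset_jitter_sd
    jitter = rng.normal(mu, sd, size=len(cue_times))
    jitter = np.clip(jitter, mu - 3 * sd, mu + 3 * sd)
    onsets = cue_times + jitter
    # enforce ordering with a minimal gap so movements never collide
    min_gap = 2 * subject.pulse_width + subject.movement_hold + 0.2
    for i in range(1, len(onsets)):
        onsets[i] = max(onsets[i], onsets[i - 1] + min_gap)
    return onsets


def _render_run(onsets: np.ndarray, duration: float, subject: SubjectModel,
                waveform: np.ndarray, rng, cues: np.ndarray | None,
                run_kind: str) -> SyntheticRecording:
    n = int(round(duration * EEG_RATE))
    movement_dur = 2 * subject.pulse_width + subject.movement_hold
    offsets = onsets + movement_dur

    eeg = _pink_noise(rng, len(EEG_CHANNELS), n, EEG_RATE, subject.noise_scale)

    # oscillations with ERD around movements and post-movement beta rebound
    alpha_amp = subject.alpha_fraction * subject.noise_scale
    beta_amp = subject.beta_fraction * subject.noise_scale
    if alpha_amp > 0 or beta_amp > 0:
        erd_env = np.zeros(n)
        rebound_env = np.zeros(n)
        for onset, offset in zip(onsets, offsets):
            _add_gate(erd_env, EEG_RATE, onset - 1.0, offset + 0.2, 1.0)
            _add_gate(rebound_env, EEG_RATE, offset + 0.4, offset + 1.4, 1.0)
        alpha_env = 1.0 - subject.erd_depth * np.clip(erd_env, 0, 1)
        beta_env = (1.0 - subject.erd_depth * np.clip(erd_env, 0, 1)
                    + 0.5 * subject.erd_depth * np.clip(rebound_env, 0, 1))
        central = default_spatial_weights() / default_spatial_weights().max()
        alpha = _band_oscillation(rng, len(EEG_CHANNELS), n, EEG_RATE, (8, 12), alpha_amp)
        beta = _band_oscillation(rng, len(EEG_CHANNELS), n, EEG_RATE, (18, 22), beta_amp)
        mod = 0.3 + 0.7 * central   # ERD strongest over motor channels
        eeg += alpha * (1 + mod[:, None] * (alpha_env[None, :] - 1))
        eeg += beta * (1 + mod[:, None] * (beta_env[None, :] - 1))

    # MRCP templates locked to each movement onset
    if np.any(waveform != 0.0):
        rel = np.round(subject.mrcp_times * EEG_RATE).astype(int)
        contribution = np.outer(subject.spatial_weights, waveform)
        for onset in onsets:
            center = int(round(onset * EEG_RATE))
            idx = center + rel
            valid = (idx >= 0) & (idx < n)
            eeg[:, idx[valid]] += contribution[:, valid]

    eog = _spontaneous_eog(rng, n, subject)
    eeg += subject.eog_coupling @ eog

    motion_xy = _motion_trace(onsets, duration, subject, rng)

    rows = []
    if cues is not None:
        rows += [(t, "cue") for t in cues]
    rows += [(t, "movement_onset") for t in onsets]
    rows += [(t, "movement_offset") for t in offsets]
    events = pd.DataFrame(rows, columns=["onset_s", "kind"]).sort_values(
        "onset_s", kind="stable", ignore_index=True)

    return SyntheticRecording(eeg=eeg, eog=eog, motion_xy=motion_xy,
                              events=events, run_kind=run_kind)


def _blink_pulse(rate: float, width: float = 0.25) -> np.ndarray:
    m = int(round(width * rate))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / m))


def _eog_base(rng, n: int) -> np.ndarray:
    """Sensor noise plus independent slow electrode drift per channel.

    The drift decorrelates the four channels (left/right gaze and the
    blink waveforms alone are nearly collinear), which is what makes the
    leakage matrix identifiable by regression."""
    eog = 2.0 * rng.standard_normal((len(EOG_CHANNELS), n))
    if n > 100:
        sos = butter(2, 2.0, btype="lowpass", fs=EEG_RATE, output="sos")
        drift = sosfiltfilt(sos, rng.standard_normal((len(EOG_CHANNELS), n)),
                            axis=1)
        scale = drift.std(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        eog += 10.0 * drift / scale
    return eog


def _spontaneous_eog(rng, n: int, subject: SubjectModel) -> np.ndarray:
    """Resting EOG: occasional blinks, small saccadic steps, sensor noise."""
    eog = _eog_base(rng, n)
    duration_min = n / EEG_RATE / 60.0
    pulse = _blink_pulse(EEG_RATE)
    n_blinks = rng.poisson(subject.blink_rate * duration_min)
    # blink projects mainly onto the vertical pair (above/below eye)
    blink_topo = np.array([30.0, 30.0, 200.0, -80.0])
    for _ in range(n_blinks):
        start = rng.integers(0, max(1, n - len(pulse)))
        eog[:, start:start + len(pulse)] += np.outer(blink_topo, pulse)
    # slow horizontal gaze drifts (piecewise-constant steps, low-passed)
    n_steps = max(2, int(duration_min * 12))
    step_times = np.sort(rng.integers(0, n, size=n_steps))
    gaze = np.zeros(n)
    level = 0.0
    prev = 0
    for st in step_times:
        gaze[prev:st] = level
        level = float(rng.uniform(-40, 40))
        prev = st
    gaze[prev:] = level
    if n > 100:
        sos = butter(2, 5.0, btype="lowpass", fs=EEG_RATE, output="sos")
        gaze = sosfiltfilt(sos, gaze)
    eog[0] += gaze
    eog[1] -= gaze
    return eog


# ---------------------------------------------------------------------------
# public simulators
# ---------------------------------------------------------------------------

def simulate_cued_run(schedule: CueSchedule, subject: SubjectModel,
                      seed: int | None = None) -> SyntheticRecording:
    """Simulate one cue-based run from a cue schedule.

    Movement onsets follow each cue by a truncated Gaussian delay; the
    EEG carries an MRCP per movement (cued template), ERD-modulated
    oscillations, 1/f noise and EOG leakage; the motion trace carries
    the two-pulse speed profile used for onset labeling.
    """
    if schedule.n_trials < 1:
        raise ValueError("schedule must contain at least one cue")
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    onsets = _jittered_onsets(schedule.cue_times, subject, rng)
    duration = max(schedule.run_duration, onsets[-1] + 2.5)
    return _render_run(onsets, duration, subject, subject.mrcp_cued, rng,
                       cues=schedule.cue_times, run_kind="cued")


def simulate_self_paced_timeline(duration: float, subject: SubjectModel,
                                 seed: int | None = None) -> np.ndarray:
    """Movement-onset times for a self-paced run.

    Alternates bursts of consecutive movements (ITI ~ 3.6 s) with
    pauses of about 10 s, giving a long-run mean ITI near 3.9 s with
    SD near 1.4 s.  Onsets are confined to [2, duration - 2] s.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    t_max = duration - 2.0
    if t_max < 2.0:
        warnings.warn("duration too short for any movement; returning empty",
                      stacklevel=2)
        return np.array([])
    onsets = [2.0]
    while True:
        burst_size = 1 + rng.poisson(23)
        for _ in range(burst_size - 1):
            gap = float(np.clip(rng.normal(3.6, 0.65), 2.0, 6.0))
            nxt = onsets[-1] + gap
            if nxt > t_max:
                return np.array(onsets)
            onsets.append(nxt)
        pause = float(np.clip(rng.normal(10.0, 1.5), 7.0, 14.0))
        nxt = onsets[-1] + pause
        if nxt > t_max:
            return np.array(onsets)
        onsets.append(nxt)


def simulate_self_paced_run(onsets: np.ndarray, subject: SubjectModel,
                            seed: int | None = None,
                            duration: float | None = None) -> SyntheticRecording:
    """Simulate a self-paced run around the given onset times.

    Identical signal model to :func:`simulate_cued_run` but uses the
    self-paced MRCP template and emits no cue events.
    """
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) == 0:
        raise ValueError("need at least one onset")
    if duration is None:
        duration = float(onsets[-1] + 4.0)
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    return _render_run(onsets, duration, subject, subject.mrcp_selfpaced, rng,
                       cues=None, run_kind="self_paced")


def simulate_eye_calibration(duration: float = 420.0,
                             subject: SubjectModel | None = None,
                             seed: int | None = None) -> SyntheticRecording:
    """Simulate the eye-movement calibration recording (~7 min).

    The EOG channels carry repeating blocks of horizontal saccades,
    vertical saccades, blinks and rest; the EEG is background noise plus
    the coupled EOG, with no movement-related activity.  Used to fit the
    EOG-removal regression.
    """
    if subject is None:
        subject = SubjectModel.default()
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    n = int(round(duration * EEG_RATE))
    eog = _eog_base(rng, n)

    block_len = 10.0
    kinds = ["saccade_horizontal", "saccade_vertical", "blink", "rest"]
    rows = []
    t = 1.0
    k = 0
    pulse = _blink_pulse(EEG_RATE)
    while t + block_len <= duration - 1.0:
        kind = kinds[k % 4]
        rows.append((t, kind))
        a = int(round(t * EEG_RATE))
        b = int(round((t + block_len) * EEG_RATE))
        if kind == "saccade_horizontal":
            sig = _saccade_train(rng, b - a)
            eog[0, a:b] += sig
            eog[1, a:b] -= sig
        elif kind == "saccade_vertical":
            sig = _saccade_train(rng, b - a)
            eog[2, a:b] += sig
            eog[3, a:b] -= 0.7 * sig
        elif kind == "blink":
            blink_topo = np.array([30.0, 30.0, 200.0, -80.0])
            for start in np.arange(a, b - len(pulse), int(1.2 * EEG_RATE)):
                eog[:, start:start + len(pulse)] += np.outer(blink_topo, pulse)
        t += block_len
        k += 1

    eeg = _pink_noise(rng, len(EEG_CHANNELS), n, EEG_RATE, subject.noise_scale)
    eeg += subject.eog_coupling @ eog
    events = pd.DataFrame(rows, columns=["onset_s", "kind"])
    motion = subject.motion_noise * rng.standard_normal((2, int(round(duration * MOTION_RATE))))
    return SyntheticRecording(eeg=eeg, eog=eog, motion_xy=motion,
                              events=events, run_kind="eye_calibration")


def _saccade_train(rng, n: int) -> np.ndarray:
    """Alternating gaze steps (uV) smoothed to saccade-like transitions."""
    sig = np.zeros(n)
    level = 0.0
    pos = 0
    while pos < n:
        hold = int(rng.uniform(0.6, 1.4) * EEG_RATE)
        sig[pos:pos + hold] = level
        level = 120.0 if level <= 0 else -120.0
        pos += hold
    if n > 100:
        sos = butter(2, 10.0, btype="lowpass", fs=EEG_RATE, output="sos")
        sig = sosfiltfilt(sos, sig)
    return sig
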