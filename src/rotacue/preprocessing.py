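"""Offline signal chain: band-pass, EOG-artifact regression, low-frequency
feature extraction and common-average referencing.

The chain applied before decoding is

    0.5-70 Hz band-pass -> EOG removal -> 3.5 Hz low-pass + 10 Hz
    downsampling -> common average reference (CAR)

All filters are 4th-order Butterworth applied forward-backward
(zero-phase), so time-locked waveforms are not delayed.  The 3.5 Hz
low-pass doubles as the anti-alias filter for the 500 -> 10 Hz
decimation (cut-off below the 5 Hz Nyquist of the target rate).

Eye artifacts are removed with a linear operator learned on a dedicated
eye-movement calibration recording: each EEG channel is regressed on
the four EOG channels by least squares and the fitted leakage is
subtracted.  CAR is applied to the decoding features only; waveform
analyses use unreferenced signals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .synthetic import SyntheticRecording

__all__ = [
    "EOGRemovalModel",
    "FeatureSeries",
    "bandpass",
    "fit_eog_removal",
    "apply_eog_removal",
    "extract_lowfreq_features",
    "common_average",
]


@dataclass(frozen=True)
class EOGRemovalModel:
    """Fixed linear operator removing EOG leakage from EEG.

    ``coupling_estimate`` has shape (n_eeg, n_eog); cleaning computes
    ``EEG - coupling_estimate @ EOG``.
    """

    coupling_estimate: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coupling_estimate)):
            raise ValueError("coupling coefficients must be finite")


@dataclass(frozen=True)
class FeatureSeries:
    """Low-frequency feature channels at 10 Hz.

    Sample ``i`` corresponds to run time ``t0 + i / rate``.
    """

    values: np.ndarray          # (channels, n_feat)
    rate: float = 10.0
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.shape[1]) / self.rate

    def with_values(self, values: np.ndarray) -> "FeatureSeries":
        return replace(self, values=values)


def _filtfilt(data: np.ndarray, sos) -> np.ndarray:
    return sosfiltfilt(sos, data, axis=-1)


def bandpass(recording: SyntheticRecording, low: float = 0.5,
             high: float = 70.0, order: int = 4) -> SyntheticRecording:
    """Zero-phase Butterworth band-pass of EEG and EOG channels."""
    if recording.eeg_rate <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper edge")
    sos = butter(order, (low, high), btype="bandpass", fs=recording.eeg_rate,
                 output="sos")
    return replace(recording, eeg=_filtfilt(recording.eeg, sos),
                   eog=_filtfilt(recording.eog, sos))


def fit_eog_removal(calibration: SyntheticRecording,
                    run_id: str = "eye_calibration") -> EOGRemovalModel:
    """Least-squares regression of each EEG channel on the EOG channels.

    Fit on the eye-movement calibration run, where ocular activity
    dominates, so the regression captures the volume-conduction leakage
    rather than genuine cortical signal.
    """
    eog = calibration.eog
    if eog.shape[0] < 1 or eog.shape[1] <= eog.shape[0]:
        raise ValueError("calibration run too short")
    gram = eog @ eog.T
    if np.linalg.matrix_rank(gram) < eog.shape[0]:
        raise ValueError("EOG channels are rank deficient (constant or "
                         "duplicated channels)")
    coeffs = np.linalg.solve(gram, eog @ calibration.eeg.T).T
    return EOGRemovalModel(coupling_estimate=coeffs, fitted_on=run_id)


def apply_eog_removal(model: EOGRemovalModel,
                      recording: SyntheticRecording) -> SyntheticRecording:
    """Subtract the fitted EOG leakage from the EEG; EOG passes through."""
    n_eeg, n_eog = model.coupling_estimate.shape
    if recording.eeg.shape[0] != n_eeg or recording.eog.shape[0] != n_eog:
        raise ValueError("channel counts do not match the fitted model")
    cleaned = recording.eeg - model.coupling_estimate @ recording.eog
    return replace(recording, eeg=cleaned)


def extract_lowfreq_features(recording: SyntheticRecording,
                             cutoff: float = 3.5, target_rate: float = 10.0,
                             order: int = 4) -> FeatureSeries:
    """3.5 Hz zero-phase low-pass, then decimation to 10 Hz."""
    factor = recording.eeg_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("input rate must be an integer multiple of the "
                         "target rate")
    sos = butter(order, cutoff, btype="lowpass", fs=recording.eeg_rate,
                 output="sos")
    smoothed = _filtfilt(recording.eeg, sos)
    step = int(round(factor))
    return FeatureSeries(values=smoothed[:, ::step], rate=target_rate, t0=0.0)


def common_average(features: FeatureSeries) -> FeatureSeries:
    """Common-average reference: subtract the instantaneous channel mean."""
    if features.values.shape[0] < 2:
        raise ValueError("CAR needs at least two channels")
    return features.with_values(
        features.values - features.values.mean(axis=0, keepdims=True))
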