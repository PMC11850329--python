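"""Neural-correlate analyses: MRCP averaging and comparison, waveform
dissimilarity vs. detection performance, and ERDS time-frequency maps.

MRCPs are compared between cue-based and self-paced movements channel by
channel and sample by sample with Mann-Whitney U tests, Bonferroni
corrected over the full channels x samples grid.  Waveform dissimilarity
between the two conditions is summarized per subject by the normalized
RMSE (normalized by the peak-to-peak range of the self-paced reference),
and related to detection TPR across subjects by Pearson correlation.

ERDS maps follow the classical band-power recipe: band-pass at 36
overlapping 2 Hz-wide center frequencies spanning 5-40 Hz, square,
average over trials, smooth over time, and express power relative to a
pre-movement reference interval as ``100 * (A - R) / R`` (negative =
desynchronization).  Per-pixel significance comes from a percentile
bootstrap over trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "EpochSet",
    "ERDSConfig",
    "ChannelStat",
    "ERDSMap",
    "epoch",
    "compare_conditions",
    "nrmse",
    "correlate_nrmse_tpr",
    "erds_map",
]


@dataclass
class EpochSet:
    """Trials stacked on a shared time axis relative to movement onset."""

    data: np.ndarray          # (trials, channels, time), uV
    times: np.ndarray         # seconds relative to onset
    rate: float
    condition: str = ""

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass(frozen=True)
class ERDSConfig:
    """ERDS map parameters.

    36 center frequencies spanning 5-40 Hz with 2 Hz bandwidth;
    reference interval [-2, -0.5] s before the onset; percentile
    bootstrap over trials for per-pixel significance; boxcar time
    smoothing of the averaged power.
    """

    center_freqs: tuple = tuple(np.linspace(5.0, 40.0, 36))
    bandwidth: float = 2.0
    reference: tuple = (-2.0, -0.5)
    n_boot: int = 1000
    alpha: float = 0.05
    smooth: float = 0.25      # s, boxcar width
    edge_crop: float = 0.5    # s trimmed per side (band-filter transients)

    def __post_init__(self) -> None:
        if min(self.center_freqs) < 5.0 - 1e-9 or max(self.center_freqs) > 40.0 + 1e-9:
            raise ValueError("center frequencies must lie in [5, 40] Hz")
        if not self.reference[0] < self.reference[1] <= 0:
            raise ValueError("reference interval must precede the onset")


@dataclass
class ChannelStat:
    """Per-(channel, time) U statistic, raw p and Bonferroni mask."""

    u: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    n_comparisons: int


@dataclass
class ERDSMap:
    values: np.ndarray        # (freqs, time), percent power change
    significant: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    config: ERDSConfig = field(repr=False)


def epoch(values: np.ndarray, rate: float, onsets, window,
          t0: float = 0.0, condition: str = "") -> EpochSet:
    """Cut (channels, samples) data into onset-locked trials.

    Onsets without full window support are dropped with a warning; an
    empty or degenerate window, or zero usable trials, is an error.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must have positive length")
    values = np.asarray(values)
    n = values.shape[1]
    i_lo = int(round(lo * rate))
    i_hi = int(round(hi * rate))
    rel = np.arange(i_lo, i_hi + 1)
    trials = []
    for onset in np.atleast_1d(np.asarray(onsets, dtype=float)):
        center = int(round((onset - t0) * rate))
        if center + i_lo < 0 or center + i_hi >= n:
            warnings.warn(f"onset at {onset:.2f} s lacks full epoch support; "
                          "dropped", stacklevel=2)
            continue
        trials.append(values[:, center + rel])
    if not trials:
        raise ValueError("no usable trials")
    return EpochSet(data=np.stack(trials), times=rel / rate, rate=rate,
                    condition=condition)


def compare_conditions(a: EpochSet, b: EpochSet,
                       alpha: float = 0.05) -> ChannelStat:
    """Mann-Whitney U per channel and time sample, Bonferroni corrected
    over the full channels x samples family."""
    if a.n_trials < 2 or b.n_trials < 2:
        raise ValueError("need at least two trials per condition")
    if a.data.shape[1:] != b.data.shape[1:]:
        raise ValueError("epoch shapes do not match")
    # exact null distribution for small tie-free samples, midrank-corrected
    # normal approximation otherwise
    res = stats.mannwhitneyu(a.data, b.data, axis=0, alternative="two-sided",
                             method="auto")
    n_comp = int(np.prod(a.data.shape[1:]))
    mask = res.pvalue < alpha / n_comp
    return ChannelStat(u=res.statistic, p=res.pvalue, significant=mask,
                       alpha=alpha, n_comparisons=n_comp)


def nrmse(waveform: np.ndarray, reference: np.ndarray) -> float:
    """RMSE between two waveforms normalized by the reference's
    peak-to-peak range."""
    waveform = np.asarray(waveform, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if waveform.shape != reference.shape:
        raise ValueError("waveforms must have equal length")
    span = np.ptp(reference)
    if span == 0:
        raise ValueError("reference has zero range; NRMSE undefined")
    return float(np.sqrt(np.mean((waveform - reference) ** 2)) / span)


def correlate_nrmse_tpr(nrmse_values, tpr_values):
    """Pearson correlation (r, two-sided p) across subjects."""
    x = np.asarray(nrmse_values, dtype=float)
    y = np.asarray(tpr_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least three paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _trial_band_power(data: np.ndarray, rate: float,
                      cfg: ERDSConfig) -> np.ndarray:
    """(freqs, trials, time) squared band-passed amplitude."""
    half = cfg.bandwidth / 2.0
    out = np.empty((len(cfg.center_freqs),) + data.shape)
    for i, f0 in enumerate(cfg.center_freqs):
        sos = butter(4, (f0 - half, f0 + half), btype="bandpass", fs=rate,
                     output="sos")
        out[i] = sosfiltfilt(sos, data, axis=-1) ** 2
    return out


def _smooth_time(power: np.ndarray, rate: float, width: float) -> np.ndarray:
    m = max(1, int(round(width * rate)))
    if m == 1:
        return power
    kernel = np.ones(m) / m
    pad = np.pad(power, [(0, 0)] * (power.ndim - 1) + [(m // 2, m - 1 - m // 2)],
                 mode="edge")
    return np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="valid"),
                               -1, pad)


def erds_map(epochs: EpochSet, cfg: ERDSConfig | None = None,
             channel: int = 0, rng=None) -> ERDSMap:
    """ERDS map for one channel with bootstrap significance.

    For each center frequency the single-trial squared band amplitude is
    averaged over trials, smoothed in time, and expressed as percent
    change relative to the mean over the reference interval.  ``n_boot``
    trial resamples give a (1 - alpha) percentile interval per pixel;
    pixels whose interval covers zero are masked as non-significant.
    """
    cfg = cfg or ERDSConfig()
    rng = np.random.default_rng(rng)
    data = epochs.data[:, channel, :]                     # (trials, time)
    power = _trial_band_power(data, epochs.rate, cfg)     # (F, trials, T)
    # trim band-filter edge transients before any averaging
    keep = (epochs.times >= epochs.times[0] + cfg.edge_crop) & \
           (epochs.times <= epochs.times[-1] - cfg.edge_crop)
    power = power[:, :, keep]
    times = epochs.times[keep]
    if not (times[0] <= cfg.reference[0] and cfg.reference[1] <= times[-1]):
        raise ValueError("reference interval must lie inside the epoch window "
                         "after edge cropping")
    ref_mask = (times >= cfg.reference[0]) & (times <= cfg.reference[1])

    def to_map(trial_power: np.ndarray) -> np.ndarray:
        avg = _smooth_time(trial_power.mean(axis=1), epochs.rate, cfg.smooth)
        ref = avg[:, ref_mask].mean(axis=1, keepdims=True)
        if np.any(ref <= 0):
            raise ValueError("reference power is zero")
        return 100.0 * (avg - ref) / ref

    values = to_map(power)

    n_trials = power.shape[1]
    f, t = values.shape
    flat = power.transpose(1, 0, 2).reshape(n_trials, f * t)
    boot = np.empty((cfg.n_boot, f, t))
    for b in range(cfg.n_boot):
        idx = rng.integers(0, n_trials, n_trials)
        counts = np.bincount(idx, minlength=n_trials) / n_trials
        avg = (counts @ flat).reshape(f, t)
        avg = _smooth_time(avg, epochs.rate, cfg.smooth)
        ref = avg[:, ref_mask].mean(axis=1, keepdims=True)
        boot[b] = 100.0 * (avg - ref) / ref
    lo = np.quantile(boot, cfg.alpha / 2, axis=0)
    hi = np.quantile(boot, 1 - cfg.alpha / 2, axis=0)
    significant = (lo > 0) | (hi < 0)
    return ERDSMap(values=values, significant=significant,
                   freqs=np.asarray(cfg.center_freqs), times=times,
                   config=cfg)
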