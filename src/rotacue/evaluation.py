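"""Detector evaluation: sample-wise MCC and event-wise TPR / FP-per-minute.

Training-time model selection scores predictions sample-by-sample with
the Matthews correlation coefficient, which stays informative under the
extreme class imbalance of single-sample movement labels.  Final
evaluation is event-by-event: a detection counts as a hit if it is the
first detection inside the asymmetric window [-0.5, +1.0] s around a
true onset; further detections inside an already-hit window are ignored
(neither hit nor false positive); detections outside every window are
false positives, normalized to FP per minute of run time.  A refractory
period (1 s) suppresses bursts of detections, and the probability
threshold is calibrated per subject to maximize TPR subject to a bound
on FP/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["EvalConfig", "EventMetrics", "mcc", "detect_events",
           "event_metrics", "calibrate_threshold"]


@dataclass(frozen=True)
class EvalConfig:
    """Event-evaluation parameters.

    ``hit_window`` is (lower, upper) in seconds around the true onset
    (lower negative); ``refractory`` suppresses detections after a
    detection; ``max_fppm`` is the calibration bound on FP/min.
    """

    hit_window: tuple = (-0.5, 1.0)
    refractory: float = 1.0
    max_fppm: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.hit_window
        if not (lo < 0 < hi):
            raise ValueError("hit_window must straddle the onset")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")
        if not self.max_fppm > 0:
            raise ValueError("max_fppm must be positive")


@dataclass(frozen=True)
class EventMetrics:
    n_true: int
    n_hit: int
    n_fp: int
    duration_min: float

    @property
    def tpr(self) -> float:
        """Percent of true onsets hit."""
        return 100.0 * self.n_hit / self.n_true if self.n_true else float("nan")

    @property
    def fppm(self) -> float:
        return self.n_fp / self.duration_min

    def as_dict(self) -> dict:
        return {"n_true": self.n_true, "n_hit": self.n_hit, "n_fp": self.n_fp,
                "tpr": self.tpr, "fppm": self.fppm,
                "duration_min": self.duration_min}


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient of a 2x2 confusion matrix.

    Returns 0 when any marginal is empty (the conventional limit), and
    NaN for the all-zero matrix.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + tn + fn == 0:
        return float("nan")
    product = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if product == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(product)


def detect_events(scores, threshold: float, refractory: float = 1.0):
    """Detection times from a score trace with a refractory period.

    ``scores`` is a :class:`~rotacue.decoder.ScoreTrace` or a
    ``(values, times)`` pair.  A detection fires at every time where the
    score reaches the threshold and no detection occurred within the
    preceding refractory interval.
    """
    values, times = _as_trace(scores)
    detections: list[float] = []
    last = -np.inf
    for v, t in zip(values, times):
        if v >= threshold and t - last > refractory:
            detections.append(t)
            last = t
    return np.asarray(detections)


def _as_trace(scores):
    if hasattr(scores, "values") and hasattr(scores, "times"):
        return np.asarray(scores.values), np.asarray(scores.times)
    values, times = scores
    return np.asarray(values), np.asarray(times)


def event_metrics(detections, true_onsets, cfg: EvalConfig,
                  duration: float) -> EventMetrics:
    """Score detections against true onsets event-by-event.

    The first detection inside an onset's hit window claims that onset
    (a hit); later detections in the same window are ignored; detections
    inside no window are false positives.  When hit windows overlap, a
    detection claims the nearest still-unclaimed eligible onset.
    """
    detections = np.sort(np.asarray(detections, dtype=float))
    true_onsets = np.sort(np.asarray(true_onsets, dtype=float))
    lo, hi = cfg.hit_window
    claimed = np.zeros(len(true_onsets), dtype=bool)
    n_fp = 0
    for det in detections:
        eligible = np.nonzero((det >= true_onsets + lo) &
                              (det <= true_onsets + hi))[0]
        if len(eligible) == 0:
            n_fp += 1
            continue
        open_ = eligible[~claimed[eligible]]
        if len(open_):
            nearest = open_[np.argmin(np.abs(det - true_onsets[open_]))]
            claimed[nearest] = True
        # else: extra detection inside an already-hit window -> ignored
    return EventMetrics(n_true=len(true_onsets), n_hit=int(claimed.sum()),
                        n_fp=n_fp, duration_min=duration / 60.0)


def calibrate_threshold(scores, true_onsets, cfg: EvalConfig,
                        duration: float):
    """Choose the probability threshold maximizing TPR under the FP/min
    bound.

    Sweeps every distinct score value in descending order; among
    thresholds whose FP/min stays within ``cfg.max_fppm`` the one with
    maximal TPR is returned (the highest such threshold on ties).  If no
    threshold satisfies the bound, a threshold above the maximal score
    is returned (no detections).
    """
    true_onsets = np.asarray(true_onsets, dtype=float)
    if len(true_onsets) == 0:
        raise ValueError("need at least one true onset")
    values, _ = _as_trace(scores)
    best = None
    for threshold in np.unique(values)[::-1]:
        detections = detect_events(scores, threshold, cfg.refractory)
        metrics = event_metrics(detections, true_onsets, cfg, duration)
        if metrics.fppm <= cfg.max_fppm:
            if best is None or metrics.tpr > best[1].tpr:
                best = (float(threshold), metrics)
    if best is None:
        threshold = float(np.nextafter(values.max(), np.inf))
        return threshold, event_metrics([], true_onsets, cfg, duration)
    return best
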