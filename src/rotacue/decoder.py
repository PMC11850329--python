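"""Shrinkage-LDA movement detector on sliding low-frequency windows.

Each decoding window stacks the last ``n_window`` feature samples
(10 Hz, all channels) preceding a time point ``t``; windows advance
with a stride of one sample.  A window is labeled *movement* only if
``t`` is the feature sample nearest ``t_onset + d``, where ``d`` is a
detection delay that lets the window cover the informative pre-onset
negativity; every other window is *no movement*.

A binary LDA with a shrunk pooled covariance scores each window with
the posterior probability of movement.  Covariance shrinkage is closed
form — either linear Ledoit-Wolf shrinkage towards a scaled identity
(default) or the quadratic-inverse shrinkage (QIS) nonlinear estimator
— so no inner cross-validation is needed for regularization.

``n_window`` and ``d`` are chosen by 3-fold run-wise cross-validation:
train on one cue-based run, test on the other two, score sample-by-
sample with the Matthews correlation coefficient (MCC), and pick the
grid point with the best mean test MCC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit
from sklearn.covariance import ledoit_wolf

from .evaluation import mcc
from .preprocessing import FeatureSeries

__all__ = [
    "DecoderConfig",
    "WindowedDataset",
    "SLDAModel",
    "ScoreTrace",
    "HyperparamResult",
    "extract_labeled_windows",
    "fit_slda",
    "score_run",
    "select_hyperparameters",
    "qis_covariance",
]


@dataclass(frozen=True)
class DecoderConfig:
    """Decoder hyperparameters and their cross-validation grids.

    ``n_window`` counts 10 Hz feature samples (3..20 spans 0.3-2.0 s,
    the MRCP timescale); ``d`` is the detection delay in seconds.
    """

    n_window: int = 10
    d: float = 0.2
    n_window_grid: tuple = tuple(range(3, 21))
    d_grid: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    shrinkage_method: str = "lw_linear"

    def __post_init__(self) -> None:
        if self.n_window < 1:
            raise ValueError("n_window must be >= 1")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if not self.n_window_grid or not self.d_grid:
            raise ValueError("grids must be non-empty")
        if self.shrinkage_method not in ("lw_linear", "qis"):
            raise ValueError("unknown shrinkage method")


@dataclass
class WindowedDataset:
    """Sliding windows with single-sample movement labels."""

    windows: np.ndarray           # (n, n_window * channels)
    labels: np.ndarray            # binary, one positive per usable onset
    window_end_times: np.ndarray  # seconds, run clock
    n_window: int
    d: float


@dataclass
class SLDAModel:
    """Binary LDA with shrunk shared covariance.

    ``weights``/``bias`` give the movement log-odds; scores are
    posterior probabilities under the shared-covariance Gaussian model.
    """

    class_means: np.ndarray       # (2, p): [no-movement, movement]
    shrunk_cov: np.ndarray
    weights: np.ndarray
    bias: float
    priors: np.ndarray
    shrinkage_method: str
    shrinkage_intensity: float | None
    n_window: int
    d: float


@dataclass
class ScoreTrace:
    """Movement posterior per feature sample (window end times)."""

    values: np.ndarray
    times: np.ndarray


@dataclass
class HyperparamResult:
    n_window: int
    d: float
    model: SLDAModel
    cv_mcc: dict = field(repr=False)


def extract_labeled_windows(features: FeatureSeries, onsets,
                            n_window: int, d: float) -> WindowedDataset:
    """Window the feature series and attach single-sample labels.

    One window per feature sample with a full ``n_window`` history; the
    window whose end time is nearest ``onset + d`` is positive.  Onsets
    whose target sample lacks full history (too close to the run start
    or end) are skipped with a warning.
    """
    values = features.values
    n = values.shape[1]
    if n < n_window:
        raise ValueError("feature series shorter than one window")
    sw = sliding_window_view(values, n_window, axis=1)   # (ch, n_w, n_window)
    windows = sw.transpose(1, 0, 2).reshape(n - n_window + 1, -1)
    end_times = features.times[n_window - 1:]
    labels = np.zeros(len(windows), dtype=int)
    for onset in np.atleast_1d(np.asarray(onsets, dtype=float)):
        j = int(round((onset + d - features.t0) * features.rate))
        i = j - (n_window - 1)
        if i < 0 or i >= len(windows):
            warnings.warn(
                f"onset at {onset:.2f} s lacks full window support; trial "
                "skipped", stacklevel=2)
            continue
        labels[i] = 1
    return WindowedDataset(windows=windows, labels=labels,
                           window_end_times=end_times,
                           n_window=n_window, d=d)


def qis_covariance(x_centered: np.ndarray, n_eff: int | None = None) -> np.ndarray:
    """Quadratic-inverse shrinkage (QIS) covariance estimate.

    Closed-form nonlinear shrinkage: the sample eigenvalues are replaced
    by an asymptotically optimal transform built from a kernel estimate
    of the eigenvalue distribution's Stieltjes transform, then the trace
    is restored.  ``x_centered`` is (n, p), already demeaned; ``n_eff``
    accounts for degrees of freedom lost to demeaning.
    """
    n_samples, p = x_centered.shape
    n = n_eff if n_eff is not None else n_samples
    sample = x_centered.T @ x_centered / n
    lam, u = np.linalg.eigh(sample)
    lam = np.maximum(lam, 0.0)
    c = p / n
    h = min(c ** 2, 1.0 / c ** 2) ** 0.35 / p ** 0.35
    nonnull = lam[max(0, p - n):]
    inv = 1.0 / np.maximum(nonnull, 1e-12 * max(lam.max(), 1e-30))
    lj = inv[:, None] * np.ones_like(inv)[None, :]       # rows: 1/lambda_i
    dij = lj - lj.T
    denom = dij ** 2 + h ** 2 * lj ** 2
    theta = np.mean(lj * dij / denom, axis=1)
    h_theta = np.mean(lj * (h * lj) / denom, axis=1)
    a_theta2 = theta ** 2 + h_theta ** 2
    if p <= n:
        delta = 1.0 / ((1 - c) ** 2 * inv + 2 * c * (1 - c) * inv * theta
                       + c ** 2 * inv * a_theta2)
    else:
        delta0 = 1.0 / ((c - 1) * np.mean(inv))
        delta = np.concatenate([np.full(p - n, delta0),
                                1.0 / (inv * a_theta2)])
    delta *= lam.sum() / delta.sum()
    return (u * delta) @ u.T


def fit_slda(ds: WindowedDataset, method: str = "lw_linear") -> SLDAModel:
    """Fit the shrinkage LDA on a labeled window set."""
    y = ds.labels
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    x = ds.windows
    mu0 = x[y == 0].mean(axis=0)
    mu1 = x[y == 1].mean(axis=0)
    centered = x - np.where(y[:, None] == 1, mu1, mu0)
    n_eff = len(y) - 2
    if method == "lw_linear":
        cov, intensity = ledoit_wolf(centered, assume_centered=True)
        cov *= len(y) / n_eff
    elif method == "qis":
        cov = qis_covariance(centered, n_eff)
        intensity = None
    else:
        raise ValueError(f"unknown shrinkage method: {method}")
    dmu = mu1 - mu0
    weights = np.linalg.solve(cov, dmu)
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    bias = float(-weights @ (mu0 + mu1) / 2 + np.log(priors[1] / priors[0]))
    return SLDAModel(class_means=np.stack([mu0, mu1]), shrunk_cov=cov,
                     weights=weights, bias=bias, priors=priors,
                     shrinkage_method=method, shrinkage_intensity=intensity,
                     n_window=ds.n_window, d=ds.d)


def score_run(model: SLDAModel, features: FeatureSeries,
              n_window: int | None = None) -> ScoreTrace:
    """Movement posterior for every feature sample with full history."""
    n_window = model.n_window if n_window is None else n_window
    values = features.values
    n = values.shape[1]
    if n < n_window:
        raise ValueError("feature series shorter than one window")
    sw = sliding_window_view(values, n_window, axis=1)
    windows = sw.transpose(1, 0, 2).reshape(n - n_window + 1, -1)
    if windows.shape[1] != model.weights.shape[0]:
        raise ValueError("feature dimensionality does not match the model")
    scores = expit(windows @ model.weights + model.bias)
    return ScoreTrace(values=scores, times=features.times[n_window - 1:])


def _fold_mcc(model: SLDAModel, test_sets) -> float:
    """Sample-by-sample MCC of thresholded posteriors over pooled test runs."""
    pred, truth = [], []
    for ds in test_sets:
        scores = expit(ds.windows @ model.weights + model.bias)
        pred.append(scores >= 0.5)
        truth.append(ds.labels.astype(bool))
    pred = np.concatenate(pred)
    truth = np.concatenate(truth)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return mcc(tp, fp, tn, fn)


def select_hyperparameters(runs, cfg: DecoderConfig) -> HyperparamResult:
    """Run-wise 3-fold CV over the (n_window, d) grid.

    ``runs`` is a sequence of three (FeatureSeries, onsets) pairs from
    the cue-based runs.  Each fold trains on one run and tests on the
    remaining two; grid points are ranked by mean test MCC, ties broken
    towards smaller ``n_window`` then smaller ``d``.  The returned
    model is refit on all three runs at the winning grid point.
    """
    runs = list(runs)
    if len(runs) != 3:
        raise ValueError("exactly three cue-based runs are required")
    cv_mcc: dict = {}
    best = None
    for n_window in sorted(cfg.n_window_grid):
        for d in sorted(cfg.d_grid):
            datasets = [extract_labeled_windows(f, o, n_window, d)
                        for f, o in runs]
            fold_scores = []
            for k in range(3):
                model = fit_slda(datasets[k], cfg.shrinkage_method)
                test = [datasets[j] for j in range(3) if j != k]
                fold_scores.append(_fold_mcc(model, test))
            mean_mcc = float(np.mean(fold_scores))
            cv_mcc[(n_window, d)] = mean_mcc
            if best is None or mean_mcc > best[0] + 1e-12:
                best = (mean_mcc, n_window, d)
    _, n_window, d = best
    datasets = [extract_labeled_windows(f, o, n_window, d) for f, o in runs]
    merged = WindowedDataset(
        windows=np.concatenate([ds.windows for ds in datasets]),
        labels=np.concatenate([ds.labels for ds in datasets]),
        window_end_times=np.concatenate([ds.window_end_times for ds in datasets]),
        n_window=n_window, d=d)
    final = fit_slda(merged, cfg.shrinkage_method)
    return HyperparamResult(n_window=n_window, d=d, model=final, cv_mcc=cv_mcc)
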