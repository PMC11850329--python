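import numpy as np
import pytest

import rotacue as rc
from rotacue.decoder import (DecoderConfig, WindowedDataset,
                             extract_labeled_windows, fit_slda, qis_covariance,
                             score_run, select_hyperparameters, _fold_mcc)
from rotacue.evaluation import mcc
from rotacue.preprocessing import FeatureSeries


def gaussian_dataset(rng, n_pos=80, n_neg=800, p=12, sep=4.0):
    neg = rng.standard_normal((n_neg, p))
    pos = rng.standard_normal((n_pos, p))
    pos[:, 0] += sep
    x = np.vstack([neg, pos])
    y = np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)])
    return WindowedDataset(windows=x, labels=y,
                           window_end_times=np.arange(len(y)) * 0.1,
                           n_window=1, d=0.0)


class TestWindowing:
    def test_one_positive_per_onset(self, rng):
        feats = FeatureSeries(values=rng.standard_normal((3, 400)))
        onsets = np.arange(2.0, 32.0, 3.0)   # 10 onsets
        ds = extract_labeled_windows(feats, onsets, n_window=5, d=0.2)
        assert ds.labels.sum() == 10

    def test_window_span(self, rng):
        feats = FeatureSeries(values=rng.standard_normal((3, 100)))
        ds = extract_labeled_windows(feats, [5.0], n_window=5, d=0.0)
        assert ds.windows.shape == (96, 15)
        # each window spans 0.5 s of features
        assert ds.window_end_times[0] - 0.4 == pytest.approx(feats.times[0])

    def test_early_onset_skipped_with_warning(self, rng):
        feats = FeatureSeries(values=rng.standard_normal((3, 100)))
        with pytest.warns(UserWarning):
            ds = extract_labeled_windows(feats, [0.1], n_window=10, d=0.0)
        assert ds.labels.sum() == 0

    def test_matches_explicit_loop(self, rng):
        """Vectorized windowing equals a brute-force re-extraction."""
        feats = FeatureSeries(values=rng.standard_normal((4, 300)))
        onsets = [4.0, 11.3, 22.71]
        n_window, d = 7, 0.3
        ds = extract_labeled_windows(feats, onsets, n_window, d)
        v = feats.values
        for i in range(0, len(ds.windows), 17):
            manual = v[:, i:i + n_window].reshape(-1)
            assert np.array_equal(ds.windows[i], manual)
        labels = np.zeros(v.shape[1] - n_window + 1, int)
        for onset in onsets:
            j = int(round((onset + d) * 10.0))
            labels[j - n_window + 1] = 1
        assert np.array_equal(ds.labels, labels)


class TestSLDA:
    def test_separated_gaussians_reach_high_mcc(self, rng):
        ds = gaussian_dataset(rng)
        model = fit_slda(ds)
        pred = (ds.windows @ model.weights + model.bias) > 0
        tp = np.sum(pred & (ds.labels == 1))
        fp = np.sum(pred & (ds.labels == 0))
        tn = np.sum(~pred & (ds.labels == 0))
        fn = np.sum(~pred & (ds.labels == 1))
        assert mcc(tp, fp, tn, fn) > 0.9

    def test_permuted_labels_give_chance_mcc(self, rng):
        ds = gaussian_dataset(rng)
        ds.labels = rng.permutation(ds.labels)
        model = fit_slda(ds)
        assert abs(_fold_mcc(model, [ds])) < 0.25

    def test_single_class_rejected(self, rng):
        ds = gaussian_dataset(rng)
        ds.labels[:] = 0
        with pytest.raises(ValueError):
            fit_slda(ds)

    @pytest.mark.parametrize("method", ["lw_linear", "qis"])
    def test_covariance_symmetric_positive_definite(self, rng, method):
        ds = gaussian_dataset(rng)
        model = fit_slda(ds, method)
        cov = model.shrunk_cov
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert np.linalg.eigvalsh(cov).min() > 0

    @staticmethod
    def anisotropic_dataset(rng, n, p=6, sep=2.0):
        scales = np.linspace(1.0, 3.0, p)
        neg = scales * rng.standard_normal((n, p))
        pos = scales * rng.standard_normal((n // 4, p))
        pos[:, 0] += sep
        x = np.vstack([neg, pos])
        y = np.concatenate([np.zeros(n, int), np.ones(n // 4, int)])
        return WindowedDataset(windows=x, labels=y,
                               window_end_times=np.arange(len(y)) * 0.1,
                               n_window=1, d=0.0), scales

    def test_lw_intensity_vanishes_with_sample_size(self):
        """For a non-spherical population covariance the estimated linear
        shrinkage intensity decays as the sample grows."""
        rng = np.random.default_rng(1)
        intensities = []
        for n in (100, 1000, 10000):
            ds, _ = self.anisotropic_dataset(rng, n)
            intensities.append(fit_slda(ds).shrinkage_intensity)
        assert all(0 <= s <= 1 for s in intensities)
        assert intensities[0] > intensities[-1]
        assert intensities[-1] < 0.05

    def test_weights_converge_to_population_lda(self):
        """The fitted direction converges to the analytic solution
        inv(Sigma) @ (mu+ - mu-) of the generating Gaussians."""
        rng = np.random.default_rng(5)
        ds, scales = self.anisotropic_dataset(rng, 20000)
        model = fit_slda(ds)
        direction = model.weights / np.linalg.norm(model.weights)
        expected = np.zeros(len(scales))
        expected[0] = 2.0 / scales[0] ** 2
        expected /= np.linalg.norm(expected)
        assert np.abs(direction @ expected) > 0.99

    def test_qis_preserves_trace(self, rng):
        x = rng.standard_normal((500, 20))
        x -= x.mean(axis=0)
        cov = qis_covariance(x, 499)
        sample = x.T @ x / 499
        assert np.trace(cov) == pytest.approx(np.trace(sample), rel=1e-6)


class TestScoring:
    def test_scores_bounded(self, rng, decode_setup):
        feats, onsets = decode_setup["train"][0]
        ds = extract_labeled_windows(feats, onsets, 8, 0.2)
        model = fit_slda(ds)
        trace = score_run(model, feats)
        assert np.all((trace.values >= 0) & (trace.values <= 1))

    def test_equal_means_score_at_prior(self, rng):
        ds = gaussian_dataset(rng)
        model = fit_slda(ds)
        model.weights = np.zeros_like(model.weights)
        model.bias = float(np.log(model.priors[1] / model.priors[0]))
        feats = FeatureSeries(values=rng.standard_normal((12, 50)))
        trace = score_run(model, feats, n_window=1)
        assert np.allclose(trace.values, model.priors[1], atol=1e-12)

    def test_scores_peak_near_onsets_at_high_snr(self, decode_setup):
        feats, onsets = decode_setup["train"][0]
        ds = extract_labeled_windows(feats, onsets, 8, 0.2)
        model = fit_slda(ds)
        trace = score_run(model, feats)
        for onset in onsets[2:12]:
            window = (trace.times >= onset - 0.5) & (trace.times <= onset + 1.0)
            assert trace.values[window].max() > 0.5

    def test_dimension_mismatch_rejected(self, rng):
        ds = gaussian_dataset(rng)
        model = fit_slda(ds)
        feats = FeatureSeries(values=rng.standard_normal((5, 50)))
        with pytest.raises(ValueError):
            score_run(model, feats, n_window=1)


class TestHyperparameterSelection:
    def test_single_point_grid(self, decode_setup):
        cfg = DecoderConfig(n_window_grid=(6,), d_grid=(0.2,))
        result = select_hyperparameters(decode_setup["train"], cfg)
        assert (result.n_window, result.d) == (6, 0.2)

    def test_requires_three_runs(self, decode_setup):
        with pytest.raises(ValueError):
            select_hyperparameters(decode_setup["train"][:2], DecoderConfig())

    def test_matches_bruteforce_cv(self, decode_setup):
        """An explicit-loop CV oracle reproduces the selected pair."""
        cfg = DecoderConfig(n_window_grid=(5, 8), d_grid=(0.1, 0.3))
        result = select_hyperparameters(decode_setup["train"], cfg)

        best, best_pair = -np.inf, None
        for n_window in cfg.n_window_grid:
            for d in cfg.d_grid:
                sets = [extract_labeled_windows(f, o, n_window, d)
                        for f, o in decode_setup["train"]]
                scores = []
                for k in range(3):
                    m = fit_slda(sets[k])
                    scores.append(_fold_mcc(
                        m, [sets[j] for j in range(3) if j != k]))
                mean = np.mean(scores)
                if mean > best + 1e-12:
                    best, best_pair = mean, (n_window, d)
        assert (result.n_window, result.d) == best_pair
        assert result.cv_mcc[best_pair] == pytest.approx(best)
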