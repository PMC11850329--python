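import itertools

import numpy as np
import pytest

from rotacue.neural_analysis import (EpochSet, ERDSConfig, compare_conditions,
                                     correlate_nrmse_tpr, epoch, erds_map,
                                     nrmse)


def make_epochs(rng, n_trials=12, n_channels=3, n_time=100, rate=100.0,
                condition=""):
    data = rng.standard_normal((n_trials, n_channels, n_time))
    times = np.arange(n_time) / rate - 0.5
    return EpochSet(data=data, times=times, rate=rate, condition=condition)


class TestEpoch:
    def test_trial_count(self, rng):
        values = rng.standard_normal((4, 2000))
        onsets = np.arange(20.0, 120.0, 10.0)
        ep = epoch(values, 10.0, onsets, (-2.0, 2.0))
        assert ep.n_trials == 10
        assert ep.times[0] == pytest.approx(-2.0)
        assert ep.times[-1] == pytest.approx(2.0)

    def test_average_recovers_injected_template(self, rng):
        rate, n = 100.0, 60000
        template = np.sin(np.linspace(0, np.pi, 101))
        values = 0.3 * rng.standard_normal((2, n))
        onsets = np.arange(5.0, 595.0, 5.0)
        for o in onsets:
            i = int(o * rate) - 50
            values[0, i:i + 101] += template
        ep = epoch(values, rate, onsets, (-0.5, 0.5))
        recovered = ep.mean()[0]
        noise_after_avg = 0.3 / np.sqrt(len(onsets))
        assert np.sqrt(np.mean((recovered - template) ** 2)) < 3 * noise_after_avg

    def test_out_of_range_onsets_dropped(self, rng):
        values = rng.standard_normal((2, 100))
        with pytest.warns(UserWarning):
            ep = epoch(values, 10.0, [0.1, 5.0], (-1.0, 1.0))
        assert ep.n_trials == 1

    def test_degenerate_window_rejected(self, rng):
        with pytest.raises(ValueError):
            epoch(rng.standard_normal((2, 100)), 10.0, [5.0], (0.0, 0.0))

    def test_no_usable_trials_rejected(self, rng):
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            epoch(rng.standard_normal((2, 50)), 10.0, [0.0], (-1.0, 1.0))


class TestCompareConditions:
    def test_identical_sets_nothing_significant(self, rng):
        a = make_epochs(rng)
        b = EpochSet(data=a.data.copy(), times=a.times, rate=a.rate)
        stat = compare_conditions(a, b)
        assert stat.significant.sum() == 0

    def test_u_statistic_exact_small_sample(self):
        """{1,2,3} vs {4,5,6}: U = 0 and the exact two-sided p equals the
        full enumeration over all 20 arrangements."""
        a = EpochSet(data=np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1),
                     times=np.array([0.0]), rate=1.0)
        b = EpochSet(data=np.array([4.0, 5.0, 6.0]).reshape(3, 1, 1),
                     times=np.array([0.0]), rate=1.0)
        stat = compare_conditions(a, b)
        assert stat.u[0, 0] == 0.0

        # enumeration oracle: rank-sum of group A over all arrangements
        values = [1, 2, 3, 4, 5, 6]
        observed = sum(1 for x in (1, 2, 3) for y in (4, 5, 6) if x > y)
        count_extreme = 0
        arrangements = list(itertools.combinations(range(6), 3))
        for idx in arrangements:
            ga = [values[i] for i in idx]
            gb = [values[i] for i in range(6) if i not in idx]
            u = sum(1 for x in ga for y in gb if x > y)
            # two-sided: as or more extreme in either direction
            if min(u, 9 - u) <= min(observed, 9 - observed):
                count_extreme += 1
        exact_p = count_extreme / len(arrangements)
        assert stat.p[0, 0] == pytest.approx(exact_p)

    def test_injected_difference_found_post_onset(self, rng):
        a = make_epochs(rng, n_trials=40)
        b = make_epochs(rng, n_trials=40)
        post = a.times > 0
        b.data[:, 1, post] += 3.0
        stat = compare_conditions(a, b)
        sig_post = stat.significant[1, post].mean()
        sig_pre = stat.significant[:, ~post].mean()
        assert sig_post > 0.8
        assert sig_pre < 0.05

    def test_bonferroni_monotone_in_alpha(self, rng):
        a = make_epochs(rng, n_trials=30)
        b = make_epochs(rng, n_trials=30)
        b.data[:, 0, :] += 1.0
        loose = compare_conditions(a, b, alpha=0.05)
        tight = compare_conditions(a, b, alpha=0.001)
        assert np.all(loose.significant | ~tight.significant)

    def test_too_few_trials_rejected(self, rng):
        a = make_epochs(rng, n_trials=1)
        b = make_epochs(rng, n_trials=5)
        with pytest.raises(ValueError):
            compare_conditions(a, b)


class TestNRMSE:
    def test_identical_is_zero(self, rng):
        x = rng.standard_normal(100)
        assert nrmse(x, x) == 0.0

    def test_offset_sine_closed_form(self):
        t = np.linspace(0, 2 * np.pi, 10000, endpoint=False)
        ref = np.sin(t)
        assert nrmse(ref + 0.2, ref) == pytest.approx(0.1, rel=1e-6)

    def test_scale_invariance(self, rng):
        x, y = rng.standard_normal((2, 64))
        assert nrmse(3.7 * x, 3.7 * y) == pytest.approx(nrmse(x, y))

    def test_nonnegative_and_zero_only_if_equal(self, rng):
        x, y = rng.standard_normal((2, 64))
        assert nrmse(x, y) > 0

    def test_flat_reference_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.arange(5.0), np.ones(5))


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.arange(9.0)
        y = 10.0 - 2.0 * x
        r, p = correlate_nrmse_tpr(x, y)
        assert r == pytest.approx(-1.0)
        assert p < 1e-8

    def test_hand_computed_table(self):
        x = np.array([0.31, 0.45, 0.22, 0.61, 0.52, 0.38, 0.70, 0.29, 0.44])
        y = np.array([62.0, 40.0, 71.0, 12.0, 30.0, 55.0, 8.0, 66.0, 43.0])
        r, _ = correlate_nrmse_tpr(x, y)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2))
            * np.sqrt(np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(manual)

    def test_null_calibration(self):
        """Under independence (n=9), |r| exceeds the two-sided 5% critical
        value 0.666 in about 5% of repetitions."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 1000
        for _ in range(reps):
            r, _ = correlate_nrmse_tpr(rng.standard_normal(9),
                                       rng.standard_normal(9))
            if abs(r) > 0.666:
                hits += 1
        assert 0.03 < hits / reps < 0.075

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlate_nrmse_tpr([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            correlate_nrmse_tpr([1, 2], [1, 2])


class TestERDS:
    def make_oscillation_epochs(self, rng, erd_gain=0.5, n_trials=20,
                                rate=250.0, freq=10.0):
        times = np.arange(int(-2.5 * rate), int(1.5 * rate)) / rate
        data = np.empty((n_trials, 1, len(times)))
        for k in range(n_trials):
            phase = rng.uniform(0, 2 * np.pi)
            amp = np.where(times < 0, 1.0, erd_gain)
            data[k, 0] = amp * np.sin(2 * np.pi * freq * times + phase) \
                + 0.05 * rng.standard_normal(len(times))
        return EpochSet(data=data, times=times, rate=rate)

    def test_has_36_frequency_bins(self, rng):
        ep = self.make_oscillation_epochs(rng, n_trials=6)
        cfg = ERDSConfig(n_boot=20)
        out = erds_map(ep, cfg, rng=rng)
        assert out.values.shape[0] == 36
        assert len(out.freqs) == 36

    def test_halved_amplitude_gives_minus_75_percent(self, rng):
        ep = self.make_oscillation_epochs(rng, erd_gain=0.5)
        cfg = ERDSConfig(n_boot=50)
        out = erds_map(ep, cfg, rng=rng)
        band = np.argmin(np.abs(out.freqs - 10.0))
        post = (out.times > 0.4) & (out.times < 1.2)
        # (0.5 A)^2 / A^2 - 1 = -75 %
        assert out.values[band][post].mean() == pytest.approx(-75.0, abs=7.0)

    def test_stationary_noise_is_null(self):
        rng = np.random.default_rng(7)
        rate = 250.0
        times = np.arange(int(-2.5 * rate), int(1.5 * rate)) / rate
        data = rng.standard_normal((30, 1, len(times)))
        ep = EpochSet(data=data, times=times, rate=rate)
        cfg = ERDSConfig(n_boot=200)
        out = erds_map(ep, cfg, rng=rng)
        assert abs(np.median(out.values)) < 15.0
        assert out.significant.mean() < 0.15

    def test_global_gain_invariance(self, rng):
        ep = self.make_oscillation_epochs(rng, n_trials=8)
        scaled = EpochSet(data=5.0 * ep.data, times=ep.times, rate=ep.rate)
        cfg = ERDSConfig(n_boot=10)
        a = erds_map(ep, cfg, rng=np.random.default_rng(1))
        b = erds_map(scaled, cfg, rng=np.random.default_rng(1))
        assert np.allclose(a.values, b.values, atol=1e-8)

    def test_reference_outside_epoch_rejected(self, rng):
        ep = self.make_oscillation_epochs(rng, n_trials=4)
        short = EpochSet(data=ep.data[:, :, ep.times > -1.0],
                         times=ep.times[ep.times > -1.0], rate=ep.rate)
        with pytest.raises(ValueError):
            erds_map(short, ERDSConfig(n_boot=5), rng=rng)
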