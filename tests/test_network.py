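"""Functional connectivity, surrogate significance, synchrony index."""

import numpy as np
import pytest

from neurocalnet import compute_dff, detect_transients
from neurocalnet import synthetic as syn
from neurocalnet.network import (
    connectivity_matrix,
    connectivity_summary,
    surrogate_significance,
    sync_index,
    synchronization_matrix,
)
from neurocalnet.synthetic import CalciumSimConfig, gen_calcium_traces


def brute_force_pearson(x):
    """Per-pair covariance/SD oracle, deliberately elementwise."""
    n = x.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
            out[i, j] = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
    return out


class TestConnectivityMatrix:
    def test_duplicate_and_negated_traces(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 200)
        x = np.vstack([base, base, -base])
        r = connectivity_matrix(x)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 3, (5, 200)) + rng.uniform(-5, 5, (5, 1))
        np.testing.assert_allclose(connectivity_matrix(x),
                                   brute_force_pearson(x), atol=1e-12)

    def test_silent_neuron_zeroed_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (3, 100))
        x[1] = 4.2
        with pytest.warns(UserWarning):
            r = connectivity_matrix(x)
        assert r[1, 0] == 0.0 and r[1, 1] == 1.0

    def test_nan_rejected(self):
        x = np.zeros((2, 100))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            connectivity_matrix(x)


class TestSurrogateSignificance:
    def test_independent_noise_calibrated(self):
        # false-positive rate at alpha=0.05 within binomial error
        rng = np.random.default_rng(3)
        fracs = []
        for s in range(5):
            x = rng.normal(0, 1, (20, 2000))
            mask = surrogate_significance(x, n_surrogates=400, alpha=0.05,
                                          seed=s)
            fracs.append(mask[np.triu_indices(20, 1)].mean())
        assert 0.02 <= np.mean(fracs) <= 0.08

    def test_full_coupling_all_significant(self):
        cfg = CalciumSimConfig(shared_drive_weight=1.0, n_neurons=6,
                               duration=120.0, seed=4, noise_sd=0.01)
        tm, _ = gen_calcium_traces(cfg)
        mask = surrogate_significance(compute_dff(tm), n_surrogates=200,
                                      alpha=0.05, seed=0)
        iu = np.triu_indices(6, 1)
        assert mask[iu].all()

    def test_seeded_rerun_identical(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (8, 500))
        m1 = surrogate_significance(x, 100, 0.05, seed=9)
        m2 = surrogate_significance(x, 100, 0.05, seed=9)
        np.testing.assert_array_equal(m1, m2)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            surrogate_significance(np.zeros((3, 500)), n_surrogates=10)


class TestSynchronizationMatrix:
    def test_identical_trains_unit_entry(self):
        trains = [np.array([1.0, 5.0, 9.0]), np.array([1.0, 5.0, 9.0])]
        m = synchronization_matrix(trains, 2, 10.0, bin_width=0.5)
        assert m[0, 1] == pytest.approx(1.0)

    def test_disjoint_single_events_nonpositive(self):
        trains = [np.array([1.0]), np.array([6.0])]
        m = synchronization_matrix(trains, 2, 10.0, bin_width=0.5)
        assert m[0, 1] <= 0.0

    def test_empty_train_zero_with_warning(self):
        trains = [np.array([1.0, 2.0]), np.array([])]
        with pytest.warns(UserWarning):
            m = synchronization_matrix(trains, 2, 10.0)
        assert m[0, 1] == 0.0

    def test_mean_entry_increases_with_coupling(self):
        means = []
        for w in (0.0, 0.5, 1.0):
            vals = []
            for s in range(5):
                tm, gt = gen_calcium_traces(
                    CalciumSimConfig(shared_drive_weight=w, seed=500 + s,
                                     n_neurons=10, duration=200.0)
                )
                m = synchronization_matrix(gt.spike_times, 10, 200.0)
                vals.append(m[np.triu_indices(10, 1)].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_duration_shorter_than_bin_rejected(self):
        with pytest.raises(ValueError):
            synchronization_matrix([np.array([0.1])], 1, 0.2, bin_width=0.5)


class TestSyncIndex:
    def test_identical_dense_trains_near_one(self):
        times = np.arange(0.25, 300.0, 1.5)
        trains = [times.copy() for _ in range(10)]
        idx = sync_index(trains, 10, 300.0, n_surrogates=300, seed=0)
        assert idx >= 0.9

    def test_independent_trains_calibrated(self):
        vals = []
        for s in range(20):
            tm, gt = gen_calcium_traces(
                CalciumSimConfig(seed=700 + s, n_neurons=25)
            )
            vals.append(sync_index(gt.spike_times, 25, 300.0,
                                   n_surrogates=300, seed=s))
        # strictly-exceeds rule on integer counts: sized at or below the
        # nominal 5%, and must not collapse to zero
        assert 0.0 < np.mean(vals) <= 0.08

    def test_single_neuron_degenerate(self):
        with pytest.warns(UserWarning):
            assert sync_index([np.array([1.0])], 1, 10.0) == 0.0

    def test_no_events_zero(self):
        with pytest.warns(UserWarning):
            assert sync_index([np.array([]), np.array([])], 2, 10.0) == 0.0


class TestConnectivitySummary:
    def test_all_ones_full_mask(self):
        m = np.ones((4, 4))
        mask = ~np.eye(4, dtype=bool)
        assert connectivity_summary(m, mask) == pytest.approx(1.0)

    def test_hand_built_mean(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.2
        m[0, 2] = m[2, 0] = 0.4
        m[1, 2] = m[2, 1] = 0.6
        mask = ~np.eye(3, dtype=bool)
        assert connectivity_summary(m, mask) == pytest.approx(0.4)

    def test_empty_mask_zero_with_warning(self):
        with pytest.warns(UserWarning):
            out = connectivity_summary(np.eye(3), np.zeros((3, 3), bool))
        assert out == 0.0

    def test_asymmetric_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValueError):
            connectivity_summary(m, np.zeros((3, 3), bool))


class TestCouplingRecovery:
    def test_spearman_against_planted_coupling(self):
        from scipy.stats import spearmanr

        wrng = np.random.default_rng(123)
        weights = tuple(wrng.uniform(0.0, 1.0, 25))
        mats = []
        for s in range(3):
            tm, gt = gen_calcium_traces(
                CalciumSimConfig(seed=900 + s, shared_drive_weight=weights)
            )
            mats.append(connectivity_matrix(compute_dff(tm)))
        est = np.mean(mats, axis=0)
        iu = np.triu_indices(25, 1)
        rho = spearmanr(gt.coupling_matrix[iu], est[iu]).statistic
        assert rho >= 0.8
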