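import math

import numpy as np
import pytest

from fwec import core
from fwec.data import DataMatrix, compute_precision

from .oracles import dispersion_oracle, objective_oracle, weight_dispersion_oracle


class TestPointwiseDistance:
    def test_zero_at_center(self):
        assert core.pointwise_distance(3.0, 3.0, 5.0) == 0.0

    def test_zero_delta_degenerates(self):
        assert core.pointwise_distance(1.0, 9.0, 0.0) == 0.0

    def test_unit_case(self):
        # delta=1, |x-c|=1 -> 1 - e^{-1}
        val = core.pointwise_distance(2.0, 1.0, 1.0)
        assert val == pytest.approx(1.0 - math.exp(-1.0), abs=1e-15)

    def test_saturates_at_one(self):
        assert core.pointwise_distance(1e6, 0.0, 1.0) == pytest.approx(1.0)
        # below float saturation the bound is strict
        assert core.pointwise_distance(5.0, 0.0, 1.0) < 1.0
        assert core.pointwise_distance(5.0, 0.0, 1.0) > 1.0 - 2e-11

    def test_euclidean_mode(self):
        assert core.pointwise_distance(5.0, 2.0, 7.0, mode="euclidean") == 9.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            core.pointwise_distance(1.0, 0.0, 1.0, mode="manhattan")


class TestDispersion:
    def test_zero_at_center(self, rng):
        X = rng.normal(size=(4, 3))
        C = np.vstack([X[0], X[2]])
        W = np.full((2, 3), 1 / 3)
        D = core.sample_cluster_dispersion(X, W, C, np.ones(3))
        assert D[0, 0] == pytest.approx(0.0, abs=1e-15)
        assert D[2, 1] == pytest.approx(0.0, abs=1e-15)

    def test_uniform_weights_are_mean(self, rng):
        X = rng.normal(size=(5, 4))
        C = rng.normal(size=(2, 4))
        delta = rng.uniform(0.1, 2, size=4)
        W = np.full((2, 4), 0.25)
        D = core.sample_cluster_dispersion(X, W, C, delta)
        d = np.array(
            [
                [
                    np.mean(
                        [core.pointwise_distance(X[i, l], C[j, l], delta[l]) for l in range(4)]
                    )
                    for j in range(2)
                ]
                for i in range(5)
            ]
        )
        np.testing.assert_allclose(D, d, atol=1e-14)

    @pytest.mark.parametrize("mode", core.DISTANCE_MODES)
    def test_matches_loop_oracle(self, rng, mode):
        X = rng.normal(size=(4, 3))
        C = rng.normal(size=(2, 3))
        W = rng.dirichlet(np.ones(3), size=2)
        delta = rng.uniform(0.1, 3.0, size=3)
        D = core.sample_cluster_dispersion(X, W, C, delta, mode=mode)
        np.testing.assert_allclose(D, dispersion_oracle(X, W, C, delta, mode), atol=1e-12)

    def test_bounded_in_kernel_mode(self, rng):
        X = rng.normal(scale=2, size=(20, 5))
        C = rng.normal(size=(3, 5))
        W = rng.dirichlet(np.ones(5), size=3)
        D = core.sample_cluster_dispersion(X, W, C, np.ones(5))
        assert np.all(D >= 0) and np.all(D < 1)
        # even absurdly distant points cannot exceed the saturation bound
        far = core.sample_cluster_dispersion(X + 1e6, W, C, np.ones(5))
        assert np.all(far <= 1.0)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch|shape"):
            core.sample_cluster_dispersion(
                np.zeros((4, 3)), np.full((2, 2), 0.5), np.zeros((2, 2)), np.ones(2)
            )


class TestUpdateMemberships:
    def test_single_cluster(self):
        U = core.update_memberships(np.random.rand(7, 1), lam=0.3)
        np.testing.assert_allclose(U, 1.0)

    def test_equal_dispersions_uniform(self):
        D = np.full((5, 4), 0.37)
        U = core.update_memberships(D, lam=0.5)
        np.testing.assert_allclose(U, 0.25, atol=1e-12)

    def test_two_cluster_closed_form(self):
        lam = 0.3
        D = np.array([[0.0, lam]])
        U = core.update_memberships(D, lam)
        assert U[0, 0] == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)

    def test_large_lam_approaches_uniform(self, rng):
        D = rng.uniform(size=(10, 3))
        U = core.update_memberships(D, lam=100.0)
        assert np.max(np.abs(U - 1 / 3)) < 0.01

    def test_rows_sum_to_one_and_positive(self, rng):
        D = rng.uniform(0, 50, size=(30, 5))
        U = core.update_memberships(D, lam=0.05)
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(U > 0)

    def test_tiny_lam_no_overflow(self, rng):
        D = rng.uniform(0, 1, size=(10, 4))
        U = core.update_memberships(D, lam=1e-6)
        assert np.all(np.isfinite(U))
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_lam(self):
        with pytest.raises(ValueError):
            core.update_memberships(np.zeros((2, 2)), lam=0.0)


class TestUpdateWeights:
    def test_single_feature(self, rng):
        X = rng.normal(size=(5, 1))
        C = rng.normal(size=(2, 1))
        U = rng.dirichlet(np.ones(2), size=5)
        W = core.update_weights(X, U, C, np.ones(1), gam=1.4)
        np.testing.assert_allclose(W, 1.0)

    def test_symmetric_dispersions_uniform(self):
        # identical columns => identical D' => uniform weights
        X = np.tile(np.array([[0.0], [1.0], [2.0]]), (1, 4))
        C = np.tile(np.array([[0.5], [1.5]]), (1, 4))
        U = np.full((3, 2), 0.5)
        W = core.update_weights(X, U, C, np.ones(4), gam=1.4)
        np.testing.assert_allclose(W, 0.25, atol=1e-12)

    def test_large_gam_uniform(self, rng):
        X = rng.normal(size=(10, 5))
        C = rng.normal(size=(3, 5))
        U = rng.dirichlet(np.ones(3), size=10)
        W = core.update_weights(X, U, C, np.ones(5), gam=100.0)
        assert np.max(np.abs(W - 0.2)) < 0.01

    def test_matches_softmax_of_loop_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        C = rng.normal(size=(2, 4))
        U = rng.dirichlet(np.ones(2), size=6)
        delta = rng.uniform(0.2, 2, size=4)
        gam = 0.7
        W = core.update_weights(X, U, C, delta, gam)
        dp = weight_dispersion_oracle(X, U, C, delta)
        expected = np.exp(-dp / gam)
        expected /= expected.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_invalid_gam(self, rng):
        with pytest.raises(ValueError):
            core.update_weights(np.zeros((2, 2)), np.full((2, 1), 1.0), np.zeros((1, 2)), np.ones(2), gam=-1.0)


class TestUpdateCenters:
    def test_single_sample_pinned(self):
        X = np.array([[2.0, -3.0]])
        U = np.array([[1.0]])
        W = np.array([[0.5, 0.5]])
        C = core.update_centers(X, U, W, np.ones(2), C_prev=np.zeros((1, 2)))
        np.testing.assert_allclose(C, X, atol=1e-12)

    def test_delta_zero_gives_weighted_mean(self, rng):
        X = rng.normal(size=(8, 2))
        U = rng.dirichlet(np.ones(2), size=8)
        W = rng.dirichlet(np.ones(2), size=2)
        C = core.update_centers(X, U, W, np.zeros(2), C_prev=rng.normal(size=(2, 2)))
        expected = (U.T @ X) / U.sum(axis=0)[:, None]
        np.testing.assert_allclose(C, expected, atol=1e-12)

    def test_midpoint_is_fixed_point(self):
        X = np.array([[0.0], [4.0]])
        U = np.array([[0.5], [0.5]])
        W = np.array([[1.0]])
        C_prev = np.array([[2.0]])  # midpoint
        C = core.update_centers(X, U, W, np.ones(1), C_prev=C_prev)
        np.testing.assert_allclose(C, C_prev, atol=1e-12)

    def test_euclidean_exact_weighted_mean(self, rng):
        X = rng.normal(size=(10, 3))
        U = rng.dirichlet(np.ones(2), size=10)
        W = rng.dirichlet(np.ones(3), size=2)
        C = core.update_centers(X, U, W, np.ones(3), C_prev=np.zeros((2, 3)), mode="euclidean")
        expected = (U.T @ X) / U.sum(axis=0)[:, None]
        np.testing.assert_allclose(C, expected, atol=1e-12)

    def test_center_stays_in_data_range(self, rng):
        X = rng.normal(size=(20, 4))
        U = rng.dirichlet(np.ones(3), size=20)
        W = rng.dirichlet(np.ones(4), size=3)
        C = core.update_centers(X, U, W, np.ones(4), C_prev=X[:3].copy())
        for l in range(4):
            assert np.all(C[:, l] >= X[:, l].min() - 1e-12)
            assert np.all(C[:, l] <= X[:, l].max() + 1e-12)

    def test_dead_kernel_keeps_previous(self):
        # huge delta, center far away: all kernel mass vanishes
        X = np.array([[1000.0], [1001.0]])
        U = np.array([[1.0], [1.0]])
        W = np.array([[1.0]])
        C_prev = np.array([[0.0]])
        C = core.update_centers(X, U, W, np.array([10.0]), C_prev=C_prev)
        np.testing.assert_allclose(C, C_prev)


class TestObjective:
    def test_degenerate_1x1(self):
        X = np.array([[2.0]])
        U = np.array([[1.0]])
        W = np.array([[1.0]])
        C = np.array([[0.5]])
        delta = np.array([1.5])
        f = core.objective(X, U, W, C, delta, lam=0.3, gam=1.4)
        assert f == pytest.approx(1.0 - math.exp(-1.5 * 2.25), abs=1e-14)

    def test_uniform_blocks_entropy_only(self):
        # all points at their centers: distance term 0, pure entropy
        n, k, m = 4, 2, 3
        X = np.zeros((n, m))
        C = np.zeros((k, m))
        U = np.full((n, k), 1 / k)
        W = np.full((k, m), 1 / m)
        lam, gam = 0.3, 1.4
        f = core.objective(X, U, W, C, np.ones(m), lam, gam)
        expected = -lam * n * math.log(k) - gam * k * math.log(m)
        assert f == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("mode", core.DISTANCE_MODES)
    def test_matches_loop_oracle(self, rng, mode):
        X = rng.normal(size=(5, 3))
        C = rng.normal(size=(2, 3))
        U = rng.dirichlet(np.ones(2), size=5)
        W = rng.dirichlet(np.ones(3), size=2)
        delta = rng.uniform(0.1, 2, size=3)
        f = core.objective(X, U, W, C, delta, lam=0.3, gam=1.4, mode=mode)
        expected = objective_oracle(X, U, W, C, delta, 0.3, 1.4, mode)
        assert f == pytest.approx(expected, abs=1e-10)
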