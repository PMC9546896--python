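"""Fisher information, Cramér–Rao matrices, and schedule-cost criteria."""

import warnings

import numpy as np
import pytest

from tslopt.crlb import (
    DEFAULT_WEIGHTS,
    ScheduleCost,
    crlb_cost,
    crm,
    default_weights,
    fim,
    mcrlb_cost,
    sample_params,
)
from tslopt.exceptions import ConfigError, EvaluationError
from tslopt.models import default_box, jacobian_array
from tslopt.scheduler import paper_grid


class TestSampling:
    def test_draws_respect_bounds_and_unit_amplitude(self, stretched_box):
        s = sample_params(stretched_box, 500, seed=3)
        assert np.all(s.theta[:, 1] >= 10.0) and np.all(s.theta[:, 1] <= 90.0)
        assert np.all(s.theta[:, 2] >= 0.4) and np.all(s.theta[:, 2] <= 1.0)
        assert np.all(s.theta[:, 0] == 1.0)

    def test_same_seed_same_draws(self, bi_box):
        a = sample_params(bi_box, 50, seed=9).theta
        b = sample_params(bi_box, 50, seed=9).theta
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_approaches_box_midpoint(self, bi_box):
        """Law of large numbers: the uniform mean is the midpoint within 3 s.e."""
        n = 100_000
        s = sample_params(bi_box, n, seed=1)
        for i in (1, 2, 3):  # amplitude is pinned to 1
            lo, hi = bi_box.lower[i], bi_box.upper[i]
            se = (hi - lo) / np.sqrt(12 * n)
            assert abs(s.theta[:, i].mean() - 0.5 * (lo + hi)) < 3 * se

    def test_count_validated(self, bi_box):
        with pytest.raises(ConfigError):
            sample_params(bi_box, 0)


class TestFIM:
    def test_matches_naive_outer_product_sum(self, bi_samples_small):
        theta = bi_samples_small.theta[4]
        tsl = np.array([0.5, 3.0, 12.0, 30.0, 55.0])
        sigma = 0.7
        naive = np.zeros((4, 4))
        for t in tsl:
            J = jacobian_array("bi", np.array([t]), theta)[0]
            naive += np.outer(J, J) / sigma**2
        F = fim(tsl, theta, sigma=sigma, model="bi").matrix
        np.testing.assert_allclose(F, naive, atol=1e-12)

    def test_identical_tsls_give_rank_one(self):
        theta = np.array([1.0, 40.0, 0.7])
        F = fim([10.0] * 5, theta, model="stretched").matrix
        F1 = fim([10.0], theta, model="stretched").matrix
        np.testing.assert_allclose(F, 5 * F1, atol=1e-12)
        assert np.linalg.matrix_rank(F) == 1

    def test_sigma_scaling(self):
        theta = np.array([1.0, 0.5, 5.0, 50.0])
        tsl = [0.5, 5.0, 20.0, 55.0]
        F1 = fim(tsl, theta, sigma=1.0, model="bi").matrix
        F2 = fim(tsl, theta, sigma=0.5, model="bi").matrix
        np.testing.assert_allclose(F2, 4 * F1, rtol=1e-12)

    def test_symmetric_psd(self, stretched_samples_small):
        tsl = [0.5, 8.0, 25.0, 55.0]
        for theta in stretched_samples_small.theta[:5]:
            F = fim(tsl, theta, model="stretched").matrix
            np.testing.assert_allclose(F, F.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(F) > -1e-10)

    def test_agrees_with_finite_difference_jacobian(self):
        theta = np.array([1.0, 0.3, 4.0, 60.0])
        tsl = np.array([0.5, 2.0, 9.0, 25.0, 55.0])
        F = fim(tsl, theta, model="bi").matrix
        Jfd = np.empty((tsl.size, 4))
        from tslopt.models import signal_array

        for i in range(4):
            h = 1e-6 * max(abs(theta[i]), 1.0)
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            Jfd[:, i] = (signal_array("bi", tsl, tp) - signal_array("bi", tsl, tm)) / (2 * h)
        np.testing.assert_allclose(F, Jfd.T @ Jfd, rtol=1e-4)


class TestCRM:
    def test_diagonal_inverse(self):
        V = crm(np.diag([4.0, 0.25]))
        np.testing.assert_allclose(V.matrix, np.diag([0.25, 4.0]))
        assert not V.degenerate

    def test_inverse_contract(self):
        theta = np.array([1.0, 0.5, 5.0, 50.0])
        F = fim([0.5, 2, 8, 20, 40, 55], theta, model="bi")
        V = crm(F)
        np.testing.assert_allclose(V.matrix @ F.matrix, np.eye(4), atol=1e-9)

    def test_singular_flagged_degenerate(self):
        V = crm(np.ones((3, 3)))
        assert V.degenerate and np.all(np.isnan(V.matrix))

    def test_appending_tsl_never_raises_any_crlb(self):
        """Information ordering: a longer schedule is never worse, per parameter."""
        rng = np.random.default_rng(5)
        box = default_box("stretched")
        worst = -np.inf
        for _ in range(100):
            theta = rng.uniform(box.lower, box.upper)
            theta[0] = 1.0
            tsl = list(rng.choice(np.arange(0.5, 55.5, 0.5), size=4))
            V0 = crm(fim(tsl, theta, model="stretched"))
            if V0.degenerate:
                continue
            V1 = crm(fim(tsl + [float(rng.choice(np.arange(0.5, 55.5)))], theta, model="stretched"))
            worst = max(worst, np.max(V1.crlbs - V0.crlbs))
        assert worst <= 1e-8


class TestCosts:
    def test_all_zero_weights_give_zero(self, stretched_samples_small):
        tsl = [0.5, 11.0, 55.0]
        assert crlb_cost(tsl, stretched_samples_small, [0, 0, 0]) == 0.0
        assert mcrlb_cost(tsl, stretched_samples_small, [0, 0, 0]) == 0.0

    def test_single_sample_one_hot_reduction(self, stretched_box):
        s = sample_params(stretched_box, 1, seed=2)
        tsl = [0.5, 9.0, 30.0, 55.0]
        V = crm(fim(tsl, s.theta[0], model="stretched"))
        assert crlb_cost(tsl, s, [0, 1, 0]) == pytest.approx(V.crlbs[1], rel=1e-12)
        expected = np.sqrt(abs(V.crlbs[2])) / abs(s.theta[0, 2])
        assert mcrlb_cost(tsl, s, [0, 0, 1]) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("criterion", ["crlb", "mcrlb"])
    def test_batched_evaluator_matches_naive_loop(self, criterion, bi_samples_small, grid):
        """The vectorized grid evaluator equals the loop-and-invert reference."""
        naive = {"crlb": crlb_cost, "mcrlb": mcrlb_cost}[criterion]
        cost = ScheduleCost("bi", grid, bi_samples_small, criterion=criterion)
        for tsl in ([0.5, 3.0, 20.0, 55.0], [0.5, 2.0, 6.0, 21.0, 22.0, 55.0]):
            assert cost(tsl) == pytest.approx(naive(tsl, bi_samples_small), rel=1e-10)

    def test_sigma_scale_invariance_of_ranking(self, stretched_samples_small, grid):
        a, b = [0.5, 11.0, 55.0], [0.5, 30.0, 55.0]
        c1 = ScheduleCost("stretched", grid, stretched_samples_small, sigma=1.0)
        c2 = ScheduleCost("stretched", grid, stretched_samples_small, sigma=3.0)
        assert c2(a) == pytest.approx(9 * c1(a), rel=1e-9)
        assert (c1(a) < c1(b)) == (c2(a) < c2(b))
        m1 = ScheduleCost("stretched", grid, stretched_samples_small, criterion="mcrlb", sigma=1.0)
        m2 = ScheduleCost("stretched", grid, stretched_samples_small, criterion="mcrlb", sigma=3.0)
        assert m2(a) == pytest.approx(3 * m1(a), rel=1e-9)

    def test_cost_non_increasing_under_appending(self, bi_samples_small, grid):
        cost = ScheduleCost("bi", grid, bi_samples_small)
        base = [0.5, 2.0, 10.0, 30.0, 55.0]
        c0 = cost(base)
        for extra in (1.0, 15.0, 55.0):
            assert cost(base + [extra]) <= c0 + 1e-9

    def test_degenerate_schedule_scores_infinite(self, bi_samples_small, grid):
        cost = ScheduleCost("bi", grid, bi_samples_small)
        assert np.isinf(cost([10.0, 10.0, 10.0, 10.0]))
        with pytest.raises(EvaluationError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                crlb_cost([10.0, 10.0, 10.0, 10.0], bi_samples_small)

    def test_default_weight_vectors(self):
        np.testing.assert_allclose(default_weights("bi"), [0.0, 0.3, 0.4, 0.3])
        np.testing.assert_allclose(default_weights("stretched"), [0.0, 0.9, 0.1])
        with pytest.raises(ConfigError):
            default_weights("quad")
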