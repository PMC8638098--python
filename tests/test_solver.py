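"""FISTA solve of the weighted-lasso D-trace model."""

import numpy as np
import pytest

import wdtrace as w
from wdtrace.solver import SolverConfig

from helpers import random_covariance_pair, reference_objective_minimum


class TestObjective:
    def test_zero_delta(self, small_cov):
        W = np.ones((10, 10))
        assert w.objective(np.zeros((10, 10)), small_cov, W, 0.5) == 0.0

    def test_lambda_zero_equals_loss(self, small_cov, rng):
        D = rng.standard_normal((10, 10))
        W = np.ones((10, 10))
        assert w.objective(D, small_cov, W, 0.0) == w.dtrace_loss(D, small_cov)

    def test_matches_term_by_term_evaluation(self, rng):
        Sx, Sy = random_covariance_pair(4, rng)
        cov = w.CovariancePair(Sx, Sy, 60, 60)
        D = rng.standard_normal((4, 4))
        W = rng.uniform(0.1, 1, size=(4, 4))
        lam = 0.2
        pen = lam * sum(
            W[i, j] * abs(D[i, j]) for i in range(4) for j in range(4) if i != j
        )
        expected = w.dtrace_loss(D, cov) + pen
        assert w.objective(D, cov, W, lam) == pytest.approx(expected, abs=1e-12)


class TestSolveWdtrace:
    def test_unpenalized_recovers_precision_difference(self):
        scn = w.make_precision_pair(5, 4, 3, 0.5, seed=7)
        X = w.sample_expression(scn.theta_X, 10_000, seed=1)
        Y = w.sample_expression(scn.theta_Y, 10_000, seed=2)
        cov = w.CovariancePair.from_samples(X, Y)
        net, trace = w.solve_wdtrace(
            cov, None, SolverConfig(lam=0.0, tol=1e-12, max_iter=20_000)
        )
        target = np.linalg.inv(cov.sigma_Y) - np.linalg.inv(cov.sigma_X)
        assert trace.converged
        assert np.abs(net.delta - target).max() < 1e-3

    def test_objective_monotone_with_restart(self, small_cov):
        _, trace = w.solve_wdtrace(small_cov, None, SolverConfig(lam=0.05))
        objs = np.array(trace.objective_per_iter)
        assert np.all(np.diff(objs) <= 1e-12)
        assert objs[-1] <= objs[0]

    def test_matches_convex_oracle(self, rng):
        for p, lam in [(3, 0.05), (4, 0.1), (5, 0.3)]:
            Sx, Sy = random_covariance_pair(p, rng)
            cov = w.CovariancePair(Sx, Sy, 60, 60)
            W = np.ones((p, p))
            net, _ = w.solve_wdtrace(
                cov, W, SolverConfig(lam=lam, tol=1e-12, max_iter=50_000)
            )
            ours = w.objective(net.delta, cov, W, lam)
            ref = reference_objective_minimum(Sx, Sy, W, lam)
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_delta_symmetric_and_support_exact(self, small_cov):
        net, _ = w.solve_wdtrace(small_cov, None, SolverConfig(lam=0.1))
        assert np.array_equal(net.delta, net.delta.T)
        expected = {
            (i, j)
            for i in range(net.p)
            for j in range(i + 1, net.p)
            if net.delta[i, j] != 0.0
        }
        assert net.support == expected

    def test_nonconvergence_reported_not_hidden(self, small_cov):
        net, trace = w.solve_wdtrace(
            small_cov, None, SolverConfig(lam=0.01, max_iter=2, tol=1e-15)
        )
        assert not trace.converged
        assert trace.n_iter == 2

    def test_backtracking_agrees_with_fixed_step(self, small_cov):
        cfg_f = SolverConfig(lam=0.1, tol=1e-10)
        cfg_b = SolverConfig(lam=0.1, tol=1e-10, step_rule="backtracking")
        net_f, _ = w.solve_wdtrace(small_cov, None, cfg_f)
        net_b, _ = w.solve_wdtrace(small_cov, None, cfg_b)
        assert np.abs(net_f.delta - net_b.delta).max() < 1e-4

    def test_support_shrinks_with_lambda_on_separated_instances(self, small_cov):
        sizes = []
        for lam in [0.4, 0.2, 0.1, 0.05]:
            net, _ = w.solve_wdtrace(small_cov, None, SolverConfig(lam=lam))
            sizes.append(net.n_edges)
        assert sizes == sorted(sizes)

    def test_huge_covariances_abort_with_diagnostic(self):
        cov = w.CovariancePair(
            1e200 * np.diag([2.0, 1.0, 1.0]), 1e200 * np.eye(3), 10, 10
        )
        with pytest.raises((FloatingPointError, OverflowError)):
            w.solve_wdtrace(cov, None, SolverConfig(lam=0.1))


class TestLambdaMax:
    def test_identical_covariances_give_zero(self):
        cov = w.CovariancePair(np.eye(4), np.eye(4), 10, 10)
        assert w.lambda_max(cov) == 0.0

    def test_penalized_diagonal_closed_form(self, rng):
        Sx, Sy = random_covariance_pair(5, rng)
        cov = w.CovariancePair(Sx, Sy, 60, 60)
        assert w.lambda_max(cov, None, penalize_diagonal=True) == pytest.approx(
            np.abs(Sx - Sy).max()
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_boundary_via_solver(self, seed):
        """Empty support at/above lambda_max, edges just below it."""
        rng = np.random.default_rng(seed)
        Sx, Sy = random_covariance_pair(6, rng, n=80)
        cov = w.CovariancePair(Sx, Sy, 80, 80)
        lm = w.lambda_max(cov)
        for mult in (1.0, 1.2):
            net, _ = w.solve_wdtrace(cov, None, SolverConfig(lam=mult * lm))
            assert net.n_edges == 0
        net, _ = w.solve_wdtrace(
            cov, None, SolverConfig(lam=0.95 * lm, tol=1e-10, max_iter=20_000)
        )
        assert net.n_edges > 0

    def test_prior_weighted_entry_lowers_threshold(self, rng):
        Sx, Sy = random_covariance_pair(5, rng)
        cov = w.CovariancePair(Sx, Sy, 60, 60)
        Wm = np.ones((5, 5))
        lm_unw = w.lambda_max(cov, Wm)
        Wm[0, 1] = Wm[1, 0] = 0.1
        lm_w = w.lambda_max(cov, Wm)
        assert lm_w >= lm_unw  # cheaper edge needs more penalty to silence
        # bisection-style check around the weighted threshold
        net_hi, _ = w.solve_wdtrace(cov, Wm, SolverConfig(lam=1.001 * lm_w))
        net_lo, _ = w.solve_wdtrace(
            cov, Wm, SolverConfig(lam=0.97 * lm_w, tol=1e-10, max_iter=20_000)
        )
        assert net_hi.n_edges == 0
        assert net_lo.n_edges > 0


class TestPriorSensitivity:
    def test_full_coverage_prior_never_hurts_recall(self):
        for seed in range(3):
            scn = w.make_precision_pair(20, 10, 6, 0.4, seed=seed)
            X = w.sample_expression(scn.theta_X, 200, seed=100 + seed)
            Y = w.sample_expression(scn.theta_Y, 200, seed=200 + seed)
            cov = w.CovariancePair.from_samples(X, Y)
            prior = w.make_prior_network(scn, coverage=1.0, noise_edges=0, seed=seed)
            Wm = w.build_weight_matrix(prior, scn.gene_ids, w=0.1).values
            lam = 0.5 * w.lambda_max(cov)
            rec = {}
            for key, weights in [("unw", None), ("prior", Wm)]:
                net, _ = w.solve_wdtrace(cov, weights, SolverConfig(lam=lam))
                rec[key] = len(net.support & scn.diff_edges) / len(scn.diff_edges)
            assert rec["prior"] >= rec["unw"]
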