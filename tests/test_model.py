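"""Unit and property tests for the variational EM core."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit, logit

from bmdd import (
    BMDDError,
    CountTable,
    Hyperparams,
    VariationalState,
    alpha_objective,
    compute_h,
    e_step,
    elbo_surrogate,
    exact_log_marginal,
    exact_posterior_mean,
    fit,
    init_params,
    m_step,
    posterior_mean,
    posterior_sample,
    update_beta,
    update_gamma,
    update_pi,
)
from bmdd.model import FitConfig

from conftest import make_bmdd_truth


def random_instance(seed, n=None, m=None, depth=200):
    """Small random model + data drawn from it, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(3, 10))
    m = m or int(rng.integers(3, 7))
    hyper = Hyperparams(
        pi=rng.uniform(0.1, 0.9, m),
        alpha0=rng.uniform(0.05, 0.5, m),
        alpha1=rng.uniform(1.0, 20.0, m),
    )
    truth, _ = make_bmdd_truth(n=n, m=m, depth=depth, seed=seed, hyper=hyper)
    return truth.table, hyper


class TestInitParams:
    def test_invariants_and_determinism(self, small_table):
        h1, s1 = init_params(small_table)
        h2, s2 = init_params(small_table)
        assert np.array_equal(s1.gamma, s2.gamma)
        assert np.array_equal(h1.alpha0, h2.alpha0)
        assert np.all((s1.gamma > 0) & (s1.gamma < 1))
        assert np.all(h1.alpha0 <= h1.alpha1)
        assert np.all((h1.pi > 0) & (h1.pi < 1))
        assert np.all(s1.beta > 0)

    def test_single_taxon_rejected(self):
        table = CountTable(counts=np.array([[3], [4]]))
        with pytest.raises(BMDDError):
            init_params(table)


class TestUpdateBeta:
    def test_printed_formula(self):
        table = CountTable(counts=np.array([[5, 5], [5, 5]]))
        hyper = Hyperparams(
            pi=np.array([0.5, 0.5]),
            alpha0=np.array([0.1, 0.1]),
            alpha1=np.array([2.0, 2.0]),
        )
        beta = update_beta(table, np.full((2, 2), 0.5), hyper)
        assert np.allclose(beta, 5 + 0.5 * 2.0 + 0.5 * 0.1)

    @pytest.mark.parametrize("g,mode", [(0.0, "alpha0"), (1.0, "alpha1")])
    def test_degenerate_gamma_collapses_to_one_mode(self, small_table, small_hyper, g, mode):
        beta = update_beta(small_table, np.full(small_table.counts.shape, g), small_hyper)
        expected = small_table.counts + getattr(small_hyper, mode)
        assert np.allclose(beta, expected)

    def test_shape_mismatch_rejected(self, small_table, small_hyper):
        with pytest.raises(BMDDError):
            update_beta(small_table, np.zeros((2, 2)), small_hyper)


class TestComputeH:
    def test_equal_modes_give_equal_branches(self):
        hyper = Hyperparams(
            pi=np.array([0.4, 0.4]),
            alpha0=np.array([1.5, 2.0]),
            alpha1=np.array([1.5, 2.0]),
        )
        h0, h1 = compute_h(np.array([2.0, 3.0]), np.array([0.3, 0.6]), hyper, 0)
        assert h0 == h1

    def test_unit_shape_unit_rest_is_zero(self):
        # alpha = 1 and expected other-taxon mass 1: logG(2) + 0 - logG(1) = 0
        hyper = Hyperparams(
            pi=np.array([0.5, 0.5]),
            alpha0=np.array([1.0, 1.0]),
            alpha1=np.array([1.0, 1.0]),
        )
        h0, h1 = compute_h(np.array([3.0, 4.0]), np.array([0.5, 0.5]), hyper, 0)
        assert h0 == pytest.approx(0.0, abs=1e-14)
        assert h1 == pytest.approx(0.0, abs=1e-14)

    def test_matches_independent_scalar_recomputation(self, rng):
        # re-evaluate the closed form with python math on scalars
        import math

        m = 3
        hyper = Hyperparams(
            pi=rng.uniform(0.2, 0.8, m),
            alpha0=rng.uniform(0.1, 1.0, m),
            alpha1=rng.uniform(2.0, 10.0, m),
        )
        beta_row = rng.uniform(0.5, 10.0, m)
        gamma_row = rng.uniform(0.0, 1.0, m)
        for j in range(m):
            h0, h1 = compute_h(beta_row, gamma_row, hyper, j)
            s = sum(
                gamma_row[k] * hyper.alpha1[k] + (1 - gamma_row[k]) * hyper.alpha0[k]
                for k in range(m)
                if k != j
            )
            from scipy.special import digamma

            t = digamma(beta_row[j]) - digamma(beta_row.sum())
            for a, h in [(hyper.alpha0[j], h0), (hyper.alpha1[j], h1)]:
                ref = math.lgamma(a + s) + (a - 1) * t - math.lgamma(a)
                assert h == pytest.approx(ref, rel=1e-12)

    def test_nonpositive_beta_rejected(self, small_hyper):
        with pytest.raises(BMDDError):
            compute_h(np.array([0.0, 1.0, 1.0]), np.full(3, 0.5), small_hyper, 0)


class TestUpdateGamma:
    def test_equal_modes_return_pi(self, small_table):
        alpha = np.array([1.0, 2.0, 3.0])
        hyper = Hyperparams(pi=np.array([0.2, 0.5, 0.8]), alpha0=alpha, alpha1=alpha)
        _, state = init_params(small_table)
        gamma = update_gamma(small_table, state, hyper)
        assert np.allclose(gamma, hyper.pi)

    def test_near_degenerate_prior_pins_gamma(self, small_table):
        # prior log-odds dominate when the two modes are close
        a0 = np.array([0.5, 1.0, 2.0])
        hyper = Hyperparams(pi=np.full(3, 1 - 1e-10), alpha0=a0, alpha1=1.05 * a0)
        _, state = init_params(small_table)
        gamma = update_gamma(small_table, state, hyper)
        assert np.all(gamma > 1 - 1e-4)

    def test_matches_bruteforce_fixed_point(self):
        table, hyper = random_instance(seed=9, n=3, m=3, depth=100)
        _, state = init_params(table)
        gamma = update_gamma(table, state, hyper, inner_tol=1e-13, max_sweeps=5000)
        # brute-force scalar fixed-point iteration from the same start
        bf = state.gamma.copy()
        for _ in range(10000):
            prev = bf.copy()
            for i in range(table.n_samples):
                for j in range(table.n_taxa):
                    h0, h1 = compute_h(state.beta[i], bf[i], hyper, j)
                    bf[i, j] = expit(logit(hyper.pi[j]) + h1 - h0)
            if np.abs(bf - prev).max() < 1e-14:
                break
        assert np.abs(gamma - bf).max() < 1e-10


class TestEStep:
    def test_equal_modes_conjugate_beta(self, small_table):
        alpha = np.array([1.0, 0.5, 2.0])
        hyper = Hyperparams(pi=np.array([0.5] * 3), alpha0=alpha, alpha1=alpha)
        _, state = init_params(small_table)
        state = e_step(small_table, state, hyper)
        assert np.allclose(state.beta, small_table.counts + alpha)

    @pytest.mark.parametrize("seed", range(6))
    def test_surrogate_elbo_never_decreases(self, seed):
        table, hyper = random_instance(seed)
        _, state = init_params(table)
        before = elbo_surrogate(table, state, hyper)
        after = elbo_surrogate(table, e_step(table, state, hyper), hyper)
        assert after >= before - 1e-8 * abs(before)

    def test_coupling_invariant(self):
        table, hyper = random_instance(seed=3)
        _, state = init_params(table)
        state = e_step(table, state, hyper)
        expected = (
            table.counts
            + state.gamma * hyper.alpha1
            + (1 - state.gamma) * hyper.alpha0
        )
        assert np.abs(state.beta - expected).max() < 1e-10

    def test_fixed_point_independent_of_start(self):
        table, hyper = random_instance(seed=11, n=5, m=4)
        _, state = init_params(table)
        alt = VariationalState(beta=state.beta, gamma=np.full_like(state.gamma, 0.5))
        s1 = e_step(table, state, hyper, inner_tol=1e-10, max_sweeps=500)
        s2 = e_step(table, alt, hyper, inner_tol=1e-10, max_sweeps=500)
        assert np.abs(s1.gamma - s2.gamma).max() < 1e-6


class TestMStep:
    def test_update_pi_is_clamped_column_mean(self):
        gamma = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        pi = update_pi(gamma, clamp=1e-4)
        assert pi[0] == pytest.approx(0.25)
        assert pi[1] == pytest.approx(0.5)
        assert update_pi(np.zeros((3, 2)))[0] == pytest.approx(1e-4)
        assert np.allclose(update_pi(np.full((5, 2), 0.3)), 0.3)

    def test_ascent_and_ordering(self):
        table, hyper = random_instance(seed=21)
        _, state = init_params(table)
        state = e_step(table, state, hyper)
        f0, _ = alpha_objective(hyper.alpha0, hyper.alpha1, state.beta, state.gamma)
        new_hyper, new_state = m_step(state, hyper)
        f1, _ = alpha_objective(
            new_hyper.alpha0, new_hyper.alpha1, new_state.beta, new_state.gamma
        )
        assert f1 >= f0 - 1e-8 * abs(f0)
        assert np.all(new_hyper.alpha0 <= new_hyper.alpha1)

    def test_delegates_pi_to_column_mean(self):
        table, hyper = random_instance(seed=4)
        _, state = init_params(table)
        state = VariationalState(beta=state.beta, gamma=np.full_like(state.gamma, 0.3))
        new_hyper, _ = m_step(state, hyper)
        # pi may be flipped by the relabeling, but only to 1 - 0.3
        assert np.all(
            np.isclose(new_hyper.pi, 0.3) | np.isclose(new_hyper.pi, 0.7)
        )


class TestAlphaObjective:
    def test_all_gamma_terms_vanish(self):
        # n=1, m=2, gamma=1, beta=(1,1), alpha1=(1,1): F = logG(2) = 0
        value, _ = alpha_objective(
            np.array([0.5, 0.5]),
            np.array([1.0, 1.0]),
            np.array([[1.0, 1.0]]),
            np.array([[1.0, 1.0]]),
        )
        assert value == pytest.approx(0.0, abs=1e-14)

    def test_alpha0_irrelevant_when_gamma_one(self, rng):
        beta = rng.uniform(0.5, 5.0, (3, 4))
        gamma = np.ones((3, 4))
        a1 = rng.uniform(1.0, 5.0, 4)
        v1, _ = alpha_objective(np.full(4, 0.2), a1, beta, gamma)
        v2, _ = alpha_objective(np.full(4, 7.0), a1, beta, gamma)
        assert v1 == pytest.approx(v2, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 4, 3
        beta = rng.uniform(0.5, 10.0, (n, m))
        gamma = rng.uniform(0.0, 1.0, (n, m))
        x = np.concatenate([rng.uniform(0.1, 1.0, m), rng.uniform(1.0, 10.0, m)])
        _, grad = alpha_objective(x[:m], x[m:], beta, gamma)
        eps = 1e-6
        for k in range(2 * m):
            xp, xm = x.copy(), x.copy()
            xp[k] += eps
            xm[k] -= eps
            vp, _ = alpha_objective(xp[:m], xp[m:], beta, gamma)
            vm, _ = alpha_objective(xm[:m], xm[m:], beta, gamma)
            fd = (vp - vm) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_nonpositive_alpha_rejected(self, rng):
        with pytest.raises(BMDDError):
            alpha_objective(
                np.array([0.0, 1.0]), np.array([1.0, 1.0]),
                np.ones((2, 2)), np.full((2, 2), 0.5),
            )


class TestElboSurrogate:
    def test_degenerate_model_equals_dirichlet_multinomial_loglik(self):
        table = CountTable(counts=np.array([[1, 1]]))
        alpha = np.array([1.0, 1.0])
        hyper = Hyperparams(pi=np.array([0.5, 0.5]), alpha0=alpha, alpha1=alpha)
        state = VariationalState(
            beta=table.counts + alpha, gamma=np.array([[0.5, 0.5]])
        )
        assert elbo_surrogate(table, state, hyper) == pytest.approx(
            np.log(1 / 3), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_lower_bounds_enumerated_log_marginal(self, seed):
        table, hyper = random_instance(seed, m=4)
        _, state = init_params(table)
        state = e_step(table, state, hyper)
        assert elbo_surrogate(table, state, hyper) <= exact_log_marginal(table, hyper)


class TestFit:
    def test_trace_monotone_and_deterministic(self):
        table, _ = random_instance(seed=13, n=8, m=5)
        r1 = fit(table)
        r2 = fit(table)
        assert np.array_equal(r1.elbo_trace, r2.elbo_trace)
        diffs = np.diff(r1.elbo_trace)
        assert np.all(diffs >= -1e-8 * np.abs(r1.elbo_trace[:-1]))

    def test_single_sample_rejected(self):
        with pytest.raises(BMDDError):
            fit(CountTable(counts=np.array([[3, 4, 5]])))

    def test_all_zero_taxon_retained(self):
        counts = np.array([[5, 0, 3], [2, 0, 6], [7, 0, 1], [1, 0, 4]])
        result = fit(CountTable(counts=counts))
        comp = posterior_mean(result.state)
        assert comp.values.shape == (4, 3)
        assert np.all(comp.values[:, 1] > 0)  # prior-driven, not dropped

    def test_single_mode_truth_collapses_mixture(self):
        # When every sample comes from the low mode, the high mode is
        # unobserved: the identifiable outcome is a collapsed mixture
        # (alpha1 close to alpha0) whose effective prior shape
        # pi*alpha1 + (1-pi)*alpha0 tracks the true single mode.
        m = 8
        rng = np.random.default_rng(2)
        hyper = Hyperparams(
            pi=np.full(m, 1e-3),
            alpha0=rng.uniform(0.2, 0.5, m),
            alpha1=rng.uniform(10.0, 30.0, m),
        )
        truth, _ = make_bmdd_truth(n=200, m=m, depth=5000, seed=2, hyper=hyper)
        h = fit(truth.table).hyperparams
        rel_sep = (h.alpha1 - h.alpha0) / h.alpha1
        assert rel_sep.mean() < 0.3
        abar = h.pi * h.alpha1 + (1 - h.pi) * h.alpha0
        assert np.mean(np.abs(abar - hyper.alpha0) / hyper.alpha0) < 0.2


class TestPosteriorOutputs:
    def test_posterior_mean_is_dirichlet_mean(self):
        state = VariationalState(
            beta=np.array([[2.0, 3.0, 5.0]]), gamma=np.full((1, 3), 0.5)
        )
        assert np.allclose(posterior_mean(state).values, [[0.2, 0.3, 0.5]])

    def test_conjugate_posterior_mean(self):
        table = CountTable(counts=np.array([[3, 7], [3, 7]]))
        alpha = np.array([1.0, 1.0])
        hyper = Hyperparams(pi=np.array([0.5, 0.5]), alpha0=alpha, alpha1=alpha)
        _, state = init_params(table)
        state = e_step(table, state, hyper)
        assert np.allclose(
            posterior_mean(state).values, [[4 / 12, 8 / 12]] * 2, atol=1e-15
        )

    def test_sampling_mean_converges_and_is_reproducible(self):
        state = VariationalState(
            beta=np.array([[2.0, 3.0, 5.0]]), gamma=np.full((1, 3), 0.5)
        )
        draws = posterior_sample(state, 10_000, seed=42)
        again = posterior_sample(state, 10_000, seed=42)
        assert np.array_equal(draws[0].values, again[0].values)
        stacked = np.stack([d.values[0] for d in draws])
        assert np.all(stacked > 0) and np.all(stacked < 1)
        mean = stacked.mean(axis=0)
        # Dirichlet(2,3,5): var_j = m_j(1-m_j)/11
        m_true = np.array([0.2, 0.3, 0.5])
        se = np.sqrt(m_true * (1 - m_true) / 11 / 10_000)
        assert np.all(np.abs(mean - m_true) < 3.5 * se)

    def test_sample_count_validated(self):
        state = VariationalState(beta=np.ones((1, 2)), gamma=np.full((1, 2), 0.5))
        with pytest.raises(BMDDError):
            posterior_sample(state, 0)


class TestExactPosteriorMean:
    def test_equal_modes_reduce_to_conjugate_mean(self, rng):
        alpha = rng.uniform(0.5, 3.0, 4)
        hyper = Hyperparams(pi=rng.uniform(0.1, 0.9, 4), alpha0=alpha, alpha1=alpha)
        w = np.array([3.0, 0.0, 5.0, 1.0])
        expected = (w + alpha) / (w.sum() + alpha.sum())
        assert np.allclose(exact_posterior_mean(w, hyper), expected, atol=1e-12)

    def test_vanishing_pi_reduces_to_low_mode(self):
        hyper = Hyperparams(
            pi=np.full(3, 1e-12),
            alpha0=np.array([0.5, 1.0, 1.5]),
            alpha1=np.array([5.0, 6.0, 7.0]),
        )
        w = np.array([2.0, 3.0, 4.0])
        expected = (w + hyper.alpha0) / (w.sum() + hyper.alpha0.sum())
        assert np.allclose(exact_posterior_mean(w, hyper), expected, atol=1e-9)

    def test_matches_scipy_mixture_and_quadrature(self):
        rng = np.random.default_rng(5)
        hyper = Hyperparams(
            pi=rng.uniform(0.2, 0.8, 3),
            alpha0=rng.uniform(1.0, 2.0, 3),
            alpha1=rng.uniform(3.0, 6.0, 3),
        )
        w = np.array([4.0, 2.0, 1.0])
        result = exact_posterior_mean(w, hyper)

        # independent route 1: scipy's Dirichlet-multinomial mixture
        tot, mean = 0.0, np.zeros(3)
        for d in range(8):
            mask = np.array([(d >> k) & 1 for k in range(3)], bool)
            a = np.where(mask, hyper.alpha1, hyper.alpha0)
            weight = np.prod(np.where(mask, hyper.pi, 1 - hyper.pi)) * np.exp(
                stats.dirichlet_multinomial(a, 7).logpmf(w)
            )
            tot += weight
            mean += weight * (w + a) / (7 + a.sum())
        assert np.allclose(result, mean / tot, atol=1e-13)

        # independent route 2: numerical integration over the simplex
        def moment(f):
            def integrand(x2, x1):
                x3 = 1 - x1 - x2
                if x3 <= 0:
                    return 0.0
                x = np.array([x1, x2, x3])
                prior = sum(
                    np.prod(
                        np.where(
                            np.array([(d >> k) & 1 for k in range(3)], bool),
                            hyper.pi,
                            1 - hyper.pi,
                        )
                    )
                    * stats.dirichlet(
                        np.where(
                            np.array([(d >> k) & 1 for k in range(3)], bool),
                            hyper.alpha1,
                            hyper.alpha0,
                        )
                    ).pdf(x)
                    for d in range(8)
                )
                return f(x) * np.prod(x**w) * prior

            return integrate.dblquad(
                integrand, 0, 1, 0, lambda x1: 1 - x1, epsabs=1e-12, epsrel=1e-12
            )[0]

        Z = moment(lambda x: 1.0)
        quad = np.array([moment(lambda x, k=k: x[k]) for k in range(3)]) / Z
        assert np.abs(result - quad).max() < 1e-8

    def test_refuses_large_m(self):
        m = 16
        hyper = Hyperparams(
            pi=np.full(m, 0.5), alpha0=np.full(m, 0.5), alpha1=np.full(m, 2.0)
        )
        with pytest.raises(BMDDError):
            exact_posterior_mean(np.ones(m), hyper)
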