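"""MML-EM fitting and EAP scoring: recovery, ascent, oracles, degeneracies."""

import numpy as np
import pytest

from grmsim import (
    DegenerateItemError,
    ItemBank,
    eap_scores,
    em_fit,
    generate_item_bank,
    make_quadrature,
    simulate_responses,
)


def _simulate(bank, n, seed):
    rng = np.random.default_rng(seed)
    thetas = rng.standard_normal(n)
    return thetas, simulate_responses(thetas, bank, rng)


def _eap_bruteforce(pattern, a1, d, n_nodes=10_001, half_width=6.0):
    """Independent dense-grid EAP: plain loops, own logistic, own prior."""
    grid = np.linspace(-half_width, half_width, n_nodes)
    prior = np.exp(-0.5 * grid**2)
    like = np.ones_like(grid)
    K = d.shape[1] + 1
    for j, cat in enumerate(pattern):
        pstar = np.concatenate(
            [np.ones((n_nodes, 1)),
             1.0 / (1.0 + np.exp(-(a1[j] * grid[:, None] + d[j][None, :]))),
             np.zeros((n_nodes, 1))],
            axis=1,
        )
        like *= pstar[:, cat] - pstar[:, cat + 1]
    post = prior * like
    return float((grid * post).sum() / post.sum())


class TestQuadrature:
    def test_weights_and_symmetry(self):
        q = make_quadrature(61, 6.0)
        assert q.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(q.nodes, -q.nodes[::-1])
        assert np.allclose(q.weights, q.weights[::-1])

    def test_prior_moments(self):
        q = make_quadrature(61, 6.0)
        mean = (q.nodes * q.weights).sum()
        var = (q.nodes**2 * q.weights).sum()
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert var == pytest.approx(1.0, abs=1e-3)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            make_quadrature(5)
        with pytest.raises(ValueError):
            make_quadrature(61, -1.0)


class TestEmFit:
    def test_large_n_recovery(self):
        # consistency of marginal ML: at n = 5000 the slope estimates sit
        # close to the generating values
        rng = np.random.default_rng(11)
        bank = generate_item_bank(10, 5, rng)
        _, resp = _simulate(bank, 5000, 12)
        fit = em_fit(resp, 5)
        assert fit.converged
        assert np.mean(np.abs(fit.a_hat - bank.a)) < 0.1

    def test_loglik_trace_nondecreasing(self, tiny_population):
        rng = tiny_population.condition.rng(0)
        from grmsim import draw_sample

        sample = draw_sample(tiny_population, rng)
        fit = em_fit(sample.responses, tiny_population.condition.K)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-8 * np.abs(fit.loglik_trace[:-1])).all()

    def test_em_ascent_on_random_instances(self):
        # the EM ascent property on 100 random small problems
        master = np.random.default_rng(99)
        for i in range(100):
            bank = generate_item_bank(3, 3, master)
            _, resp = _simulate(bank, 80, 1000 + i)
            if any(len(np.unique(resp[:, j])) < 2 for j in range(3)):
                continue  # degenerate draw; the error path has its own test
            fit = em_fit(resp, 3, max_cycles=15)
            diffs = np.diff(fit.loglik_trace)
            assert (diffs >= -1e-8 * np.abs(fit.loglik_trace[:-1])).all()

    def test_rmse_decreases_with_n(self):
        rng = np.random.default_rng(21)
        bank = generate_item_bank(10, 5, rng)
        rmses = []
        for n, seed in [(1000, 31), (4000, 32), (16000, 33)]:
            _, resp = _simulate(bank, n, seed)
            fit = em_fit(resp, 5)
            rmses.append(np.sqrt(np.mean((fit.a_hat - bank.a) ** 2)))
        assert rmses[1] < rmses[0] + 0.01
        assert rmses[2] < rmses[1] + 0.01

    def test_category_reversal_antisymmetry(self):
        # appending the category-reversed mirror of every response makes the
        # data reversal-invariant, so fitted locations must be antisymmetric
        bank = ItemBank(
            a=np.array([1.0, 1.5, 2.0]),
            b=np.array([[-1.2, 0.0, 1.2], [-0.8, 0.0, 0.8], [-1.5, 0.0, 1.5]]),
        )
        _, resp = _simulate(bank, 400, 17)
        augmented = np.vstack([resp, bank.K - 1 - resp])
        fit = em_fit(augmented, bank.K)
        assert np.allclose(fit.b_hat, -fit.b_hat[:, ::-1], atol=0.02)

    def test_degenerate_item_named(self):
        resp = np.zeros((60, 2), dtype=int)
        resp[:, 0] = np.tile([0, 1, 2], 20)
        resp[:, 1] = 2
        with pytest.raises(DegenerateItemError, match="item 1"):
            em_fit(resp, 3)

    def test_nonconvergence_is_flag_not_exception(self, tiny_population):
        from grmsim import draw_sample

        sample = draw_sample(tiny_population, tiny_population.condition.rng(1))
        fit = em_fit(sample.responses, tiny_population.condition.K, max_cycles=2)
        assert not fit.converged
        assert fit.n_cycles == 2

    def test_input_validation(self):
        with pytest.raises(ValueError, match="respondents"):
            em_fit(np.zeros((10, 3), dtype=int), 3)
        bad = np.zeros((60, 3), dtype=int)
        bad[0, 0] = 7
        with pytest.raises(ValueError, match="0..2"):
            em_fit(bad, 3)

    def test_fitted_locations_ascending(self):
        rng = np.random.default_rng(5)
        bank = generate_item_bank(6, 6, rng)
        _, resp = _simulate(bank, 600, 6)
        fit = em_fit(resp, 6)
        assert (np.diff(fit.b_hat, axis=1) >= 0).all()
        assert (fit.a1_hat > 0).all()

    def test_simulating_from_fit_reproduces_marginals(self):
        # scale round-trip: data simulated from the fitted bank has category
        # marginal frequencies matching the original within Monte Carlo error
        rng = np.random.default_rng(77)
        bank = generate_item_bank(5, 4, rng)
        n = 2000
        _, resp = _simulate(bank, n, 78)
        fit = em_fit(resp, 4)
        refit_bank = ItemBank.from_intercepts(fit.a_hat, fit.d_hat, D=fit.D)
        _, resp2 = _simulate(refit_bank, n, 79)
        for j in range(bank.J):
            f1 = np.bincount(resp[:, j], minlength=4) / n
            f2 = np.bincount(resp2[:, j], minlength=4) / n
            se = np.sqrt(2 * f1 * (1 - f1) / n)
            assert (np.abs(f1 - f2) <= 3 * se + 2e-2).all()


class TestEapScores:
    def test_information_free_items_give_prior_mean(self):
        resp = np.random.default_rng(0).integers(0, 3, size=(20, 4))
        a1 = np.zeros(4)
        d = np.tile([0.5, -0.5], (4, 1))
        eap, psd = eap_scores(resp, a1, d, make_quadrature())
        assert np.allclose(eap, 0.0, atol=1e-12)
        assert np.allclose(psd, 1.0, atol=1e-3)

    def test_reversed_pattern_flips_sign(self, symmetric_item):
        bank = ItemBank(
            a=np.array([1.2, 0.9]), b=np.array([[-1.0, 0.0, 1.0], [-0.5, 0.0, 0.5]])
        )
        quad = make_quadrature()
        patterns = np.array([[0, 1], [3, 2], [1, 3]])
        reversed_patterns = bank.K - 1 - patterns
        eap_f, _ = eap_scores(patterns, bank.a1, bank.d, quad)
        eap_r, _ = eap_scores(reversed_patterns, bank.a1, bank.d, quad)
        assert np.allclose(eap_f, -eap_r, atol=1e-10)

    def test_matches_dense_grid_oracle(self, rng):
        a1 = rng.uniform(0.5, 2.5, 6)
        d = -np.sort(rng.uniform(-2.5, 2.5, (6, 3)), axis=1)[:, ::-1] * 1.0
        d = np.sort(d, axis=1)[:, ::-1]  # strictly descending intercepts
        patterns = rng.integers(0, 4, size=(5, 6))
        eap, _ = eap_scores(patterns, a1, d, make_quadrature(61, 6.0))
        for i, pattern in enumerate(patterns):
            oracle = _eap_bruteforce(pattern, a1, d)
            assert eap[i] == pytest.approx(oracle, abs=1e-3)

    def test_eap_shrinkage(self, tiny_population):
        from grmsim import draw_sample

        cond = tiny_population.condition
        for rep in range(3):
            sample = draw_sample(tiny_population, cond.rng(rep))
            fit = em_fit(sample.responses, cond.K)
            assert fit.theta_eap.var() < sample.theta_true.var()
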