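"""Response-model primitives: boundary curves, category probabilities, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grmsim import ItemBank, category_probs, cumulative_prob, simulate_responses
from grmsim.grm_model import boundary_probs, probs_from_boundaries

# independently evaluated logistic value for logit argument 1.701
EXPIT_1701 = 0.8456652955393212


class TestCumulativeProb:
    def test_half_probability_at_location(self):
        for a, D in [(0.7, 1.0), (1.3, 1.701), (2.5, 1.701)]:
            assert cumulative_prob(0.4, a, 0.4, D) == pytest.approx(0.5)

    def test_limits_and_monotonicity(self):
        assert cumulative_prob(60.0, 1.0, 0.0) == pytest.approx(1.0)
        assert cumulative_prob(-60.0, 1.0, 0.0) == pytest.approx(0.0, abs=1e-12)
        grid = np.linspace(-4, 4, 41)
        vals = cumulative_prob(grid, 1.3, 0.2)
        assert (np.diff(vals) > 0).all()
        # decreasing in the location
        assert cumulative_prob(0.0, 1.3, -0.5) > cumulative_prob(0.0, 1.3, 0.5)

    def test_reference_value(self):
        assert cumulative_prob(1.0, 1.0, 0.0, 1.701) == pytest.approx(EXPIT_1701, abs=1e-15)

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            cumulative_prob(bad, 1.0, 0.0)
        with pytest.raises(ValueError):
            cumulative_prob(0.0, bad, 0.0)


class TestCategoryProbs:
    def test_sums_to_one_and_nonnegative(self, rng):
        for _ in range(200):
            a = rng.uniform(0.5, 2.5)
            b = np.sort(rng.uniform(-2, 2, size=4))
            theta = rng.normal()
            p = category_probs(theta, a, b)
            assert p.shape == (5,)
            assert (p >= 0).all()
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_binary_reduction_is_2pl(self):
        # K = 2: probabilities are (1 - P*, P*) with the boundary curve itself
        theta, a, b = 0.3, 1.4, np.array([0.1])
        p = category_probs(theta, a, b, slope_rescaled=True)
        pstar = cumulative_prob(theta, a, b[0])
        assert p == pytest.approx([1 - pstar, pstar])

    def test_symmetric_item_at_zero(self):
        # a=1, D=1.701, b=(-1,0,1), theta=0: symmetry of the logistic forces
        # P_1 = P_4 and P_2 = P_3 (values frozen from direct evaluation)
        p = category_probs(0.0, 1.0, [-1.0, 0.0, 1.0], slope_rescaled=True)
        assert p == pytest.approx(
            [0.15433470446067876, 0.34566529553932124, 0.34566529553932124, 0.15433470446067876]
        )
        # the same reversal symmetry holds under the unrescaled convention
        p2 = category_probs(0.0, 1.0, [-1.0, 0.0, 1.0], slope_rescaled=False)
        assert p2 == pytest.approx(p2[::-1])

    def test_non_ascending_locations_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            category_probs(0.0, 1.0, [0.5, -0.5])

    @settings(max_examples=50, deadline=None)
    @given(
        theta=st.floats(-4, 4),
        a=st.floats(0.5, 2.5),
        rescaled=st.booleans(),
        data=st.data(),
    )
    def test_cumulative_structure_monotone(self, theta, a, rescaled, data):
        # boundary probabilities are nonincreasing across ascending locations
        b = np.sort(data.draw(st.lists(st.floats(-2, 2), min_size=3, max_size=6)))
        a1 = 1.701 * a if rescaled else a
        d = -1.701 * a * np.asarray(b)
        pstar = boundary_probs(theta, np.array([a1]), d[None, :])[0, 0]
        assert (np.diff(pstar) <= 1e-15).all()


class TestItemBank:
    def test_intercept_identity_and_roundtrip(self, rng):
        a = rng.uniform(0.5, 2.5, 6)
        b = np.sort(rng.uniform(-2, 2, (6, 3)), axis=1)
        bank = ItemBank(a=a, b=b)
        assert np.allclose(bank.d + bank.D * a[:, None] * b, 0.0, atol=1e-12)
        back = ItemBank.from_intercepts(bank.a, bank.d, D=bank.D)
        assert np.allclose(back.b, b, atol=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="ascending"):
            ItemBank(a=[1.0], b=[[0.5, -0.5]])
        with pytest.raises(ValueError, match="positive"):
            ItemBank(a=[-1.0], b=[[0.0]])
        with pytest.raises(ValueError, match="D"):
            ItemBank(a=[1.0], b=[[0.0]], D=-2.0)

    def test_csv_roundtrip(self, small_bank, tmp_path):
        path = tmp_path / "bank.csv"
        small_bank.to_csv(path)
        back = ItemBank.from_csv(path)
        assert np.allclose(back.a, small_bank.a)
        assert np.allclose(back.b, small_bank.b)
        assert np.allclose(back.d, small_bank.d)


class TestSimulateResponses:
    def test_extreme_theta_hits_top_category(self, small_bank, rng):
        resp = simulate_responses(np.full(20, 10.0), small_bank, rng)
        assert (resp == small_bank.K - 1).all()
        resp = simulate_responses(np.full(20, -10.0), small_bank, rng)
        assert (resp == 0).all()

    def test_reproducible_with_same_seed(self, small_bank):
        thetas = np.linspace(-2, 2, 50)
        r1 = simulate_responses(thetas, small_bank, np.random.default_rng(5))
        r2 = simulate_responses(thetas, small_bank, np.random.default_rng(5))
        assert (r1 == r2).all()

    def test_empty_thetas_rejected(self, small_bank, rng):
        with pytest.raises(ValueError):
            simulate_responses(np.array([]), small_bank, rng)

    def test_frequencies_match_analytic_probs(self, rng):
        # 50,000 draws at theta = 0 for one item vs the analytic category
        # probabilities, within 3 binomial standard errors
        bank = ItemBank(a=np.array([1.5]), b=np.array([[-1.0, 0.2, 0.9]]))
        n = 50_000
        resp = simulate_responses(np.zeros(n), bank, rng)[:, 0]
        expected = category_probs(0.0, bank.a[0], bank.b[0], slope_rescaled=bank.slope_rescaled)
        freq = np.bincount(resp, minlength=bank.K) / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(freq - expected) < 3 * se + 1e-9).all()

    def test_expected_category_nondecreasing_in_theta(self, small_bank):
        grid = np.linspace(-3, 3, 25)
        pstar = boundary_probs(grid, small_bank.a1, small_bank.d)
        probs = probs_from_boundaries(pstar)  # (J, T, K)
        expected = (probs * np.arange(small_bank.K)).sum(axis=2)
        assert (np.diff(expected, axis=1) >= -1e-12).all()
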