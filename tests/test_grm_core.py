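"""Core graded-response-model mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gafscore.bank import ItemParameters
from gafscore.grm import (
    category_probabilities,
    cumulative_probabilities,
    expected_item_score,
    expected_test_score,
    item_information,
    loading_to_slope,
    modal_category_set,
    slope_to_loading,
)
from gafscore.grm import test_information as total_information


def random_item(rng):
    a = rng.uniform(0.3, 3.0)
    d1 = rng.uniform(0.5, 3.5)
    gaps = rng.uniform(0.3, 2.5, size=3)
    d = d1 - np.concatenate([[0.0], np.cumsum(gaps)])
    return ItemParameters("r", a, tuple(d))


class TestCumulativeProbabilities:
    def test_logistic_midpoint(self):
        item = ItemParameters("x", 2.0, (1.0, 0.0, -1.0))
        # a*theta + d_2 = 0 at theta = 0 for the middle boundary
        assert cumulative_probabilities(item, 0.0)[1] == pytest.approx(0.5)

    def test_low_theta_limit(self, item1):
        assert np.all(cumulative_probabilities(item1, -40.0) < 1e-12)

    def test_item1_at_zero(self, item1):
        # direct logistic evaluation of the published item 1 parameters
        expected = [0.956562, 0.334256, 0.060654, 0.001768]
        np.testing.assert_allclose(
            cumulative_probabilities(item1, 0.0), expected, atol=5e-5
        )

    def test_non_increasing_in_k(self, bank):
        theta = np.linspace(-8, 8, 41)
        for item in bank:
            ps = cumulative_probabilities(item, theta)
            assert np.all(np.diff(ps, axis=-1) <= 0)

    def test_rejects_nonfinite_theta(self, item1):
        with pytest.raises(ValueError):
            cumulative_probabilities(item1, np.nan)


class TestCategoryProbabilities:
    def test_simplex_on_published_bank(self, bank):
        theta = np.linspace(-8, 8, 101)
        for item in bank:
            p = category_probabilities(item, theta)
            assert np.all(p >= 0)
            np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)

    def test_high_theta_limit(self, item1):
        p = category_probabilities(item1, 40.0)
        assert p[-1] == pytest.approx(1.0, abs=1e-12)

    def test_item1_at_zero(self, item1):
        expected = [0.043438, 0.622306, 0.273602, 0.058886, 0.001768]
        np.testing.assert_allclose(
            category_probabilities(item1, 0.0), expected, atol=5e-5
        )

    @settings(max_examples=30, deadline=None)
    @given(theta=st.floats(-8, 8), seed=st.integers(0, 10_000))
    def test_simplex_property(self, theta, seed):
        item = random_item(np.random.default_rng(seed))
        p = category_probabilities(item, theta)
        assert np.all(p >= -1e-15)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestExpectedScores:
    def test_extreme_theta_saturates_test_score(self, bank):
        assert expected_test_score(bank, 40.0) == pytest.approx(40.0, abs=1e-9)
        assert expected_test_score(bank, -40.0) == pytest.approx(8.0, abs=1e-9)

    def test_flat_item_constant(self, flat_item):
        es = expected_item_score(flat_item, np.linspace(-5, 5, 11))
        assert np.ptp(es) < 1e-12

    def test_monotone_in_theta(self, bank):
        theta = np.linspace(-6, 6, 241)
        es = expected_test_score(bank, theta)
        assert np.all(np.diff(es) >= 0)

    def test_matches_bruteforce_summation(self, bank):
        # independent oracle: sum_k k P(k) item by item via raw logistics
        theta = 0.0
        total = 0.0
        for item in bank:
            ps = 1 / (1 + np.exp(-(item.a * theta + np.asarray(item.d))))
            full = np.concatenate([[1.0], ps, [0.0]])
            p = full[:-1] - full[1:]
            total += sum((k + 1) * p[k] for k in range(5))
        assert expected_test_score(bank, theta) == pytest.approx(total, abs=1e-12)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            expected_test_score([], 0.0)


class TestInformation:
    def test_zero_slope_zero_information(self, flat_item):
        info = item_information(flat_item, np.linspace(-6, 6, 25))
        np.testing.assert_allclose(info, 0.0, atol=1e-15)

    def test_additivity(self, bank):
        theta = np.linspace(-6, 6, 50)
        total = total_information(bank, theta)
        summed = sum(item_information(it, theta) for it in bank)
        np.testing.assert_allclose(total, summed, rtol=1e-12)

    def test_against_finite_difference_oracle(self, bank):
        # I(theta) = sum_k P'(k)^2 / P(k) with P' from central differences
        h = 1e-6
        for item in bank[:3]:
            for theta in (-2.0, 0.0, 1.5):
                p = category_probabilities(item, theta)
                dp = (
                    category_probabilities(item, theta + h)
                    - category_probabilities(item, theta - h)
                ) / (2 * h)
                oracle = np.sum(dp**2 / p)
                assert item_information(item, theta) == pytest.approx(
                    oracle, abs=1e-6
                )

    def test_nonnegative_everywhere(self, bank):
        theta = np.linspace(-8, 8, 161)
        assert np.all(total_information(bank, theta) >= 0)

    def test_matches_score_function_variance(self, item1):
        # I(theta) equals the conditional variance of d/dtheta log P(X)
        theta = 0.7
        h = 1e-6
        p = category_probabilities(item1, theta)
        dlogp = (
            np.log(category_probabilities(item1, theta + h))
            - np.log(category_probabilities(item1, theta - h))
        ) / (2 * h)
        var = np.sum(p * dlogp**2) - np.sum(p * dlogp) ** 2
        assert item_information(item1, theta) == pytest.approx(var, abs=1e-5)


class TestLoadingConversion:
    @pytest.mark.parametrize(
        "a, lam",
        [(2.802, 0.855), (1.235, 0.587)],  # published items 1 and 12
    )
    def test_published_loadings(self, a, lam):
        assert slope_to_loading(a).lam == pytest.approx(lam, abs=5e-4)

    def test_zero_slope(self):
        rec = slope_to_loading(0.0)
        assert rec.lam == 0.0 and rec.h2 == 0.0

    def test_full_bank_loadings_to_3dp(self, bank):
        # published loadings; the slopes themselves are printed to 3 d.p.,
        # so agreement is to within one unit in the third decimal
        published = [0.855, 0.790, 0.808, 0.816, 0.740, 0.587, 0.743, 0.671]
        for item, lam in zip(bank, published):
            rec = slope_to_loading(item.a)
            assert rec.lam == pytest.approx(lam, abs=1e-3)
            assert rec.h2 == pytest.approx(rec.lam**2, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(-10, 10))
    def test_roundtrip_identity(self, a):
        lam = slope_to_loading(a).lam
        assert loading_to_slope(lam) == pytest.approx(a, abs=1e-10)

    def test_inverse_rejects_unit_loading(self):
        with pytest.raises(ValueError):
            loading_to_slope(1.0)


class TestModalCategories:
    def test_binary_item_both_modal(self):
        item = ItemParameters("b", 1.5, (0.3,))
        assert modal_category_set(item) == {1, 2}

    def test_published_middle_category_census(self, bank):
        # items 11, 12, 14 never have a modal middle category
        missing_middle = {
            it.label for it in bank if 3 not in modal_category_set(it)
        }
        assert missing_middle == {11, 12, 14}

    def test_wide_item_all_modal(self):
        item = ItemParameters("wide", 2.0, (6.0, 2.0, -2.0, -6.0))
        assert modal_category_set(item) == {1, 2, 3, 4, 5}

    def test_requires_wide_grid(self, item1):
        with pytest.raises(ValueError):
            modal_category_set(item1, np.linspace(-2, 2, 100))
        with pytest.raises(ValueError):
            modal_category_set(item1, [])


class TestItemParameters:
    def test_rejects_unordered_intercepts(self):
        with pytest.raises(ValueError):
            ItemParameters("bad", 1.0, (0.0, 1.0))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            ItemParameters("bad", np.inf, (1.0, 0.0))

    def test_category_count(self, item1):
        assert item1.K == 5
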