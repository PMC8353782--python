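"""Wald DIF machinery: FDR, effect sizes, and the iterative procedure."""

import numpy as np
import pytest

from gafscore.bank import ItemParameters, LatentDist, gafs8_bank
from gafscore.dif import (
    bh_fdr,
    essd,
    etssd,
    iterative_wald_dif,
    subgroup_dif_scan,
    uetsds,
    wabc,
)
from gafscore.simulate import (
    DIFShift,
    default_two_group_config,
    simulate_responses,
)


def shifted(item, delta):
    return ItemParameters(item.label, item.a, tuple(np.asarray(item.d) + delta))


class TestBhFdr:
    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_matches_bruteforce_stepup(self):
        p = np.array([0.01, 0.02, 0.03, 0.20])
        # brute-force step-up: adj_i = min over j >= i of m * p_(j) / j
        order = np.argsort(p)
        m = p.size
        sorted_adj = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(sorted_adj, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])


class TestWabc:
    def test_identical_items_zero(self, item1):
        assert wabc(item1, item1, LatentDist(1, 1.2)) == 0.0

    def test_monotone_in_shift(self, item1):
        focal = LatentDist(1.0, 1.17)
        vals = [wabc(item1, shifted(item1, d), focal) for d in (0.2, 0.5, 1.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_matches_numeric_integration_oracle(self, item1):
        from scipy.integrate import quad
        from gafscore.grm import expected_item_score
        from scipy.stats import norm

        focal = LatentDist(0.8, 1.1)
        item_f = shifted(item1, 0.5)

        def integrand(t):
            diff = expected_item_score(item1, t) - expected_item_score(item_f, t)
            return abs(diff) * norm.pdf(t, focal.mu, focal.sigma)

        oracle, _ = quad(integrand, -8, 10, limit=200)
        assert wabc(item1, item_f, focal) == pytest.approx(oracle, abs=1e-3)

    def test_symmetric_in_group_roles(self, item1):
        focal = LatentDist(0.5, 1.0)
        item_f = shifted(item1, 0.7)
        assert wabc(item1, item_f, focal) == pytest.approx(
            wabc(item_f, item1, focal)
        )

    def test_mismatched_categories_rejected(self, item1):
        other = ItemParameters("k3", 1.0, (1.0, -1.0))
        with pytest.raises(ValueError):
            wabc(item1, other, LatentDist(0, 1))


class TestEssd:
    def test_identical_zero(self, item1, bank):
        focal = LatentDist(1, 1.17)
        assert essd(item1, item1, focal) == 0.0
        assert etssd(bank, bank, focal) == 0.0
        assert uetsds(bank, bank, np.linspace(-2, 2, 50)) == 0.0

    def test_easier_focal_items_positive(self, item1):
        focal = LatentDist(1, 1.17)
        assert essd(item1, shifted(item1, 0.5), focal) > 0

    def test_location_shift_invariance(self, bank):
        # shifting both groups' trait scale leaves effect sizes unchanged
        focal_a = LatentDist(0.0, 1.1)
        focal_b = LatentDist(1.0, 1.1)
        bank_f = [shifted(it, 0.4) for it in bank]
        shifted_ref = [
            ItemParameters(it.label, it.a, tuple(np.asarray(it.d) - it.a * 1.0))
            for it in bank
        ]
        shifted_foc = [
            ItemParameters(it.label, it.a, tuple(np.asarray(it.d) - it.a * 1.0))
            for it in bank_f
        ]
        assert etssd(bank, bank_f, focal_a) == pytest.approx(
            etssd(shifted_ref, shifted_foc, focal_b), abs=1e-6
        )

    def test_two_item_monte_carlo_oracle(self):
        # simulate a large focal sample and score both parameterizations
        from gafscore.grm import category_probabilities

        bank_r = gafs8_bank()[:2]
        bank_f = [shifted(it, 0.6) for it in bank_r]
        focal = LatentDist(0.5, 1.0)
        rng = np.random.default_rng(77)
        theta = rng.normal(focal.mu, focal.sigma, 1_000_000)

        def draw_scores(bank):
            total = np.zeros(theta.size)
            for it in bank:
                p = category_probabilities(it, theta)
                u = rng.random(theta.size)
                total += (u[:, None] < np.cumsum(p, axis=1)).argmax(axis=1) + 1
            return total

        s_r = draw_scores(bank_r)
        s_f = draw_scores(bank_f)
        mc = (s_f.mean() - s_r.mean()) / np.sqrt((s_r.var() + s_f.var()) / 2)
        assert etssd(bank_r, bank_f, focal) == pytest.approx(mc, abs=2e-3)

    def test_zero_pooled_sd_rejected(self):
        flat = ItemParameters("f", 0.0, (400.0, 300.0, 200.0, 100.0))
        # degenerate: probability mass entirely in the top category
        with pytest.raises(ValueError):
            essd(flat, flat, LatentDist(0, 1))


class TestIterativeWald:
    def test_planted_dif_flagged(self):
        cfg = default_two_group_config(
            n_norm=500, n_clin=500, seed=55,
            dif_spec={(9, "clinical"): DIFShift(d_shift=1.0)},
        )
        rm = simulate_responses(cfg)
        res = iterative_wald_dif(rm, reference="normative", tol=3e-4,
                                 n_quadrature=41)
        flagged = {it.item for it in res.items if it.flagged}
        assert 9 in flagged
        by_item = {it.item: it for it in res.items}
        assert by_item[9].wabc == max(it.wabc for it in res.items)
        assert by_item[9].essd > 0  # easier in the focal group
        assert 9 not in res.anchors
        assert by_item[9].flagged_params  # follow-up tests localized it

    def test_anchors_exclude_flagged_only(self, two_group_sample):
        res = iterative_wald_dif(two_group_sample, reference="normative",
                                 tol=3e-4, n_quadrature=41)
        flagged = {it.item for it in res.items if it.flagged}
        assert set(res.anchors) == set(two_group_sample.items) - flagged
        for it in res.items:
            assert it.flagged == (it.p_fdr < 0.05)
            assert it.wabc >= 0
        assert res.n_iterations <= 10

    def test_requires_two_groups(self, normative_sample):
        with pytest.raises(ValueError):
            iterative_wald_dif(normative_sample)


class TestSubgroupScan:
    def test_random_split_not_practically_significant(self, two_group_sample):
        rng = np.random.default_rng(123)
        labels = rng.integers(0, 2, two_group_sample.n)
        table = subgroup_dif_scan(
            two_group_sample, {"random": labels}, tol=3e-4, n_quadrature=41
        )
        assert not table["practically_significant"].iloc[0]

    def test_degenerate_partition_rejected(self, two_group_sample):
        with pytest.raises(ValueError):
            subgroup_dif_scan(
                two_group_sample, {"allsame": np.zeros(two_group_sample.n)}
            )
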