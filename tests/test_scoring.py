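"""GAFS-8 scoring: MAP/EAP estimators, reliability, classical composites."""

import numpy as np
import pandas as pd
import pytest

from gafscore.bank import GAFS8_ITEMS, ItemParameters, LatentDist
from gafscore.scoring import (
    CLINICAL_PRIOR,
    GAFS8Scorer,
    classical_scores,
    conditional_reliability,
    reliability_bounds,
    score_eap,
    score_map,
    score_range,
)


def flat_bank():
    return [
        ItemParameters(i, 0.0, (2.0, 0.5, -0.5, -2.0)) for i in GAFS8_ITEMS
    ]


class TestScoreMap:
    def test_flat_bank_returns_prior_mean(self):
        prior = LatentDist(0.4, 1.0)
        r = score_map({i: 3 for i in GAFS8_ITEMS}, flat_bank(), prior)
        assert r.theta == pytest.approx(0.4, abs=1e-4)

    def test_monotone_in_responses(self, bank):
        base = {i: 3 for i in GAFS8_ITEMS}
        t0 = score_map(base, bank).theta
        for item in GAFS8_ITEMS:
            up = dict(base)
            up[item] = 4
            assert score_map(up, bank).theta >= t0 - 1e-9

    def test_extremes_bound_all_patterns(self, bank):
        lo, hi = score_range(bank)
        rng = np.random.default_rng(0)
        for _ in range(20):
            resp = {i: int(c) for i, c in zip(GAFS8_ITEMS, rng.integers(1, 6, 8))}
            t = score_map(resp, bank).theta
            assert lo - 1e-6 <= t <= hi + 1e-6

    def test_published_extremes_under_clinical_prior(self, bank):
        # the published score range (all-lowest / all-highest patterns) is
        # referenced to the clinical calibration group's latent density
        lo, hi = score_range(bank, CLINICAL_PRIOR)
        assert lo == pytest.approx(-2.19, abs=0.05)
        assert hi == pytest.approx(3.52, abs=0.05)

    def test_t_score_affine_identity(self, bank):
        r = score_map({i: 4 for i in GAFS8_ITEMS}, bank)
        assert r.t_score == pytest.approx(50 + 10 * r.theta, abs=1e-12)

    def test_missing_items_dropped(self, bank):
        r = score_map({1: 5, 2: 5, 6: 5}, bank)
        assert r.n_items_used == 3

    def test_all_missing_rejected(self, bank):
        with pytest.raises(ValueError):
            score_map({}, bank)

    def test_out_of_range_category_names_item(self, bank):
        with pytest.raises(ValueError, match="12"):
            score_map({i: (7 if i == 12 else 3) for i in GAFS8_ITEMS}, bank)

    def test_zero_based_coding_shim(self, bank):
        a = score_map({i: 0 for i in GAFS8_ITEMS}, bank).theta
        b = score_map({i: 1 for i in GAFS8_ITEMS}, bank).theta
        assert a == pytest.approx(b, abs=1e-9)

    def test_simulation_recovers_trait_ordering(self, bank):
        # scores should track the generating trait strongly (the published
        # marginal reliability is ~0.9)
        from gafscore.simulate import default_two_group_config, simulate_responses

        cfg = default_two_group_config(n_norm=1000, n_clin=1000, seed=99)
        rm, theta = simulate_responses(cfg, return_theta=True)
        est = [
            score_map(dict(zip(rm.items, row)), bank).theta
            for row in rm.values
        ]
        assert np.corrcoef(theta, est)[0, 1] > 0.9


class TestScoreEap:
    def test_flat_bank_exact_prior_mean(self):
        prior = LatentDist(-0.7, 1.0)
        r = score_eap({i: 2 for i in GAFS8_ITEMS}, flat_bank(), prior)
        assert r.theta == pytest.approx(-0.7, abs=1e-9)

    def test_matches_dense_grid_oracle(self, bank):
        resp = {1: 4, 2: 3, 6: 5, 9: 2, 11: 4, 12: 3, 13: 4, 14: 5}
        r = score_eap(resp, bank, n_quadrature=201)
        # brute-force posterior on a 100k-point grid
        grid = np.linspace(-8, 8, 100_001)
        lw = -0.5 * grid**2
        for item in bank:
            ps = 1 / (1 + np.exp(-(item.a * grid[:, None] + np.asarray(item.d))))
            full = np.concatenate(
                [np.ones((grid.size, 1)), ps, np.zeros((grid.size, 1))], axis=1
            )
            p = full[:, :-1] - full[:, 1:]
            lw += np.log(p[:, resp[item.label] - 1])
        w = np.exp(lw - lw.max())
        w /= w.sum()
        oracle = np.sum(grid * w)
        assert r.theta == pytest.approx(oracle, abs=1e-4)

    def test_mirrored_bank_symmetry(self):
        items = [
            ItemParameters("p", 1.5, (1.0, -1.0)),
            ItemParameters("q", 1.5, (1.0, -1.0)),
        ]
        hi = score_eap({"p": 3, "q": 1}, items, LatentDist(0, 1))
        lo = score_eap({"p": 1, "q": 3}, items, LatentDist(0, 1))
        assert hi.theta == pytest.approx(-lo.theta + 0.0, abs=1e-9)

    def test_close_to_map_for_informative_pattern(self, bank):
        resp = {i: 4 for i in GAFS8_ITEMS}
        assert abs(
            score_eap(resp, bank).theta - score_map(resp, bank).theta
        ) < 0.1


class TestConditionalReliability:
    def test_zero_information_zero_reliability(self):
        assert conditional_reliability(0.0, flat_bank()) == pytest.approx(0.0)

    def test_published_score_range_is_reliable(self, bank):
        theta = np.linspace(-2.19, 3.52, 101)
        assert np.all(conditional_reliability(theta, bank) >= 0.7)

    def test_published_crossing_points(self, bank):
        lo, hi = reliability_bounds(0.7, bank)
        assert lo == pytest.approx(-2.43, abs=0.05)
        assert hi == pytest.approx(3.53, abs=0.05)


class TestClassicalScores:
    def test_all_threes_prorated(self):
        cs = classical_scores({i: 3 for i in range(1, 21)})
        assert cs.prorated_total == pytest.approx(60.0)
        assert not cs.high_alexithymia

    def test_cutoff_boundary(self):
        # total of exactly 61 flags high alexithymia
        resp = {i: 3 for i in range(1, 21)}
        resp[1] = 4  # 61 after reverse keying
        cs = classical_scores(resp)
        assert cs.tas20_total == 61
        assert cs.high_alexithymia

    def test_all_ones_with_reverse_keying(self):
        cs = classical_scores({i: 1 for i in range(1, 21)})
        assert cs.tas20_total == 15 * 1 + 5 * 5

    def test_sixteen_item_prorating(self):
        resp = {i: 2 for i in range(1, 17)}
        cs = classical_scores(resp)
        assert cs.tas20_total is None
        # items 4, 5, 10 reverse to 4; mean = (13*2 + 3*4)/16
        assert cs.prorated_total == pytest.approx((13 * 2 + 3 * 4) / 16 * 20)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            classical_scores({i: 3 for i in range(1, 11)})


class TestGAFS8Scorer:
    def test_transform_dataframe(self):
        df = pd.DataFrame(
            {f"tas{i:02d}": [3, 5] for i in GAFS8_ITEMS}
        )
        out = GAFS8Scorer().fit().transform(df)
        assert list(out.columns[:4]) == ["theta", "se", "reliability", "t_score"]
        assert out.loc[1, "theta"] > out.loc[0, "theta"]
        assert out["complete"].all()

    def test_transform_array_matches_function(self, bank):
        X = np.array([[3, 3, 3, 3, 3, 3, 3, 3]])
        out = GAFS8Scorer().fit().transform(X)
        direct = score_map(dict(zip(GAFS8_ITEMS, X[0])), bank)
        assert out.loc[0, "theta"] == pytest.approx(direct.theta, abs=1e-9)

    def test_sklearn_param_interface(self):
        s = GAFS8Scorer(method="EAP")
        assert s.get_params()["method"] == "EAP"
        s.set_params(method="MAP")
        assert s.method == "MAP"
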