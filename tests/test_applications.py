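import numpy as np
import pytest

import lw25
from lw25.applications import CutScores, _band_volume, classify_regions, hdr


class TestClassifyRegions:
    def test_rows_sum_to_one_both_modes(self, sixitem_combos):
        cuts = {0: CutScores((-1.0, 0.5)), "xi": CutScores((0.0,))}
        for mode in ("quadrature", "normal"):
            df = classify_regions(sixitem_combos, cuts, mode=mode)
            two = df[df["dim"] == "0"][["region0", "region1", "region2"]]
            assert np.allclose(two.sum(axis=1), 1.0, atol=1e-10)
            one = df[df["dim"] == "xi"][["region0", "region1"]]
            assert np.allclose(one.sum(axis=1), 1.0, atol=1e-10)

    def test_far_cut_puts_all_mass_on_one_side(self, sixitem_combos):
        with pytest.warns(UserWarning, match="outside grid range"):
            df = classify_regions(sixitem_combos, {0: CutScores((-100.0,))})
        assert np.allclose(df["region0"], 0.0)
        assert np.allclose(df["region1"], 1.0)

    def test_region_mass_shifts_upward_with_score(self, sixitem_combos):
        """At fixed rest score, a higher cluster score moves primary mass
        out of the bottom region."""
        df = classify_regions(sixitem_combos, {0: CutScores((0.0,))})
        for sr in range(5):
            low = [
                float(df[(df.s_n == s1) & (df.s_rest == sr)]["region0"].iloc[0])
                for s1 in range(3)
            ]
            assert np.all(np.diff(low) < 0)

    def test_normal_mode_vs_monte_carlo(self, sixitem_combos):
        cp = sixitem_combos[(1, 2)]
        cuts = CutScores((-0.5, 0.5))
        df = classify_regions(
            lw25.ComboTable(1, [cp], M=1), {0: cuts}, mode="normal"
        )
        probs = df[["region0", "region1", "region2"]].to_numpy()[0]
        rng = np.random.default_rng(55)
        draws = lw25.normal_approx(cp).sample(1_000_000, rng)[:, 0]
        for k, (lo, hi) in enumerate([(-np.inf, -0.5), (-0.5, 0.5), (0.5, np.inf)]):
            phat = np.mean((draws > lo) & (draws <= hi))
            se = np.sqrt(phat * (1 - phat) / len(draws))
            assert abs(probs[k] - phat) < 3 * se


class TestScoreProbabilities:
    def test_marginals_sum_to_one(self, sixitem_combos):
        for side, n in (("focal", 3), ("rest", 5)):
            total = sum(
                lw25.marginal_score_prob(sixitem_combos, side, s) for s in range(n)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_focal_marginal_matches_single_cluster_model(self, sixitem, demo_grid):
        """With conditionally independent clusters, the focal-score marginal
        equals the total-score distribution of the focal cluster alone."""
        ct = lw25.combo_posteriors(sixitem.model, 1, demo_grid)
        solo = lw25.TwoTierModel(
            items=sixitem.model.cluster_items(1), M=1, N=sixitem.model.N
        )
        tps = lw25.lw20_posteriors(solo, demo_grid)
        for s in range(3):
            assert lw25.marginal_score_prob(ct, "focal", s) == pytest.approx(
                tps[s].prob, abs=1e-10
            )

    def test_percentile_hand_computed_table(self):
        joint = np.array([[0.1, 0.2, 0.1], [0.05, 0.15, 0.1], [0.1, 0.1, 0.1]])
        got = lw25.conditional_percentile(joint, given=1, at=1)
        assert got == pytest.approx(100 * (0.05 + 0.15) / 0.30)
        lt = lw25.conditional_percentile(joint, given=1, at=1, rule="lt")
        assert lt == pytest.approx(100 * 0.05 / 0.30)
        mid = lw25.conditional_percentile(joint, given=1, at=1, rule="midpoint")
        assert mid == pytest.approx(100 * (0.05 + 0.075) / 0.30)

    def test_percentile_reaches_100_at_max_score(self, sixitem_combos):
        assert lw25.conditional_percentile(sixitem_combos, 1, 4) == pytest.approx(100.0)

    def test_percentile_monotone_in_at(self, sixitem_combos):
        vals = [lw25.conditional_percentile(sixitem_combos, 1, a) for a in range(5)]
        assert np.all(np.diff(vals) >= 0)

    def test_zero_marginal_raises(self):
        joint = np.array([[0.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="zero marginal"):
            lw25.conditional_percentile(joint, given=0, at=1)


def _fake_combo(s_n, s_rest, prob, mu0, mu_n, var=1e-4):
    return lw25.ComboPosterior(
        focal=1, score=s_n, rest_score=s_rest, prob=prob, weights=None,
        eta_grid=None, xi_grid=None,
        mu=np.array([mu0, mu_n]), sigma=np.eye(2) * var,
    )


class TestSubscoreScreen:
    def test_near_collinear_tight_posteriors_fill_band(self):
        """Combos hugging a line, with posteriors far tighter than the
        residual scatter: the band contains essentially all their mass."""
        combos = []
        for k, (a, b) in enumerate((a, b) for a in range(3) for b in range(3)):
            x = a - b
            wiggle = 0.05 if k % 2 == 0 else -0.05
            combos.append(_fake_combo(a, b, 1 / 9, x, 0.5 + 2 * x + wiggle, var=1e-6))
        ct = lw25.ComboTable(focal=1, combos=combos, M=1)
        band, df = lw25.subscore_screen(ct, level=0.95)
        assert band.slope == pytest.approx(2.0, abs=0.05)
        assert band.intercept == pytest.approx(0.5, abs=0.05)
        assert np.all(df["volume_in_band"] > 0.99)

    def test_discordant_combos_have_smallest_volume(self, sixitem_combos):
        """The least-covered combination is an extreme discordant score
        pair, not a concordant one."""
        _, df = lw25.subscore_screen(sixitem_combos, level=0.95)
        worst = df.loc[df["volume_in_band"].idxmin()]
        assert (worst["s_n"], worst["s_rest"]) in {(2, 0), (0, 4)}
        assert df["volume_in_band"].between(0, 1).all()

    def test_volume_monotone_in_level(self, sixitem_combos):
        frames = [
            lw25.subscore_screen(sixitem_combos, level=lv)[1] for lv in (0.5, 0.8, 0.95)
        ]
        v = np.stack([f["volume_in_band"].to_numpy() for f in frames])
        assert np.all(np.diff(v, axis=0) >= -1e-12)

    def test_volume_vs_monte_carlo(self, sixitem_combos):
        band, df = lw25.subscore_screen(sixitem_combos, level=0.95)
        cp = sixitem_combos[(2, 0)]
        vol = float(
            df[(df.s_n == 2) & (df.s_rest == 0)]["volume_in_band"].iloc[0]
        )
        rng = np.random.default_rng(99)
        draws = lw25.normal_approx(cp).sample(1_000_000, rng)
        inside = (draws[:, 1] >= band.lower(draws[:, 0])) & (
            draws[:, 1] <= band.upper(draws[:, 0])
        )
        phat = inside.mean()
        se = np.sqrt(phat * (1 - phat) / len(draws))
        assert abs(vol - phat) < 3 * se + 1e-3  # 1e-3 midpoint-rule allowance

    def test_degenerate_regression_rejected(self):
        combos = [_fake_combo(i, 0, 1 / 3, 0.0, float(i)) for i in range(3)]
        with pytest.raises(ValueError, match="degenerate regression"):
            lw25.subscore_screen(lw25.ComboTable(1, combos, M=1))


class TestHDR:
    def test_exact_cumulative_hit(self):
        joint = np.array([[0.5, 0.3], [0.15, 0.05]])
        res = hdr(joint, alpha=0.95)
        assert res.included.shape[0] == 3
        assert res.coverage == pytest.approx(0.95)
        assert tuple(res.excluded[["s_n", "s_rest"]].iloc[0]) == (1, 1)

    def test_uniform_probabilities(self):
        joint = np.full((4, 5), 1 / 20)
        res = hdr(joint, alpha=0.95)
        assert res.included.shape[0] == int(np.ceil(0.95 * 20))

    def test_nesting(self, sixitem_combos):
        r95 = hdr(sixitem_combos, 0.95)
        r99 = hdr(sixitem_combos, 0.99)
        in95 = set(map(tuple, r95.included[["s_n", "s_rest"]].values))
        in99 = set(map(tuple, r99.included[["s_n", "s_rest"]].values))
        assert in95 <= in99

    def test_minimal_top_probability_set(self, sixitem_combos):
        """The included set is the smallest top-probability set reaching
        alpha: dropping its last member falls below coverage."""
        res = hdr(sixitem_combos, 0.95)
        probs = np.sort(sixitem_combos.prob_matrix.ravel())[::-1]
        k = res.included.shape[0]
        assert probs[:k].sum() >= 0.95 - 1e-12
        assert probs[: k - 1].sum() < 0.95
        assert res.included["prob"].min() >= res.excluded["prob"].max() - 1e-15
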