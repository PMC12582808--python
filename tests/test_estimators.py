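"""Univariable estimators against hand arithmetic and independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from medmr.estimators import (
    MREstimate,
    _mode_point,
    _ratios_and_weights,
    _weighted_median,
    ivw,
    mode_estimate,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from conftest import make_hset, random_hset


class TestWaldRatio:
    def test_hand_arithmetic(self):
        e = wald_ratio(0.5, 0.25, 0.1)
        assert (e.beta, e.se) == pytest.approx((0.5, 0.2))

    def test_null_effect_has_p_one(self):
        e = wald_ratio(1.0, 0.0, 1.0)
        assert e.beta == 0 and e.pval == pytest.approx(1.0)

    def test_sign_propagation(self):
        e = wald_ratio(-1.0, 0.3, 0.1)
        assert (e.beta, e.se) == pytest.approx((-0.3, 0.1))

    def test_zero_exposure_effect_is_undefined(self):
        with pytest.raises(ValueError, match="undefined ratio"):
            wald_ratio(0.0, 0.1, 0.1)


class TestIVW:
    def test_identical_ratios(self):
        h = make_hset([1, 1], [2, 2], [1, 1])
        e = ivw(h, "fixed")
        assert e.beta == pytest.approx(2.0)
        assert e.se == pytest.approx(1 / np.sqrt(2))

    def test_closed_form_two_snps(self):
        h = make_hset([1, 2], [1, 4], [1, 1])
        assert ivw(h, "fixed").beta == pytest.approx(1.8)

    def test_random_effects_floor_at_fixed(self):
        # exact proportionality: Q = 0 <= df, so no inflation
        h = make_hset([1, 2, 3], [0.5, 1.0, 1.5], [1, 1, 1])
        assert ivw(h, "random").se == pytest.approx(ivw(h, "fixed").se)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_statsmodels_wls_through_origin(self, seed):
        h = random_hset(np.random.default_rng(seed), n=int(5 + seed % 9))
        w = 1 / h.se_out**2
        fit = sm.WLS(h.beta_out, h.beta_exp, weights=w).fit()
        fixed = ivw(h, "fixed")
        assert fixed.beta == pytest.approx(fit.params[0], abs=1e-12)
        assert fixed.se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale), rel=1e-10)
        rand = ivw(h, "random")
        assert rand.se == pytest.approx(fixed.se * max(1, np.sqrt(fit.scale)), rel=1e-10)

    def test_all_zero_exposure_effects_error(self):
        with pytest.raises(ValueError, match="no instrument signal"):
            ivw(make_hset([0, 0], [1, 1], [1, 1]))

    def test_requires_two_snps(self):
        with pytest.raises(ValueError):
            ivw(make_hset([1], [1], [1]))


class TestMREgger:
    def test_noiseless_line_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(bx, 0.02 + 0.5 * bx, np.full(4, 0.05))
        fit = mr_egger(h)
        assert fit.intercept == pytest.approx(0.02, abs=1e-12)
        assert fit.slope.beta == pytest.approx(0.5, abs=1e-12)

    def test_no_pleiotropy_gives_zero_intercept(self):
        bx = np.array([0.1, 0.25, 0.4])
        h = make_hset(bx, 0.5 * bx, np.full(3, 0.05))
        fit = mr_egger(h)
        assert fit.intercept == pytest.approx(0.0, abs=1e-14)
        assert fit.intercept_p == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_weighted_least_squares_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 10
        bx = rng.normal(0.15, 0.05, n)
        sy = rng.uniform(0.01, 0.05, n)
        by = 0.05 + 0.4 * bx + rng.normal(0, 1, n) * sy  # directional pleiotropy
        h = make_hset(bx, by, sy)
        fit = mr_egger(h)
        sign = np.where(bx < 0, -1, 1)
        X = sm.add_constant(bx * sign)
        ref = sm.WLS(by * sign, X, weights=1 / sy**2).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert fit.slope.beta == pytest.approx(ref.params[1], abs=1e-10)
        adj = np.sqrt(max(1, ref.scale) / ref.scale)
        assert fit.slope.se == pytest.approx(ref.bse[1] * adj, rel=1e-10)
        assert fit.intercept_se == pytest.approx(ref.bse[0] * adj, rel=1e-10)
        # p-values from t with n - 2 df
        tval = fit.slope.beta / fit.slope.se
        assert fit.slope.pval == pytest.approx(2 * stats.t.sf(abs(tval), n - 2))

    def test_collinear_design_rejected(self):
        h = make_hset([0.2, 0.2, -0.2], [0.1, 0.12, -0.09], [0.05, 0.05, 0.05])
        with pytest.raises(ValueError, match="collinear"):
            mr_egger(h)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            mr_egger(make_hset([1, 2], [1, 2], [1, 1]))


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        h = make_hset([1, 1, 1], [1, 2, 5], [1, 1, 1])
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(2.0)

    def test_dominant_weight_returns_its_ratio(self):
        # weights 0.2 / 0.6 / 0.2: cumulative midpoint of the heavy SNP is 0.5
        sy = np.array([1.0, 1.0, 1.0])
        bx = np.array([np.sqrt(0.2), np.sqrt(0.6), np.sqrt(0.2)])
        by = np.array([1.0, 3.0, 10.0]) * bx  # ratios 1, 3, 10
        h = make_hset(bx, by, sy)
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_interpolation_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        h = random_hset(rng, n=7)
        r, w = _ratios_and_weights(h)

        def oracle(ratios, weights):
            order = np.argsort(ratios)
            r_s, w_s = np.array(ratios)[order], np.array(weights)[order]
            w_s = w_s / w_s.sum()
            cum = 0.0
            mids = []
            for wi in w_s:
                mids.append(cum + wi / 2)
                cum += wi
            for i in range(len(mids) - 1):
                if mids[i] <= 0.5 <= mids[i + 1]:
                    frac = (0.5 - mids[i]) / (mids[i + 1] - mids[i])
                    return r_s[i] + frac * (r_s[i + 1] - r_s[i])
            return r_s[0] if 0.5 < mids[0] else r_s[-1]

        est = weighted_median(h, n_boot=50, seed=seed)
        assert est.beta == pytest.approx(oracle(r, w), abs=1e-12)

    def test_bootstrap_se_deterministic_given_seed(self):
        h = random_hset(np.random.default_rng(42), n=6)
        a = weighted_median(h, n_boot=200, seed=9)
        b = weighted_median(h, n_boot=200, seed=9)
        assert a.se == b.se


class TestModeEstimate:
    def test_majority_cluster_dominates_simple_mode(self):
        h = make_hset([1, 1, 1, 1], [1.0, 1.0, 1.0, 9.0], [1, 1, 1, 1])
        e = mode_estimate(h, weighted=False, n_boot=50, seed=1)
        assert e.beta == pytest.approx(1.0)

    def test_identical_ratios_return_common_value(self):
        h = make_hset([1, 2, 4], [1.5, 3.0, 6.0], [1, 1, 1])
        e = mode_estimate(h, weighted=True, n_boot=50, seed=1)
        assert e.beta == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_finer_grid_argmax_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        # two ratio clusters of unequal mass
        bx = np.abs(rng.normal(0.2, 0.03, 9))
        ratios = np.concatenate([rng.normal(1.0, 0.05, 6), rng.normal(3.0, 0.05, 3)])
        sy = rng.uniform(0.02, 0.06, 9)
        h = make_hset(bx, ratios * bx, sy)
        r, w = _ratios_and_weights(h, weighted=True)
        est = mode_estimate(h, weighted=True, n_boot=50, seed=seed).beta

        # oracle: same kernel density evaluated on a 10x finer grid
        wn = w / w.sum()
        s = 1.4826 * np.median(np.abs(r - np.median(r)))
        bw = 1.06 * s * len(r) ** -0.2
        m = np.mean(r)
        lo, hi = min(m - 4 * s, r.min()), max(m + 4 * s, r.max())
        fine = np.linspace(lo, hi, 5120)
        dens = np.sum(wn * np.exp(-0.5 * ((fine[:, None] - r) / bw) ** 2), axis=1)
        oracle = fine[np.argmax(dens)]
        assert abs(est - oracle) <= (hi - lo) / 511

    def test_phi_scales_bandwidth(self):
        r = np.array([1.0, 1.1, 2.9, 3.0, 3.1])
        w = np.ones(5)
        narrow = _mode_point(r, w, phi=0.5)
        assert 2.8 < narrow < 3.2  # larger cluster wins at any sane bandwidth
        assert 2.8 < _mode_point(r, w, phi=1.0) < 3.2


class TestEstimatorInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_exposure_sign_flip_leaves_estimates_unchanged(self, seed):
        rng = np.random.default_rng(400 + seed)
        h = random_hset(rng, n=8)
        flipped = make_hset(-h.beta_exp, -h.beta_out, h.se_out, sx=h.se_exp)
        assert ivw(h, "random").beta == pytest.approx(ivw(flipped, "random").beta)
        assert mr_egger(h).slope.beta == pytest.approx(mr_egger(flipped).slope.beta)
        assert weighted_median(h, 50, seed=1).beta == pytest.approx(
            weighted_median(flipped, 50, seed=1).beta
        )
        assert mode_estimate(h, seed=1, n_boot=50).beta == pytest.approx(
            mode_estimate(flipped, seed=1, n_boot=50).beta
        )

    def test_point_estimates_unbiased_on_valid_instruments(self):
        """All five estimators center on the true effect without pleiotropy."""
        true = 0.3
        rng = np.random.default_rng(77)
        est = {k: [] for k in ("ivw", "egger", "wm", "sm", "wmode")}
        for _ in range(500):
            # strong instruments: exposure measurement error negligible
            bx = rng.normal(0.15, 0.05, 12)
            bx[np.abs(bx) < 0.02] = 0.05
            sy = rng.uniform(0.005, 0.02, 12)
            by = true * bx + rng.normal(0, 1, 12) * sy
            h = make_hset(bx, by, sy, sx=np.full(12, 0.002))
            est["ivw"].append(ivw(h, "random").beta)
            est["egger"].append(mr_egger(h).slope.beta)
            r, w = _ratios_and_weights(h)
            est["wm"].append(_weighted_median(r, w))
            est["sm"].append(_mode_point(r, np.ones_like(r), 1.0))
            est["wmode"].append(_mode_point(r, w, 1.0))
        for k, v in est.items():
            v = np.asarray(v)
            mc = 4 * v.std() / np.sqrt(len(v))
            assert abs(v.mean() - true) < max(mc, 0.02), k

    def test_weighted_median_robust_to_minority_directional_pleiotropy(self):
        """Valid majority weight: median bias well below IVW bias."""
        rng = np.random.default_rng(88)
        true, shift = 0.2, 0.5
        wm_est, ivw_est = [], []
        for _ in range(200):
            bx = rng.normal(0.2, 0.02, 10)
            sy = np.full(10, 0.01)
            by = true * bx + rng.normal(0, 1, 10) * sy
            by[7:] += shift * bx[7:]  # 3 of 10 invalid, same direction
            h = make_hset(bx, by, sy)
            r, w = _ratios_and_weights(h)
            wm_est.append(_weighted_median(r, w))
            ivw_est.append(ivw(h, "fixed").beta)
        wm_bias = abs(np.mean(wm_est) - true)
        ivw_bias = abs(np.mean(ivw_est) - true)
        assert wm_bias < ivw_bias / 3


class TestOddsRatioView:
    def test_null_effect_symmetric_interval(self):
        orv = to_odds_ratio(MREstimate("ivw_fixed", 0.0, 0.1, 1.0, 2))
        assert orv.or_point == pytest.approx(1.0)
        assert orv.ci_low * orv.ci_high == pytest.approx(1.0)

    def test_reproduces_published_style_interval(self):
        orv = to_odds_ratio(MREstimate("ivw_random", -0.106264, 0.048846, 0.0296, 10))
        assert orv.or_point == pytest.approx(0.899187, rel=2e-6)
        assert orv.ci_low == pytest.approx(0.817092, rel=2e-6)
        assert orv.ci_high == pytest.approx(0.989530, rel=2e-6)

    def test_alternative_level_uses_exact_quantile(self):
        e = MREstimate("ivw_fixed", 0.1, 0.05, 0.5, 2)
        orv = to_odds_ratio(e, level=0.9)
        z = stats.norm.ppf(0.95)
        assert orv.ci_low == pytest.approx(np.exp(0.1 - z * 0.05))
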