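"""Estimator correctness against closed-form and brute-force oracles."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import special, stats

from tscmr import (
    InputError,
    RatioInput,
    cochran_q,
    egger,
    estimate_all,
    f_statistic,
    ivw,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from tscmr.mr_estimators import _mode_bandwidth


def ri(b_gx, b_gy, se_gy=0.05, se_gx=0.01, snp_id=""):
    return RatioInput(b_gx=b_gx, se_gx=se_gx, b_gy=b_gy, se_gy=se_gy,
                      snp_id=snp_id)


class TestWaldRatio:
    def test_hand_arithmetic(self):
        est = wald_ratio(ri(0.1, 0.2, se_gy=0.05))
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)
        assert est.ci_low == pytest.approx(2.0 - 1.959964 * 0.5, abs=1e-5)

    def test_zero_numerator(self):
        assert wald_ratio(ri(0.3, 0.0)).beta == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(InputError):
            wald_ratio(ri(0.0, 0.2))

    @pytest.mark.parametrize("b_gx,b_gy,se_gx,se_gy", [
        (0.1, 0.2, 0.01, 0.05), (-0.3, 0.1, 0.2, 0.02), (2.0, -1.0, 0.5, 0.5),
    ])
    def test_delta_se_never_smaller_than_first_order(self, b_gx, b_gy, se_gx, se_gy):
        r = ri(b_gx, b_gy, se_gy=se_gy, se_gx=se_gx)
        assert wald_ratio(r, "delta").se >= wald_ratio(r, "first_order").se
        assert wald_ratio(r, "delta").beta == wald_ratio(r, "first_order").beta


class TestIVW:
    def test_two_identical_snps_pool_to_single_ratio(self):
        r = ri(0.1, 0.2, se_gy=0.05)
        est = ivw([r, r])
        single = wald_ratio(r)
        assert est.beta == pytest.approx(single.beta)
        assert est.se == pytest.approx(single.se / np.sqrt(2))

    def test_equal_weight_mean(self):
        # same b_gx and se_gy -> equal weights; ratios 2 and 4 -> 3
        est = ivw([ri(0.1, 0.2), ri(0.1, 0.4)])
        assert est.beta == pytest.approx(3.0)

    def test_equals_zero_intercept_weighted_regression(self, ratio_fixture):
        est = ivw(ratio_fixture)
        b_gx = np.array([r.b_gx for r in ratio_fixture])
        b_gy = np.array([r.b_gy for r in ratio_fixture])
        se_gy = np.array([r.se_gy for r in ratio_fixture])
        fit = sm.WLS(b_gy, b_gx[:, None], weights=1 / se_gy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], rel=1e-12)

    def test_lies_within_ratio_range(self, ratio_fixture):
        ratios = [r.b_gy / r.b_gx for r in ratio_fixture]
        assert min(ratios) <= ivw(ratio_fixture).beta <= max(ratios)

    def test_single_snp_rejected(self):
        with pytest.raises(InputError, match="wald_ratio"):
            ivw([ri(0.1, 0.2)])


class TestEgger:
    def test_exact_collinear_fit(self):
        rs = [ri(b, 0.7 * b) for b in (0.1, 0.2, 0.3, 0.4)]
        est = egger(rs)
        assert est.beta == pytest.approx(0.7, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_directional_shift(self):
        rs = [ri(b, 0.7 * b + 0.02) for b in (0.1, 0.25, 0.4)]
        est = egger(rs)
        assert est.beta == pytest.approx(0.7, abs=1e-10)
        assert est.intercept == pytest.approx(0.02, abs=1e-10)

    def test_matches_normal_equations_oracle(self, ratio_fixture):
        est = egger(ratio_fixture)
        b_gx = np.array([abs(r.b_gx) for r in ratio_fixture])
        b_gy = np.array([r.b_gy * np.sign(r.b_gx) for r in ratio_fixture])
        w = 1 / np.array([r.se_gy for r in ratio_fixture]) ** 2
        X = np.column_stack([np.ones_like(b_gx), b_gx])
        XtWX = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(XtWX, X.T @ (w * b_gy))
        assert est.intercept == pytest.approx(coef[0], rel=1e-10, abs=1e-12)
        assert est.beta == pytest.approx(coef[1], rel=1e-10)

    def test_orients_negative_exposure_effects(self):
        rs = [ri(b, 0.7 * b + 0.02 * np.sign(b)) for b in (0.1, -0.25, 0.4)]
        est = egger(rs)
        assert est.beta == pytest.approx(0.7, abs=1e-10)

    def test_needs_three_snps(self):
        with pytest.raises(InputError):
            egger([ri(0.1, 0.2), ri(0.2, 0.3)])


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        rs = [ri(0.1, 0.1 * v) for v in (1.0, 2.0, 9.0)]
        assert weighted_median(rs, seed=1).beta == pytest.approx(2.0)

    def test_dominant_weight_snp_wins(self):
        rs = [ri(0.1, 0.5, se_gy=0.001), ri(0.1, 0.1), ri(0.1, 0.9)]
        assert weighted_median(rs, seed=1).beta == pytest.approx(5.0)

    def test_matches_grid_search_oracle(self, ratio_fixture):
        est = weighted_median(ratio_fixture, seed=1)
        ratios = np.array([r.b_gy / r.b_gx for r in ratio_fixture])
        w = np.array([r.b_gx**2 / r.se_gy**2 for r in ratio_fixture])
        w = w / w.sum()
        order = np.argsort(ratios)
        r_s, w_s = ratios[order], w[order]
        cum = np.cumsum(w_s) - 0.5 * w_s
        grid = np.arange(r_s[0], r_s[-1], 1e-6)
        interp = np.interp(0.5, cum, r_s)
        oracle = grid[np.argmin(np.abs(grid - interp))]
        assert est.beta == pytest.approx(oracle, abs=2e-6)

    def test_needs_three_snps(self):
        with pytest.raises(InputError):
            weighted_median([ri(0.1, 0.2), ri(0.1, 0.3)], seed=1)


class TestWeightedMode:
    def test_identical_ratios_any_bandwidth(self):
        rs = [ri(0.1, 0.25)] * 4
        for bw in (0.5, 1.0, 3.0):
            assert weighted_mode(rs, bandwidth_factor=bw, seed=1).beta == \
                pytest.approx(2.5)

    def test_dominant_cluster_beats_outlier(self):
        rs = [ri(0.1, 0.1 * v) for v in (1.0, 1.01, 0.99, 5.0)]
        assert weighted_mode(rs, seed=1).beta == pytest.approx(1.0, abs=0.02)

    def test_matches_fine_grid_density_argmax(self, ratio_fixture):
        est = weighted_mode(ratio_fixture, seed=1)
        ratios = np.array([r.b_gy / r.b_gx for r in ratio_fixture])
        w = np.array([r.b_gx**2 / r.se_gy**2 for r in ratio_fixture])
        h = _mode_bandwidth(ratios, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 200_001)
        dens = np.zeros_like(grid)
        for rj, wj in zip(ratios, w):
            dens += wj * stats.norm.pdf((grid - rj) / h)
        oracle = grid[np.argmax(dens)]
        assert est.beta == pytest.approx(oracle, abs=5e-4)


class TestCochranQ:
    def test_homogeneous_ratios_give_zero(self):
        rs = [ri(0.1, 0.2), ri(0.2, 0.4), ri(0.4, 0.8)]
        q, df, p = cochran_q(rs)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_snp_value(self):
        # unit weights: b_gx = 1, se_gy = 1; ratios 0 and 2 -> Q = 2, df = 1
        rs = [ri(1.0, 0.0, se_gy=1.0), ri(1.0, 2.0, se_gy=1.0)]
        q, df, p = cochran_q(rs)
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_p_matches_independent_chi_square_tail(self, ratio_fixture):
        q, df, p = cochran_q(ratio_fixture)
        assert p == pytest.approx(float(special.gammaincc(df / 2, q / 2)), rel=1e-12)


class TestFStatistic:
    def test_forced_arithmetic(self):
        assert f_statistic(0.1, 0.05) == pytest.approx(4.0)
        assert f_statistic(0.0, 0.05) == 0.0

    def test_equals_squared_z_of_instrument_p(self):
        from tscmr import SummaryAssociation
        rec = SummaryAssociation("rs1", "A", "G", beta=0.12, se=0.03)
        z = stats.norm.isf(rec.p_value() / 2)
        assert f_statistic(rec.beta, rec.se) == pytest.approx(z**2, rel=1e-6)


class TestSuiteProperties:
    def test_negating_outcomes_negates_estimates(self, ratio_fixture):
        flipped = [dataclasses.replace(r, b_gy=-r.b_gy) for r in ratio_fixture]
        for fwd, rev in zip(estimate_all(ratio_fixture, seed=3),
                            estimate_all(flipped, seed=3)):
            assert rev.beta == pytest.approx(-fwd.beta, rel=1e-9, abs=1e-12)
        assert egger(flipped).intercept == pytest.approx(
            -egger(ratio_fixture).intercept, rel=1e-9)

    def test_single_snp_promotes_to_wald(self):
        (est,) = estimate_all([ri(0.1, 0.2)])
        assert est.method == "wald"
        assert est.beta == pytest.approx(2.0)

    def test_bootstrap_estimators_reproducible(self, ratio_fixture):
        a = weighted_median(ratio_fixture, n_boot=200, seed=9)
        b = weighted_median(ratio_fixture, n_boot=200, seed=9)
        assert a == b
        c = weighted_mode(ratio_fixture, n_boot=200, seed=9)
        d = weighted_mode(ratio_fixture, n_boot=200, seed=9)
        assert c == d
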