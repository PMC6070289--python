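"""Negative-binomial statistical core: normalization, dispersion, Wald
tests, the zero-RPF posterior, and P-value machinery."""

import numpy as np
import pytest
from scipy import stats

from uorfkit.simulate import sample_nb
from uorfkit.te_stats import (
    DispersionTrend,
    ZeroRPFNull,
    bh_fdr,
    concordance_chi2,
    count_based_te,
    estimate_dispersion_trend,
    estimate_log2te_and_se,
    fisher_combine,
    fit_se_surface,
    pooled_zero_rpf,
    prob_zero_rpf,
    size_factors,
    wald_test_beta,
    wald_test_beta_u,
    wald_test_gamma,
)


class TestSizeFactors:
    def test_identical_libraries(self):
        K = np.tile(np.array([[5], [10], [50]]), (1, 3))
        assert np.allclose(size_factors(K), 1.0)

    def test_doubled_library(self):
        K = np.array([[10, 20], [30, 60], [5, 10]])
        assert np.allclose(size_factors(K), [2**-0.5, 2**0.5])

    def test_single_feature_proportional(self):
        K = np.array([[10, 40]])
        sf = size_factors(K)
        assert np.prod(sf) == pytest.approx(1.0)
        assert sf[1] / sf[0] == pytest.approx(4.0)

    def test_no_common_feature_errors(self):
        with pytest.raises(ValueError):
            size_factors(np.array([[0, 5], [5, 0]]))

    def test_matches_external_median_of_ratios(self, rng):
        # independent oracle: the reference RNA-seq normalization routine
        from pydeseq2.preprocessing import deseq2_norm

        K = rng.negative_binomial(5, 0.05, size=(300, 4)).astype(float) + 1
        _, sf_ref = deseq2_norm(K.T)
        ours = size_factors(K)
        assert np.allclose(ours / ours[0], np.asarray(sf_ref) / np.asarray(sf_ref)[0],
                           rtol=1e-6)


class TestDispersionTrend:
    def test_parameter_recovery(self, rng):
        n = 5000
        mu = rng.lognormal(5.0, 1.3, n)
        phi = 0.05 + 5.0 / mu
        K = np.column_stack([sample_nb(rng, mu, phi), sample_nb(rng, mu, phi)])
        trend = estimate_dispersion_trend(K, min_mean=30)
        assert trend.a0 == pytest.approx(0.05, rel=0.2)
        assert trend.a1 == pytest.approx(5.0, rel=0.2)

    def test_poisson_data_gives_near_zero_a0(self, rng):
        mu = np.maximum(rng.lognormal(5.5, 1.0, 3000), 30)
        K = np.column_stack([rng.poisson(mu), rng.poisson(mu)])
        trend = estimate_dispersion_trend(K, min_mean=30)
        assert trend.a0 <= 0.01

    def test_identical_replicates_give_zero_dispersion(self):
        K = np.tile(np.arange(40, 140, dtype=float)[:, None], (1, 2))
        trend = estimate_dispersion_trend(K, min_mean=30)
        assert trend.a0 == pytest.approx(0.0, abs=1e-6)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            estimate_dispersion_trend(np.ones((100, 1)))

    def test_trend_is_monotone_nonincreasing(self):
        trend = DispersionTrend("mrna", 0.05, 5.0)
        mus = np.linspace(1, 1e4, 100)
        vals = trend(mus)
        assert np.all(np.diff(vals) <= 0) and np.all(vals >= 0)


class TestLog2TE:
    def test_equal_counts_give_zero(self, trends):
        res = estimate_log2te_and_se(np.array([[50, 60]]), np.array([[50, 60]]), *trends)
        assert res["log2te"].iloc[0] == pytest.approx(0.0)

    def test_fourfold_rpf_gives_two(self, trends):
        res = estimate_log2te_and_se(np.array([[100, 100]]), np.array([[400, 400]]), *trends)
        assert res["log2te"].iloc[0] == pytest.approx(2.0)

    def test_zero_rows_skipped(self, trends):
        res = estimate_log2te_and_se(np.array([[0, 0]]), np.array([[5, 5]]), *trends)
        assert np.isnan(res["log2te"].iloc[0]) and np.isnan(res["se"].iloc[0])

    @pytest.mark.parametrize("te", [0.25, 1.0, 4.0])
    def test_planted_te_grid_recovery(self, te, trends, rng):
        mu = np.full(2000, 800.0)
        m = sample_nb(rng, mu, trends[0](mu))
        r = sample_nb(rng, mu * te, trends[1](mu * te))
        res = estimate_log2te_and_se(
            np.column_stack([m[:1000], m[1000:]]), np.column_stack([r[:1000], r[1000:]]),
            *trends,
        )
        assert res["log2te"].mean() == pytest.approx(np.log2(te), abs=0.1)


class TestSESurface:
    def test_constant_surface(self, rng):
        lt = rng.uniform(-3, 3, 400)
        c = 10 ** rng.uniform(1.5, 4, 400)
        surf = fit_se_surface(lt, c, np.full(400, 0.3))
        pred, clamped = surf.predict([0.0, -1.0, 2.0], [100, 1000, 5000])
        assert np.allclose(pred, 0.3, atol=0.01)
        assert not clamped.any()

    def test_decreasing_in_count(self, rng):
        lt = rng.uniform(-3, 3, 500)
        c = 10 ** rng.uniform(1.5, 4, 500)
        surf = fit_se_surface(lt, c, 1 / np.sqrt(c))
        grid = [50, 200, 1000, 5000]
        preds = [surf.predict([0.0], [g])[0][0] for g in grid]
        assert all(a > b for a, b in zip(preds, preds[1:]))

    def test_out_of_domain_clamped_and_flagged(self, rng):
        lt = rng.uniform(-1, 1, 200)
        c = 10 ** rng.uniform(2, 3, 200)
        surf = fit_se_surface(lt, c, np.full(200, 0.2))
        pred_out, cl = surf.predict([10.0], [10**6])
        pred_edge, _ = surf.predict([lt.max()], [10 ** 3])
        assert cl.all()
        assert pred_out[0] > 0

    def test_degenerate_domain_errors(self):
        with pytest.raises(ValueError):
            fit_se_surface(np.zeros(200), np.full(200, 100.0), np.full(200, 0.1))

    def test_too_few_features_errors(self):
        with pytest.raises(ValueError):
            fit_se_surface(np.arange(50.0), np.arange(1, 51.0), np.full(50, 0.1))


class TestWaldBeta:
    def test_null_ratio_gives_p_one(self):
        res = wald_test_beta([1.0], [1.0], [0.5], [0.5])
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_quantile_example(self):
        # se = sqrt(0.5^2 + 0.5^2) = 0.7071; log2(beta) = 1.3859 -> z = 1.96
        res = wald_test_beta([1.3859], [0.0], [0.5], [0.5])
        assert res["se"].iloc[0] == pytest.approx(0.7071, rel=1e-4)
        assert res["p"].iloc[0] == pytest.approx(0.050, abs=5e-4)

    def test_null_calibration(self, trends, rng):
        n = 10_000
        mu = np.maximum(rng.lognormal(5.5, 0.8, n), 100)

        def sim():
            m = np.column_stack([sample_nb(rng, mu, trends[0](mu)) for _ in range(2)])
            r = np.column_stack([sample_nb(rng, mu, trends[1](mu)) for _ in range(2)])
            return estimate_log2te_and_se(m, r, *trends)

        u, c = sim(), sim()
        res = wald_test_beta(u["log2te"], c["log2te"], u["se"], c["se"])
        assert 0.04 <= (res["p"] < 0.05).mean() <= 0.06

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test_beta([1.0], [0.0], [0.0], [0.5])


class TestWaldGamma:
    def test_no_change_gives_p_one(self):
        res = wald_test_gamma([0.0], [0.0], [0.0], [0.0], *([[0.5]] * 4))
        assert res["log2_gamma"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_uorf_te_doubling_with_flat_cds(self):
        res = wald_test_gamma([0.0], [0.0], [1.0], [0.0], *([[0.5]] * 4))
        assert res["log2_gamma"].iloc[0] == pytest.approx(-1.0)

    def test_four_se_combination(self):
        res = wald_test_gamma([0.0], [0.0], [0.0], [1.96], *([[0.5]] * 4))
        assert res["se"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] == pytest.approx(0.050, abs=5e-4)

    def test_beta_u_two_term_se(self):
        res = wald_test_beta_u([0.0], [1.3859], [0.5], [0.5])
        assert res["se"].iloc[0] == pytest.approx(0.7071, rel=1e-4)
        assert res["p"].iloc[0] == pytest.approx(0.050, abs=5e-4)


class TestProbZeroRPF:
    def test_null_te_zero_gives_one(self, trends):
        assert prob_zero_rpf(100, ZeroRPFNull.point(0.0), *trends) == 1.0

    def test_point_null_matches_monte_carlo(self, trends, rng):
        # point-mass null: latent mRNA count drawn from NB, then the single
        # NB zero mass (1 + phi_R(xK)*xK)^(-1/phi_R) at x = 0.1
        K_obs, x0 = 200.0, 0.1
        got = prob_zero_rpf(K_obs, ZeroRPFNull.point(x0), *trends)
        n = 400_000
        phi_m = float(trends[0](K_obs))
        K = rng.negative_binomial(1 / phi_m, 1 / (1 + phi_m * K_obs), n)
        m = x0 * K
        pos = m > 0
        phi_r = trends[1](m[pos])
        zeros = np.count_nonzero(
            rng.negative_binomial(1 / phi_r, 1 / (1 + phi_r * m[pos])) == 0
        ) + np.count_nonzero(~pos)
        mc = zeros / n
        se = np.sqrt(mc * (1 - mc) / n)
        assert abs(got - mc) < 3 * se + 1e-12

    def test_monotone_in_mrna_count_and_null_te(self, trends):
        null = ZeroRPFNull.from_cds(np.log2(0.5), 0.3)
        ps = [prob_zero_rpf(k, null, *trends) for k in (30, 100, 300)]
        assert ps[0] > ps[1] > ps[2]
        ps_te = [
            prob_zero_rpf(100, ZeroRPFNull.point(x), *trends) for x in (0.05, 0.1, 0.5)
        ]
        assert ps_te[0] > ps_te[1] > ps_te[2]

    def test_matches_monte_carlo(self, trends, rng):
        null = ZeroRPFNull.from_cds(np.log2(0.8), 0.35)
        K_obs = 60
        p = prob_zero_rpf(K_obs, null, *trends)
        n = 200_000
        x = 2 ** rng.normal(np.log2(0.8), np.sqrt(2) * 0.35, n)
        phi_m = float(trends[0](K_obs))
        K = rng.negative_binomial(1 / phi_m, 1 / (1 + phi_m * K_obs), n)
        m = x * K
        pos = m > 0
        phi_r = trends[1](m[pos])
        R = np.zeros(n)
        R[pos] = rng.negative_binomial(1 / phi_r, 1 / (1 + phi_r * m[pos]))
        mc = (R == 0).mean()
        se = np.sqrt(mc * (1 - mc) / n)
        assert abs(p - mc) < 3 * se + 1e-12

    def test_h0u_requires_two_samples(self):
        with pytest.raises(ValueError):
            ZeroRPFNull.from_other_samples([0.5], se=0.3)

    def test_nonpoint_null_needs_positive_sd(self, trends):
        with pytest.raises(ValueError):
            prob_zero_rpf(100, ZeroRPFNull("c", log2_te=0.0, se=0.0), *trends)

    def test_pooling_decreases_p(self, trends):
        null = ZeroRPFNull.point(0.1)
        single = prob_zero_rpf(50, null, *trends)
        pooled = pooled_zero_rpf([50, 50], null, *trends)
        assert pooled < single
        assert pooled_zero_rpf([50], null, *trends) == pytest.approx(single)


class TestCombinationAndFDR:
    def test_fisher_example(self):
        # X = -2(ln 0.1 + ln 0.1) = 9.2103, chi2 with 4 df
        assert fisher_combine([0.1, 0.1]) == pytest.approx(0.0561, abs=2e-4)

    def test_fisher_all_ones(self):
        assert fisher_combine([1, 1, 1]) == pytest.approx(1.0)

    def test_fisher_single_p_identity(self):
        assert fisher_combine([0.31]) == pytest.approx(0.31)

    def test_fisher_rejects_zero(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])

    def test_bh_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_bh_single_and_all_ones(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_bh_appending_ones_preserves_small_q(self):
        base = bh_fdr([0.001, 0.01, 0.02])
        extended = bh_fdr([0.001, 0.01, 0.02, 1.0, 1.0])
        order_base = np.argsort(base)
        order_ext = np.argsort(extended[:3])
        assert np.array_equal(order_base, order_ext)


class TestConcordanceChi2:
    @pytest.mark.parametrize(
        "inv,conc,expected_p",
        [
            (331 + 33, 0 + 2, 7.5e-80),
            (20 + 1129, 0, 7.4e-252),
            (97 + 3, 0, 1.5e-23),
            (244 + 8, 0, 9.5e-57),
            (10 + 25, 0, 3.3e-9),
            (1 + 140, 0, 1.6e-32),
            (3 + 78, 1, 1.0e-18),
        ],
    )
    def test_developmental_pair_pvalues(self, inv, conc, expected_p):
        """All seven stage-pair concordance tests reproduce to 2 sig figs."""
        _, p = concordance_chi2(inv, conc)
        assert p == pytest.approx(expected_p, rel=0.05)

    def test_balanced_counts_give_p_one(self):
        chi2, p = concordance_chi2(10, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            concordance_chi2(0, 0)


class TestCountBasedTE:
    def test_ratio_and_guard(self):
        assert count_based_te(30, 60) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            count_based_te(1, 0)
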