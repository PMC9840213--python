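"""2SLS estimation tests against explicit two-stage oracles and statsmodels."""

import numpy as np
import pytest
from scipy import stats

from jackmr.mr import (
    WeakInstrumentError,
    adjusted_r2,
    first_stage_fstat,
    rank_inverse_normal,
    tsls_fit,
    tsls_multivariable,
)
from jackmr.simulate import SimulationParams, allocate_true_effects, simulate_cohort

from _helpers import TOY_X, TOY_Y, TOY_Z, tsls_oracle as _tsls_oracle


class TestTslsUnivariable:
    def test_degenerates_to_ols_when_instrument_is_exposure(self, rng):
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        fit = tsls_fit(y, x, x)
        r = stats.linregress(x, y)
        assert fit.beta_hat == pytest.approx(r.slope, rel=1e-12)
        assert fit.se == pytest.approx(r.stderr, rel=1e-12)

    def test_eight_point_toy_vs_two_stage_oracle(self):
        fit = tsls_fit(TOY_Y, TOY_X, TOY_Z, true_value=0.2)
        beta, se = _tsls_oracle(TOY_Y, TOY_X, TOY_Z)
        assert fit.beta_hat == pytest.approx(beta, rel=1e-10)
        assert fit.se == pytest.approx(se, rel=1e-10)
        assert fit.ci_low == pytest.approx(beta - 1.96 * se, rel=1e-10)
        assert fit.z == pytest.approx((beta - 0.2) / se, rel=1e-10)

    def test_matches_statsmodels_iv2sls(self, rng):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        n = 300
        z = rng.standard_normal(n)
        u = rng.standard_normal(n)
        x = 0.8 * z + u + rng.standard_normal(n)
        y = 0.4 * x + u + rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        fit = tsls_fit(y, x, z, covariates=cov)
        exog = np.column_stack([np.ones(n), x, cov])
        instr = np.column_stack([np.ones(n), z, cov])
        sm = IV2SLS(y, exog, instrument=instr).fit()
        assert fit.beta_hat == pytest.approx(sm.params[1], rel=1e-8)
        assert fit.se == pytest.approx(sm.bse[1], rel=1e-8)

    def test_instrument_scale_invariance(self, rng):
        z = rng.standard_normal(120)
        x = z + rng.standard_normal(120)
        y = 0.3 * x + rng.standard_normal(120)
        f1 = tsls_fit(y, x, z)
        f2 = tsls_fit(y, x, -42.0 * z)
        assert f2.beta_hat == pytest.approx(f1.beta_hat, rel=1e-10)
        assert f2.se == pytest.approx(f1.se, rel=1e-10)
        assert f2.fstat == pytest.approx(f1.fstat, rel=1e-9)

    def test_zero_variance_instrument_raises(self, rng):
        x = rng.standard_normal(50)
        with pytest.raises(WeakInstrumentError):
            tsls_fit(x + 1, x, np.zeros(50))

    def test_rank_deficient_covariates_raise(self, rng):
        z = rng.standard_normal(50)
        x = z + rng.standard_normal(50)
        c = np.column_stack([np.ones(50), np.ones(50)])
        with pytest.raises(np.linalg.LinAlgError):
            tsls_fit(x + 1, x, z, covariates=c)

    def test_consistency_strong_instrument_large_n(self):
        """Single large replicate: the 2SLS estimate recovers the true causal
        effect while confounded OLS overshoots it."""
        p = SimulationParams(n_applied=200_000, n_snp=100, seed=99)
        rng = np.random.default_rng(p.seed)
        b = allocate_true_effects(p, rng)
        c = simulate_cohort(p, b, "applied", rng)
        score = c.genotypes @ b
        fit = tsls_fit(c.outcome, c.exposure, score)
        assert abs(fit.beta_hat - p.beta_xy) < 0.01
        xc = c.exposure - c.exposure.mean()
        ols = (xc @ c.outcome) / (xc @ xc)
        assert ols > fit.beta_hat  # positive confounding


class TestFirstStage:
    def test_single_instrument_equals_squared_t(self, rng):
        z = rng.standard_normal(80)
        x = 0.6 * z + rng.standard_normal(80)
        r = stats.linregress(z, x)
        f = first_stage_fstat(x, z)
        assert f == pytest.approx((r.slope / r.stderr) ** 2, rel=1e-10)

    def test_instrument_equals_exposure_overflow_guarded(self, rng):
        x = rng.standard_normal(30)
        f = first_stage_fstat(x, x)
        assert np.isfinite(f) and f > 1e12

    def test_twenty_point_toy_vs_rss_oracle(self, rng):
        x = rng.standard_normal(20)
        z = np.column_stack([rng.standard_normal(20), rng.standard_normal(20)])
        f = first_stage_fstat(x, z)
        # brute-force nested-model comparison
        n = 20
        w = np.ones((n, 1))
        rss_r = np.sum((x - x.mean()) ** 2)
        full = np.column_stack([w, z])
        bhat = np.linalg.lstsq(full, x, rcond=None)[0]
        rss_f = np.sum((x - full @ bhat) ** 2)
        want = ((rss_r - rss_f) / 2) / (rss_f / (n - 3))
        assert f == pytest.approx(want, rel=1e-10)


class TestAdjustedR2:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert adjusted_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_five_point_toy_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        z = np.array([0.0, 1.0, 1.0, 2.0, 2.0])
        r = stats.linregress(z, x)
        want = 1 - (1 - r.rvalue**2) * 4 / 3
        assert adjusted_r2(x, z) == pytest.approx(want, rel=1e-12)

    def test_independent_large_n_near_zero(self, rng):
        x = rng.standard_normal(5000)
        z = rng.standard_normal(5000)
        assert abs(adjusted_r2(x, z)) < 0.01


class TestMultivariable:
    def test_moment_equations_solved(self, rng):
        n = 500
        z = rng.standard_normal((n, 2))
        u = rng.standard_normal(n)
        x = z @ np.array([[1.0, 0.2], [0.1, 0.9]]).T + u[:, None] \
            + rng.standard_normal((n, 2))
        y = x @ np.array([0.5, -0.3]) + u + rng.standard_normal(n)
        fit = tsls_multivariable(y, x, z)
        zt = z - z.mean(axis=0)
        resid = (y - x @ fit.beta_hat)
        resid = resid - resid.mean()
        assert np.max(np.abs(zt.T @ resid)) < 1e-8 * n

    def test_irrelevant_second_exposure(self, rng):
        n = 4000
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        u = rng.standard_normal(n)
        x1 = z1 + u + rng.standard_normal(n)
        x2 = z2 + rng.standard_normal(n)  # pure noise exposure, valid IV
        y = 0.4 * x1 + u + rng.standard_normal(n)
        uni = tsls_fit(y, x1, z1)
        multi = tsls_multivariable(y, [x1, x2], [z1, z2])
        assert abs(multi.beta_hat[0] - uni.beta_hat) < 2 * uni.se
        assert abs(multi.beta_hat[1]) < 3 * multi.se[1]

    def test_mediation_recovery(self):
        """X_child -> X_adult -> Y with no direct path: the multivariable
        direct effect of X_child is ~0 while the univariable total effect is
        the product along the path."""
        p = SimulationParams(n_applied=50_000, n_snp=60, seed=31)
        rng = np.random.default_rng(p.seed)
        b1 = allocate_true_effects(p, rng)
        child = simulate_cohort(p, b1, "applied", rng)
        x_child = child.exposure
        g2 = simulate_cohort(p, b1, "external", rng).genotypes
        b2 = allocate_true_effects(p, rng)
        x_adult = 0.6 * x_child + g2 @ b2 + rng.standard_normal(p.n_applied) * 0.7
        y = 0.5 * x_adult + rng.standard_normal(p.n_applied)
        z1 = child.genotypes @ b1
        z2 = g2 @ b2
        total = tsls_fit(y, x_child, z1)
        assert total.beta_hat == pytest.approx(0.6 * 0.5, abs=3 * total.se)
        multi = tsls_multivariable(
            y, [x_child, x_adult], [z1, z2], true_values=[0.0, 0.5]
        )
        assert abs(multi.beta_hat[0]) < 3 * multi.se[0]
        assert multi.beta_hat[1] == pytest.approx(0.5, abs=3 * multi.se[1])
        assert np.all(multi.fstat > 10)

    def test_collinear_instruments_raise(self, rng):
        n = 100
        z = rng.standard_normal(n)
        x = np.column_stack([z + rng.standard_normal(n),
                             z + rng.standard_normal(n)])
        y = x @ np.array([0.2, 0.1]) + rng.standard_normal(n)
        with pytest.raises(np.linalg.LinAlgError):
            tsls_multivariable(y, x, np.column_stack([z, 2 * z]))


class TestRankInverseNormal:
    def test_three_values_closed_form(self):
        out = rank_inverse_normal(np.array([5.0, -1.0, 2.0]))
        # Blom: (r - 3/8)/(n + 1/4) at n=3 -> probabilities 0.625/3.25 etc.
        want = stats.norm.ppf(np.array([2.625, 0.625, 1.625]) / 3.25)
        np.testing.assert_allclose(out, want, rtol=1e-12)
        assert out[0] == pytest.approx(-out[1])  # symmetric around 0
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_and_near_normal_preserving(self, rng):
        v = rng.gamma(2.0, size=1000)
        t = rank_inverse_normal(v)
        assert np.all(np.diff(t[np.argsort(v)]) >= 0)
        w = rng.standard_normal(1000)
        assert np.corrcoef(rank_inverse_normal(w), w)[0, 1] > 0.99

    def test_ties_share_rank(self):
        t = rank_inverse_normal(np.array([1.0, 1.0, 5.0, 9.0]))
        assert t[0] == t[1]

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            rank_inverse_normal(np.full(10, 3.3))
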