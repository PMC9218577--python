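import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from conftest import FAST, make_design
from expodet.datamodel import build_design_matrix
from expodet.mcmc import (
    SD_LOWER,
    SD_UPPER,
    CensoredBayesLM,
    McmcSettings,
    PriorSpec,
    credible_interval,
    derive_seed,
    fit_censored_fixed,
    fit_censored_random_intercept,
    mcse,
    sample_truncated_normal_upper,
    slice_sample_bounded,
)


class TestTruncatedNormalSampler:
    def test_mean_at_zero_bound_matches_closed_form(self):
        rng = np.random.default_rng(0)
        x = sample_truncated_normal_upper(np.zeros(100_000), 1.0, np.zeros(100_000), rng)
        assert x.mean() == pytest.approx(-stats.norm.pdf(0) / stats.norm.cdf(0), abs=0.01)
        assert x.max() <= 0

    def test_infinite_bound_recovers_plain_normal(self):
        rng = np.random.default_rng(1)
        x = sample_truncated_normal_upper(np.zeros(10_000), 1.0, np.inf, rng)
        _, p = stats.kstest(x, "norm")
        assert p > 0.01

    def test_extreme_tail_is_stable(self):
        rng = np.random.default_rng(2)
        x = sample_truncated_normal_upper(np.zeros(5000), 1.0, -8.0, rng)
        assert np.isfinite(x).all()
        assert (x <= -8.0).all()
        assert x.min() > -10.0  # tail draws concentrate just below the bound

    def test_location_scale_and_scalar_interface(self):
        rng = np.random.default_rng(3)
        x = sample_truncated_normal_upper(5.0, 2.0, 4.0, rng)
        assert np.isscalar(x) and x <= 4.0
        with pytest.raises(ValueError):
            sample_truncated_normal_upper(0.0, 0.0, 1.0, rng)


class TestSliceSampler:
    def test_bounded_normal_target_moments(self):
        rng = np.random.default_rng(4)
        logp = lambda s: -0.5 * (s - 1.0) ** 2 / 0.04
        draws = []
        x = 1.0
        for _ in range(4000):
            x = slice_sample_bounded(logp, x, 0.5, 1.5, rng)
            draws.append(x)
        draws = np.asarray(draws[500:])
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        assert draws.std() == pytest.approx(0.2, rel=0.15)
        assert draws.min() >= 0.5 and draws.max() <= 1.5


class TestDiagnostics:
    def test_mcse_constant_chain_is_zero(self):
        assert mcse(np.ones(1000)) == 0.0

    def test_mcse_iid_chain_near_sd_over_sqrt_n(self):
        x = np.random.default_rng(5).standard_normal(10_000)
        assert mcse(x) == pytest.approx(0.01, rel=0.5)

    def test_mcse_inflates_under_autocorrelation(self):
        rng = np.random.default_rng(6)
        n, rho = 20_000, 0.9
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n) * math.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        assert mcse(x) > 2.0 * x.std() / math.sqrt(n)

    def test_credible_interval_quantile_rule(self):
        lo, hi = credible_interval(np.arange(1, 101, dtype=float), 0.80)
        assert (lo, hi) == pytest.approx((10.9, 90.1))
        assert credible_interval(np.full(50, 3.0), 0.95) == (3.0, 3.0)

    def test_credible_interval_normal_quantiles(self):
        x = np.random.default_rng(7).standard_normal(100_000)
        lo, hi = credible_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.5, 0.99), st.integers(0, 2**31 - 1))
    def test_interval_widens_with_level(self, level, seed):
        x = np.random.default_rng(seed).standard_normal(500)
        lo1, hi1 = credible_interval(x, level * 0.8)
        lo2, hi2 = credible_interval(x, level)
        assert lo2 <= lo1 and hi2 >= hi1

    def test_derived_seeds_are_stable_and_bounded(self):
        s1 = derive_seed(42, 7)
        assert s1 == derive_seed(42, 7)
        assert s1 != derive_seed(42, 8)
        assert 0 <= s1 < 2**31


class TestFixedEffectModel:
    def test_no_censoring_matches_sample_mean(self):
        rng = np.random.default_rng(8)
        y = 2.0 + rng.standard_normal(150)
        dm = make_design(y, np.ones((150, 1)), ["intercept"])
        chain = fit_censored_fixed(dm, settings=FAST)
        mu = chain.param("intercept")
        assert abs(np.mean(mu) - y.mean()) < 2 * max(mcse(mu), 1e-3)

    def test_matches_ols_without_censoring(self):
        rng = np.random.default_rng(9)
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [1.0, 0.5, -0.7] + 0.8 * rng.standard_normal(n)
        dm = make_design(y, X, ["intercept", "x1", "x2"])
        chain = fit_censored_fixed(dm, settings=FAST)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        for j, name in enumerate(["intercept", "x1", "x2"]):
            d = chain.param(name)
            assert abs(np.mean(d) - ols[j]) < 3 * max(mcse(d), 1e-3)

    def test_tobit_mle_oracle_agreement_with_30pct_censoring(self):
        rng = np.random.default_rng(10)
        n = 200
        x = rng.normal(size=n)
        y = 1.0 * x + rng.standard_normal(n)
        lod = np.quantile(y, 0.3)
        cens = y < lod
        yobs = np.where(cens, lod, y)
        dm = make_design(yobs, np.column_stack([np.ones(n), x]), ["intercept", "x"],
                         censored=cens, bound=np.full(n, lod))
        chain = fit_censored_fixed(
            dm, settings=McmcSettings(burn_in=500, kept_iterations=1500, thin=2, seed=2)
        )

        def nll(p):
            b0, b1, ls = p
            s = math.exp(ls)
            m = b0 + b1 * x
            ll = np.where(
                cens,
                stats.norm.logcdf((lod - m) / s),
                stats.norm.logpdf((yobs - m) / s) - ls,
            )
            return -ll.sum()

        opt = optimize.minimize(nll, [0.0, 0.5, 0.0], method="Nelder-Mead")
        beta_draws = chain.param("x")
        assert abs(np.median(beta_draws) - opt.x[1]) < 3 * beta_draws.std()

    def test_imputation_respects_bounds_via_posterior_consistency(self):
        # with heavy censoring the posterior mean must sit below the bound-
        # substitution estimate (bound substitution biases upward)
        rng = np.random.default_rng(11)
        y = rng.standard_normal(200)
        lod = np.quantile(y, 0.5)
        cens = y < lod
        yobs = np.where(cens, lod, y)
        dm = make_design(yobs, np.ones((200, 1)), ["intercept"],
                         censored=cens, bound=np.full(200, lod))
        chain = fit_censored_fixed(dm, settings=FAST)
        assert np.mean(chain.param("intercept")) < yobs.mean()

    def test_all_censored_design_rejected(self):
        dm = make_design(np.zeros(10), np.ones((10, 1)), ["intercept"],
                         censored=np.ones(10, bool), bound=np.zeros(10))
        with pytest.raises(ValueError, match="censored"):
            fit_censored_fixed(dm, settings=FAST)

    def test_singular_design_warns_but_runs(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(50)
        X = np.ones((50, 2))  # duplicate of the intercept
        with pytest.warns(UserWarning, match="rank deficient"):
            dm = make_design(y, X, ["intercept", "dup"])
            chain = fit_censored_fixed(dm, settings=FAST)
        assert np.isfinite(chain.draws).all()

    def test_chain_shape_and_schedule(self):
        y = np.random.default_rng(13).standard_normal(40)
        dm = make_design(y, np.ones((40, 1)), ["intercept"])
        s = McmcSettings(burn_in=100, kept_iterations=250, thin=3, seed=1)
        chain = fit_censored_fixed(dm, settings=s)
        assert chain.draws.shape == (250, 2)
        assert (chain.param("sigma_within") > 0).all()


class TestRandomInterceptModel:
    def _grouped_data(self, seed=14, n_subj=40, reps=5, sb=0.5, sw=1.0, censor=False):
        rng = np.random.default_rng(seed)
        subj = np.repeat(np.arange(n_subj), reps)
        b = sb * rng.standard_normal(n_subj)
        y = 1.0 + b[subj] + sw * rng.standard_normal(n_subj * reps)
        cens = np.zeros(len(y), bool)
        bound = y.copy()
        if censor:
            lod = np.quantile(y, 0.25)
            cens = y < lod
            y = np.where(cens, lod, y)
            bound = np.full(len(y), lod)
        return make_design(y, np.ones((len(y), 1)), ["intercept"],
                           censored=cens, bound=bound, subjects=subj)

    def test_recovers_both_variance_components(self):
        dm = self._grouped_data()
        chain = fit_censored_random_intercept(
            dm, settings=McmcSettings(burn_in=600, kept_iterations=1200, thin=2, seed=3)
        )
        assert np.median(chain.param("sigma_between")) == pytest.approx(0.5, rel=0.25)
        assert np.median(chain.param("sigma_within")) == pytest.approx(1.0, rel=0.25)

    def test_sd_draws_respect_uniform_prior_bounds(self):
        dm = self._grouped_data(censor=True)
        chain = fit_censored_random_intercept(dm, settings=FAST)
        for name in ("sigma_within", "sigma_between"):
            d = chain.param(name)
            assert (d >= SD_LOWER).all() and (d <= SD_UPPER).all()

    def test_singleton_subjects_rejected_toward_fixed_variant(self):
        rng = np.random.default_rng(15)
        y = rng.standard_normal(30)
        dm = make_design(y, np.ones((30, 1)), ["intercept"])  # every subject once
        with pytest.raises(ValueError, match="fixed-effect"):
            fit_censored_random_intercept(dm, settings=FAST)

    def test_convergence_and_mixing_on_default_fixture(self, default_study):
        ds, _ = default_study
        dm = build_design_matrix(ds, ["sampled_task"], "overall")
        chain = fit_censored_random_intercept(
            dm, settings=McmcSettings(burn_in=400, kept_iterations=600, thin=3, seed=5)
        )
        # first/second half stability within 3 MCSEs
        for name in ("intercept", "sigma_within"):
            d = chain.param(name)
            half = len(d) // 2
            se = max(mcse(d), 1e-4)
            assert abs(d[:half].mean() - d[half:].mean()) < 3 * se * math.sqrt(2)
        # thinned coefficient chains decorrelate
        g = chain.param("sampled_task[grinding]")
        lag1 = np.corrcoef(g[:-1], g[1:])[0, 1]
        assert lag1 < 0.2

    def test_identical_seed_gives_identical_chain(self, default_study):
        ds, _ = default_study
        dm = build_design_matrix(ds, [], "grinding")
        c1 = fit_censored_random_intercept(dm, settings=FAST)
        c2 = fit_censored_random_intercept(dm, settings=FAST)
        np.testing.assert_array_equal(c1.draws, c2.draws)


class TestCoverage:
    def test_95_ci_coverage_of_true_beta(self):
        """95% intervals from repeated reduced-n fits cover truth at a rate
        consistent with nominal (99% binomial band around 0.95)."""
        rng = np.random.default_rng(16)
        n, reps = 60, 100
        hits = 0
        for r in range(reps):
            x = rng.normal(size=n)
            y = 0.8 * x + rng.standard_normal(n)
            lod = np.quantile(y, 0.25)
            cens = y < lod
            yobs = np.where(cens, lod, y)
            dm = make_design(yobs, np.column_stack([np.ones(n), x]), ["intercept", "x"],
                             censored=cens, bound=np.full(n, lod))
            chain = fit_censored_fixed(
                dm, settings=McmcSettings(burn_in=150, kept_iterations=300, thin=1, seed=r)
            )
            lo, hi = credible_interval(chain.param("x"), 0.95)
            hits += lo <= 0.8 <= hi
        # 99% binomial band for p=0.95, n=100: ~ [89, 100]
        assert hits >= 89


class TestResultsApi:
    def test_summary_table_and_export(self, tmp_path):
        y = np.random.default_rng(17).standard_normal(60) + 1.0
        dm = make_design(y, np.ones((60, 1)), ["intercept"])
        res = CensoredBayesLM(dm, PriorSpec()).fit(FAST)
        tab = res.summary()
        assert list(tab.columns) == ["median", "ci95_low", "ci95_high", "mcse"]
        assert set(tab.index) == {"intercept", "sigma_within"}
        res.chain.export(tmp_path / "chain.csv", tmp_path / "chain.json")
        assert (tmp_path / "chain.csv").exists() and (tmp_path / "chain.json").exists()
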