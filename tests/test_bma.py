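import itertools

import numpy as np
import pytest

from expodet.bma import (
    BayesianModelAveraging,
    ModelSpace,
    ModelSpec,
    average_coefficient,
    enumerate_models,
    fit_model_space,
    gsd_reduction,
    percent_change,
)
from expodet.datamodel import DeterminantSpec, ExposureRecord, StudyDataset
from expodet.descriptive import fit_intercept_only
from expodet.mcmc import McmcSettings, PosteriorChain, credible_interval, mcse
from expodet.screening import ExclusionSet

BMA_SETTINGS = McmcSettings(burn_in=200, kept_iterations=400, thin=1, seed=9)


def brute_force_space(names, banned_pairs):
    """Independent oracle: filter the full power set."""
    admissible = []
    for k in range(len(names) + 1):
        for subset in itertools.combinations(names, k):
            s = frozenset(subset)
            if any(frozenset(p) <= s for p in banned_pairs):
                continue
            admissible.append(s)
    return set(admissible)


class TestEnumerateModels:
    @pytest.mark.parametrize("p", [1, 3, 5, 8, 12])
    def test_matches_power_set_oracle_without_exclusions(self, p):
        names = [f"d{i}" for i in range(p)]
        space = enumerate_models(names)
        oracle = brute_force_space(names, [])
        assert {m.determinants for m in space.models} == oracle
        assert space.total_models == 2**p - 1
        for n in names:
            assert space.membership_counts[n] == 2 ** (p - 1)

    @pytest.mark.parametrize("p,banned", [
        (3, [("d0", "d1")]),
        (5, [("d0", "d1"), ("d2", "d3")]),
        (7, [("d0", "d1"), ("d1", "d2"), ("d4", "d6")]),
    ])
    def test_matches_power_set_filter_oracle_with_exclusions(self, p, banned):
        names = [f"d{i}" for i in range(p)]
        ex = ExclusionSet(collinear_pairs={frozenset(b) for b in banned})
        space = enumerate_models(names, ex)
        oracle = brute_force_space(names, banned)
        assert {m.determinants for m in space.models} == oracle
        # no admissible model contains an excluded pair
        for m in space.models:
            for a, b in banned:
                assert not {a, b} <= m.determinants

    def test_three_determinants_one_exclusion_counts(self):
        ex = ExclusionSet(collinear_pairs={frozenset(("A", "B"))})
        space = enumerate_models(["A", "B", "C"], ex)
        assert len(space.models) == 6  # incl. null
        assert space.membership_counts["A"] == 2

    def test_single_determinant_space(self):
        space = enumerate_models(["A"])
        assert len(space.models) == 2
        assert space.null_model.determinants == frozenset()

    def test_null_model_flagged_and_excluded_from_counts(self):
        space = enumerate_models(["A", "B"])
        assert space.null_model.includes_null
        assert space.total_models == 3

    def test_pct_models_arithmetic_matches_printed_convention(self):
        # a determinant in 242 of 483 models reports 50.1%
        from expodet.descriptive import round_half_away

        assert round_half_away(100 * 242 / 483, 1) == 50.1
        assert round_half_away(100 * 17 / 76, 1) == 22.4

    def test_refuses_oversized_spaces(self):
        with pytest.raises(ValueError, match="2\\^24"):
            enumerate_models([f"d{i}" for i in range(25)])


def _const_chain(model_id, values_by_param, n=200):
    names = list(values_by_param)
    draws = np.tile([values_by_param[k] for k in names], (n, 1))
    return PosteriorChain(draws, names, BMA_SETTINGS, model_id=model_id)


class TestAveraging:
    def _space_two_models(self):
        models = [
            ModelSpec(0, frozenset(), includes_null=True),
            ModelSpec(1, frozenset({"A"})),
            ModelSpec(2, frozenset({"A", "B"})),
        ]
        return ModelSpace(models, ["A", "B"], {"A": 2, "B": 1}, total_models=2)

    def test_single_model_identity(self):
        space = self._space_two_models()
        rng = np.random.default_rng(0)
        draws_b = rng.normal(size=200)
        chains = {
            1: _const_chain(1, {"intercept": 0.0, "A": 1.0}),
            2: PosteriorChain(
                np.column_stack([np.zeros(200), np.ones(200), draws_b]),
                ["intercept", "A", "B"], BMA_SETTINGS, 2),
        }
        out = average_coefficient(chains, space, "B")
        np.testing.assert_array_equal(out["B"], draws_b)

    def test_two_constant_models_average_to_midpoint(self):
        space = self._space_two_models()
        chains = {
            1: _const_chain(1, {"intercept": 0.0, "A": 1.0}),
            2: _const_chain(2, {"intercept": 0.0, "A": 2.0, "B": 0.5}),
        }
        out = average_coefficient(chains, space, "A", method="iteration_mean")
        np.testing.assert_allclose(out["A"], 1.5)
        # the mixture form agrees on the central estimate
        assert np.median(average_coefficient(chains, space, "A")["A"]) == 1.5

    def test_explicit_equal_weights_match_unweighted_mean(self):
        space = self._space_two_models()
        rng = np.random.default_rng(1)
        chains = {
            1: PosteriorChain(np.column_stack([np.zeros(100), rng.normal(1, 0.2, 100)]),
                              ["intercept", "A"], BMA_SETTINGS, 1),
            2: PosteriorChain(
                np.column_stack([np.zeros(100), rng.normal(1, 0.2, 100), rng.normal(size=100)]),
                ["intercept", "A", "B"], BMA_SETTINGS, 2),
        }
        default = average_coefficient(chains, space, "A", method="iteration_mean")
        explicit = average_coefficient(chains, space, "A", weights={1: 0.5, 2: 0.5})
        np.testing.assert_allclose(default["A"], explicit["A"])

    def test_mixture_preserves_member_posterior_spread(self):
        # two agreeing member models: the averaged spread must not collapse
        space = self._space_two_models()
        rng = np.random.default_rng(5)
        a1, a2 = rng.normal(1, 0.3, 2000), rng.normal(1, 0.3, 2000)
        chains = {
            1: PosteriorChain(np.column_stack([np.zeros(2000), a1]),
                              ["intercept", "A"], BMA_SETTINGS, 1),
            2: PosteriorChain(np.column_stack([np.zeros(2000), a2, rng.normal(size=2000)]),
                              ["intercept", "A", "B"], BMA_SETTINGS, 2),
        }
        mixture = average_coefficient(chains, space, "A")["A"]
        mean_wise = average_coefficient(chains, space, "A", method="iteration_mean")["A"]
        assert mixture.std() == pytest.approx(0.3, rel=0.1)
        assert mean_wise.std() < 0.8 * mixture.std()

    def test_unknown_determinant_errors(self):
        space = self._space_two_models()
        with pytest.raises(ValueError):
            average_coefficient({}, space, "Z")

    def test_restricted_averaging_avoids_shrinkage(self):
        # zero-filling the absent models shrinks the magnitude
        space = self._space_two_models()
        chains = {
            1: _const_chain(1, {"intercept": 0.0, "A": 1.0, "B": 0.0}),  # B absent really
            2: _const_chain(2, {"intercept": 0.0, "A": 1.0, "B": 0.8}),
        }
        restricted = average_coefficient(chains, space, "B")["B"]
        zero_filled = 0.5 * (chains[2].param("B") + 0.0)
        assert abs(np.median(restricted)) >= abs(np.median(zero_filled))


class TestPercentChange:
    def test_zero_beta_gives_zero_percent(self):
        _, med, _ = percent_change(np.zeros(100))
        assert med == 0.0

    def test_log_two_gives_hundred_percent(self):
        _, med, _ = percent_change(np.full(100, np.log(2.0)))
        assert med == pytest.approx(100.0)

    def test_printed_gev_bound_transform(self):
        _, med, _ = percent_change(np.full(10, -1.13))
        assert med == pytest.approx(-67.7, abs=0.2)

    def test_quantiles_commute_with_monotone_transform(self):
        rng = np.random.default_rng(2)
        beta = rng.normal(0.3, 0.4, 5000)
        draws, med, (lo, hi) = percent_change(beta, unit_scale=250.0)
        blo, bhi = credible_interval(beta, 0.95)
        assert lo == pytest.approx((np.exp(blo * 250) - 1) * 100, rel=1e-12)
        assert hi == pytest.approx((np.exp(bhi * 250) - 1) * 100, rel=1e-12)
        assert med == pytest.approx((np.exp(np.median(beta) * 250) - 1) * 100, rel=1e-12)

    def test_notable_boundary_convention(self):
        from expodet.bma import AveragedCoefficient

        touching = AveragedCoefficient("d", "d", 1, 100.0, 0.2, (0.0, 0.5), 22.0, (0.0, 65.0))
        inside = AveragedCoefficient("d", "d", 1, 100.0, 0.3, (0.1, 0.5), 35.0, (10.5, 65.0))
        assert not touching.notable_95
        assert inside.notable_95


def _two_determinant_study(beta_a=1.0, beta_b=0.0, n=160, seed=0, censor_lod=0.8):
    rng = np.random.default_rng(seed)
    specs = [
        DeterminantSpec(name="A", level="sample", kind="categorical",
                        reference="no", categories=("no", "yes")),
        DeterminantSpec(name="B", level="sample", kind="categorical",
                        reference="no", categories=("no", "yes")),
    ]
    records = []
    for i in range(n):
        a = (i >> 0) % 2 == 1
        b = (i >> 1) % 2 == 1  # orthogonal to a
        logc = 0.3 + beta_a * a + beta_b * b + 0.8 * rng.standard_normal()
        conc = float(np.exp(logc))
        censored = conc < censor_lod
        records.append(
            ExposureRecord(
                f"s{i}", f"F{i%4}", "diacetyl", censor_lod, censored, 15.0, "grinding",
                concentration_ppb=None if censored else conc,
                subject_id=f"w{i%16}",
                determinants={"A": "yes" if a else "no", "B": "yes" if b else "no"},
            )
        )
    return StudyDataset(records=records, determinants=specs, analyte="diacetyl")


class TestFitModelSpaceAndEngine:
    def test_space_bookkeeping_and_determinism(self):
        ds = _two_determinant_study(seed=3)
        space = enumerate_models(["A", "B"])
        chains, manifest = fit_model_space(ds, space, "grinding", BMA_SETTINGS)
        assert set(chains) == {m.model_id for m in space.models}
        assert all(c.draws.shape[0] == 400 for c in chains.values())
        chains2, _ = fit_model_space(ds, space, "grinding", BMA_SETTINGS)
        for mid in chains:
            np.testing.assert_array_equal(chains[mid].draws, chains2[mid].draws)
        assert manifest["failures"] == []

    def test_null_model_gm_matches_descriptive_fit(self):
        ds = _two_determinant_study(seed=4)
        space = enumerate_models(["A"])
        chains, _ = fit_model_space(ds, space, "grinding", BMA_SETTINGS)
        null = chains[space.null_model.model_id]
        desc = fit_intercept_only(ds, "grinding", settings=BMA_SETTINGS)
        mu_a, mu_b = null.param("intercept"), desc.param("intercept")
        tol = 3 * max(mcse(mu_a), mcse(mu_b))
        assert abs(np.mean(mu_a) - np.mean(mu_b)) < tol

    def test_gsd_reduction_sign_and_null_identity(self):
        ds = _two_determinant_study(beta_a=2.0, seed=5)
        space = enumerate_models(["A"])
        chains, _ = fit_model_space(ds, space, "grinding", BMA_SETTINGS)
        null = chains[space.null_model.model_id]
        full = chains[[m for m in space.models if m.determinants][0].model_id]
        assert gsd_reduction(null, null) == 0.0
        assert gsd_reduction(null, full) > 0.0

    def test_engine_summary_flags_true_effect_and_not_null(self):
        ds = _two_determinant_study(beta_a=1.2, beta_b=0.0, n=240, seed=6)
        engine = BayesianModelAveraging(ds, ["A", "B"], task_filter="grinding")
        fitted = engine.fit(BMA_SETTINGS)
        tab = fitted.summary()
        row_a = tab[tab.determinant == "A"].iloc[0]
        row_b = tab[tab.determinant == "B"].iloc[0]
        assert row_a["notable_95"]
        assert row_a["beta_ci95_low"] <= 1.2 <= row_a["beta_ci95_high"]
        assert not row_b["notable_95"]
        assert row_a["n_models"] == 2 and row_a["pct_models"] == pytest.approx(100 * 2 / 3)
        assert fitted.intercept_reference_gm_ppb > 0

    def test_chain_cache_round_trips_identically(self, tmp_path):
        ds = _two_determinant_study(seed=8)
        space = enumerate_models(["A"])
        first, _ = fit_model_space(ds, space, "grinding", BMA_SETTINGS,
                                   cache_dir=tmp_path / "cache")
        assert any((tmp_path / "cache").iterdir())
        second, _ = fit_model_space(ds, space, "grinding", BMA_SETTINGS,
                                    cache_dir=tmp_path / "cache")
        for mid in first:
            np.testing.assert_array_equal(first[mid].draws, second[mid].draws)
            assert first[mid].parameter_names == second[mid].parameter_names

    def test_gsd_reduction_weights_run(self):
        ds = _two_determinant_study(beta_a=1.0, seed=7)
        engine = BayesianModelAveraging(ds, ["A"], task_filter="grinding",
                                        weights="gsd_reduction")
        fitted = engine.fit(BMA_SETTINGS)
        assert not fitted.summary().empty
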