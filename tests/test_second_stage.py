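"""Tests for the second-stage mixed model and sign probabilities."""

import numpy as np
import pytest
from scipy import stats

from commvar import (
    McmcConfig,
    ParamSummary,
    SecondLevelDesign,
    build_design,
    fit_mixed_model,
    sign_probability,
)


def make_summaries(means, sds, sites, continents, guilds=None):
    out = []
    for j, (m, s) in enumerate(zip(means, sds)):
        out.append(
            ParamSummary(
                site=sites[j],
                species=f"sp{j}",
                parameter="C_ii",
                posterior_mean=float(m),
                posterior_sd=float(s),
                guild=guilds[j] if guilds else "dabbling",
                continent=continents[j],
            )
        )
    return out


def synthetic_design(beta, sigma_p, n_sites=4, n_species=4, seed=0, alpha_sd=0.0):
    """Summaries from the stage-2 generative model itself with known beta."""
    rng = np.random.default_rng(seed)
    means, sds, sites, continents = [], [], [], []
    for s in range(n_sites):
        continent = "Europe" if s < n_sites // 2 else "NorthAmerica"
        alpha = 0.1 + alpha_sd * rng.standard_normal()
        for _ in range(n_species):
            c = 0.0 if continent == "Europe" else 1.0
            means.append(alpha + beta * c + sigma_p * rng.standard_normal())
            sds.append(sigma_p)
            sites.append(f"s{s}")
            continents.append(continent)
    return make_summaries(means, sds, sites, continents)


fast = McmcConfig(chains=4, iterations=4000, burn_in=2000, thin=4, seed=1)


class TestSignProbability:
    def test_symmetric_draws(self, rng):
        assert sign_probability(rng.standard_normal(100_000)) == pytest.approx(0.5, abs=0.01)

    def test_one_sided_draws(self):
        assert sign_probability(np.abs(np.random.default_rng(1).standard_normal(500))) == 1.0

    def test_normal_tail_matches_closed_form(self, rng):
        draws = rng.normal(1.0, 1.0, size=100_000)
        assert sign_probability(draws) == pytest.approx(stats.norm.cdf(1.0), abs=0.01)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            sign_probability(np.ones(50))


class TestDesignValidation:
    def test_two_communities_need_factorial_mode(self):
        summaries = make_summaries([0.1, 0.2], [0.01, 0.01], ["a", "b"],
                                   ["Europe", "NorthAmerica"])
        with pytest.raises(ValueError, match="factorial"):
            SecondLevelDesign(
                observations=summaries,
                dummy=np.array([0.0, 1.0]),
                grouping=np.array([0, 1]),
                mode="random_intercept",
            )

    def test_single_factor_level_rejected(self):
        summaries = make_summaries([0.1, 0.2], [0.01, 0.01], ["a", "b"],
                                   ["Europe", "Europe"])
        with pytest.raises(ValueError, match="both dummy levels"):
            build_design(summaries, factor="continent")

    def test_build_design_defaults_to_factorial_for_two_sites(self):
        summaries = make_summaries([0.1, 0.2], [0.01, 0.01], ["a", "b"],
                                   ["Europe", "NorthAmerica"])
        design = build_design(summaries, factor="continent")
        assert design.mode == "factorial_dummy"


class TestFitMixedModel:
    def test_no_signal_centers_beta_at_zero(self):
        summaries = make_summaries([0.2] * 8, [0.02] * 8,
                                   [f"s{j // 2}" for j in range(8)],
                                   ["Europe"] * 4 + ["NorthAmerica"] * 4)
        res = fit_mixed_model(build_design(summaries, factor="continent"), fast)
        assert abs(res.beta_mean) < 0.05
        assert res.p < 0.75

    def test_recovers_injected_effect(self):
        summaries = synthetic_design(beta=0.07, sigma_p=0.01, seed=3)
        res = fit_mixed_model(build_design(summaries, factor="continent"), fast)
        assert abs(res.beta_mean - 0.07) < 2 * res.beta_sd
        assert res.p > 0.9

    def test_doubling_observation_sds_widens_posterior(self):
        base = synthetic_design(beta=0.05, sigma_p=0.02, seed=4)
        wide = [
            ParamSummary(s.site, s.species, s.parameter, s.posterior_mean,
                         2 * s.posterior_sd, s.guild, s.continent)
            for s in base
        ]
        res1 = fit_mixed_model(build_design(base, factor="continent"), fast)
        res2 = fit_mixed_model(build_design(wide, factor="continent"), fast)
        assert res2.beta_sd > res1.beta_sd

    def test_permutation_invariance_within_mcmc_error(self):
        summaries = synthetic_design(beta=0.07, sigma_p=0.01, seed=5)
        perm = [summaries[i] for i in np.random.default_rng(0).permutation(len(summaries))]
        res1 = fit_mixed_model(build_design(summaries, factor="continent"), fast)
        res2 = fit_mixed_model(build_design(perm, factor="continent"), fast)
        assert res1.beta_mean == pytest.approx(res2.beta_mean, abs=3 * res1.beta_sd / 10)
        assert res1.p == pytest.approx(res2.p, abs=0.05)

    def test_factorial_mode_guild_within_two_communities(self):
        # two North American communities, guild varying within each: the
        # factorial variant with intercept + community contrast + guild dummy
        rng = np.random.default_rng(6)
        guilds = ["dabbling", "dabbling", "diving", "diving"] * 2
        means = [0.10 + 0.15 * (g == "diving") + 0.005 * rng.standard_normal()
                 for g in guilds]
        summaries = make_summaries(means, [0.01] * 8,
                                   ["a"] * 4 + ["b"] * 4,
                                   ["NorthAmerica"] * 8, guilds=guilds)
        res = fit_mixed_model(build_design(summaries, factor="guild"), fast)
        assert res.mode == "factorial_dummy"
        assert res.beta_mean == pytest.approx(0.15, abs=0.05)
        assert res.p > 0.9

    def test_factorial_mode_rejects_collinear_factor(self):
        # a between-community factor cannot be separated from the community
        # contrasts when there are only two communities
        summaries = make_summaries([0.1] * 4 + [0.2] * 4, [0.01] * 8,
                                   ["a"] * 4 + ["b"] * 4,
                                   ["Europe"] * 4 + ["NorthAmerica"] * 4)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_mixed_model(build_design(summaries, factor="continent"), fast)

    def test_guild_factor_coding(self):
        summaries = make_summaries(
            [0.1, 0.1, 0.3, 0.3] * 3,
            [0.01] * 12,
            [f"s{j // 4}" for j in range(12)],
            ["Europe"] * 12,
            guilds=["dabbling", "dabbling", "diving", "diving"] * 3,
        )
        res = fit_mixed_model(build_design(summaries, factor="guild"), fast)
        # diving coded 1: effect should be ~ +0.2
        assert res.beta_mean == pytest.approx(0.2, abs=0.05)
        assert res.p > 0.95

    def test_rhat_reported_for_all_parameters(self):
        # sigma_alpha lives in a funnel when the true between-community
        # variance is zero, so this check runs at the full default schedule
        summaries = synthetic_design(beta=0.0, sigma_p=0.02, seed=7)
        res = fit_mixed_model(build_design(summaries, factor="continent"),
                              McmcConfig(seed=7))
        assert {"beta", "mu", "sigma_alpha", "sigma_eps"} <= set(res.rhat)
        assert all(v < 1.1 for v in res.rhat.values())
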