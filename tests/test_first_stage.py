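"""Tests for stage-1 data preparation, fitting, and diagnostics."""

import numpy as np
import pytest
from scipy import stats

from commvar import (
    CommunityCounts,
    FirstBayesPosterior,
    McmcConfig,
    PriorSpec,
    default_k_bounds,
    filter_series,
    fit_state_space,
    gelman_rubin,
    prepare_log_counts,
    summarize,
)


def make_counts(counts, **kw):
    counts = np.asarray(counts)
    T, S = counts.shape
    defaults = dict(
        years=2000 + np.arange(T),
        species=[f"sp{i}" for i in range(S)],
        guild=["dabbling"] * S,
    )
    defaults.update(kw)
    return CommunityCounts(counts=counts, **defaults)


class TestZeroCountFilter:
    def test_half_zeros_even_T_dropped(self):
        # T = 10, 5 zeros: 5 is not fewer than half, so the species goes
        col_bad = np.array([0, 0, 0, 0, 0, 1, 2, 3, 4, 5])
        col_ok = np.arange(1, 11)
        comm = make_counts(np.c_[col_bad, col_ok])
        kept = filter_series(comm)
        assert kept.species == ["sp1"]

    def test_just_under_half_odd_T_retained(self):
        # T = 9, 4 zeros: 4 < 4.5, retained
        col = np.array([0, 0, 0, 0, 1, 2, 3, 4, 5])
        comm = make_counts(np.c_[col, np.arange(1, 10)])
        kept = filter_series(comm)
        assert kept.species == ["sp0", "sp1"]

    def test_no_zeros_retained(self):
        comm = make_counts(np.ones((6, 2), dtype=int))
        assert filter_series(comm) is comm

    def test_all_dropped_raises(self):
        comm = make_counts(np.zeros((6, 2), dtype=int))
        with pytest.raises(ValueError, match="all species dropped"):
            filter_series(comm)


class TestLogCountPreparation:
    def test_zeros_become_missing_but_states_remain(self):
        col = np.ones(20, dtype=int) * 12
        col[[3, 7]] = 0
        comm = make_counts(col[:, None])
        y = prepare_log_counts(comm)
        assert y.shape == (20, 1)  # latent grid keeps all 20 years
        assert np.isnan(y[3, 0]) and np.isnan(y[7, 0])
        assert np.isfinite(y).sum() == 18
        assert y[0, 0] == pytest.approx(np.log(12))


class TestKBounds:
    def test_normal_case(self):
        rng = np.random.default_rng(0)
        y = (3.0 + rng.standard_normal(4000))[:, None]
        lo, hi = default_k_bounds(y)[0]
        m, sd = y.mean(), y.std(ddof=1)
        assert lo == pytest.approx(m - 2.576 * sd)
        assert hi == pytest.approx(m + 2.576 * sd)

    def test_constant_series_fallback(self):
        y = np.full((10, 1), 2.0)
        with pytest.warns(UserWarning, match="constant"):
            lo, hi = default_k_bounds(y)[0]
        assert (lo, hi) == (1.5, 2.5)

    def test_bounds_contain_mean(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(15, 3)) * [0.5, 1.0, 2.0] + [1.0, 3.0, -2.0]
        b = default_k_bounds(y)
        assert np.all(b[:, 0] < y.mean(axis=0))
        assert np.all(b[:, 1] > y.mean(axis=0))


class TestGelmanRubin:
    def test_identical_constant_chains(self):
        with pytest.warns(UserWarning, match="zero within-chain"):
            assert gelman_rubin(np.full((4, 100), 3.0)) == 1.0

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 1000))
        assert gelman_rubin(chains) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(4)
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        assert gelman_rubin(chains) > 5.0

    def test_requires_multiple_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


def make_posterior(draw_dict, species=("a", "b")):
    S = len(species)
    return FirstBayesPosterior(
        draws=draw_dict,
        rhat={},
        converged=True,
        species=list(species),
        guild=["dabbling"] * S,
        site="X",
        continent="Europe",
    )


class TestSummarize:
    def test_degenerate_sd_floored(self):
        draws = {"C_ii": np.full((2, 100, 1), 0.3)}
        post = make_posterior(draws, species=("a",))
        with pytest.warns(UserWarning, match="degenerate"):
            (s,) = summarize(post, "C_ii")
        assert s.posterior_mean == pytest.approx(0.3)
        assert s.posterior_sd == 1e-6

    def test_unknown_parameter_rejected(self):
        post = make_posterior({"C_ii": np.zeros((2, 50, 1))}, species=("a",))
        with pytest.raises(ValueError, match="unknown parameter"):
            summarize(post, "r")

    def test_mean_is_expectation_of_derived_draws_not_plugin(self):
        # skewed r draws: E[(r/k)^2 Var(n)] differs from (E r / k)^2 Var(E n)
        rng = np.random.default_rng(5)
        n_draws = 4000
        r = rng.lognormal(-1.0, 0.8, size=n_draws)
        k, var_n = 3.0, 2.0
        I = (r / k) ** 2 * var_n
        draws = {"I": I.reshape(2, n_draws // 2, 1)}
        post = make_posterior(draws, species=("a",))
        (s,) = summarize(post, "I")
        assert s.posterior_mean == pytest.approx(I.mean())
        plugin = (r.mean() / k) ** 2 * var_n
        assert abs(s.posterior_mean - plugin) > 5 * I.std() / np.sqrt(n_draws)


class TestFitStateSpace:
    def test_seed_determinism_and_bookkeeping(self, small_community, short_config):
        _, _, comm = small_community
        y = prepare_log_counts(comm)
        post1 = fit_state_space(y, config=short_config)
        post2 = fit_state_space(y, config=short_config)
        assert np.array_equal(post1.draws["C"], post2.draws["C"])
        assert np.array_equal(post1.draws["n"], post2.draws["n"])
        n_ret = (short_config.iterations - short_config.burn_in) // short_config.thin
        assert post1.draws["r"].shape == (short_config.chains, n_ret, 2)

    def test_derived_quantities_consistent_per_draw(self, small_community, short_config):
        _, _, comm = small_community
        y = prepare_log_counts(comm)
        post = fit_state_space(y, config=short_config)
        I = post.draws["I"]
        C_ii = post.draws["C_ii"]
        prop = post.draws["Prop(I)"]
        assert np.array_equal(prop, I / (I + C_ii))
        assert np.all((prop >= 0) & (prop <= 1))
        # C_ii matches the diagonal of the C draws, and every C draw is PSD
        assert np.array_equal(C_ii, np.diagonal(post.draws["C"], axis1=2, axis2=3))
        eigs = np.linalg.eigvalsh(post.draws["C"].reshape(-1, 2, 2))
        assert eigs.min() > 0

    def test_var_n_uses_unbiased_sample_variance(self, small_community, short_config):
        _, _, comm = small_community
        y = prepare_log_counts(comm)
        post = fit_state_space(y, config=short_config)
        n = post.draws["n"][0, 0]  # (T, S)
        r = post.draws["r"][0, 0]
        k = post.draws["k"][0, 0]
        expect = (r / k) ** 2 * n.var(axis=0, ddof=1)
        assert np.allclose(post.draws["I"][0, 0], expect)

    def test_single_species_requires_fixed_covariance(self):
        y = np.log(np.arange(5, 20, dtype=float))[:, None]
        with pytest.raises(ValueError, match="S >= 2"):
            fit_state_space(y, config=McmcConfig(chains=2, iterations=200, burn_in=100,
                                                 thin=1, seed=0))

    def test_prior_predictive_r_matches_half_normal(self):
        """With every observation missing the marginal posterior of r is its
        half-normal prior (the data contribute nothing)."""
        T, S = 10, 2
        y = np.full((T, S), np.nan)
        priors = PriorSpec(k_bounds=np.tile([2.0, 5.0], (S, 1)))
        config = McmcConfig(chains=4, iterations=6000, burn_in=2000, thin=4, seed=8)
        post = fit_state_space(y, priors=priors, config=config)
        r_draws = post.pooled("r").ravel()
        d, _ = stats.kstest(r_draws, lambda x: 2 * stats.norm.cdf(x) - 1)
        assert d < 0.05
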