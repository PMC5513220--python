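"""Stage-2 inference: Bayesian mixed model on stage-1 posterior summaries.

Each observation is a species-by-community posterior mean p_x of one
stage-1 parameter (C_ii, I, or Prop(I)) with its posterior SD sigma_p,x.
The latent true value follows

    pi_x = alpha_z + beta * c_x + eps_x,     p_x ~ Normal(pi_x, sigma_p,x^2)

where c_x is a 0/1 dummy (continent or guild), alpha_z is a community
random intercept with alpha_z ~ Normal(mu, sigma_alpha^2), and eps_x ~
Normal(0, sigma_eps^2). The stage-1 SDs enter as fixed, known observation
error scales; they are not re-estimated. Priors are diffuse: Normal(0,
10000) on mu and beta, Uniform(0, 10) on both SDs. With only two
communities a random intercept is not identifiable, so a factorial variant
replaces alpha_z with an intercept plus fixed community contrasts.

The reported "p" is the posterior probability that the coefficient deviates
from zero, taken as the larger of the two tail masses, so p in [0.5, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _gibbs
from .first_stage import McmcConfig, ParamSummary, gelman_rubin

__all__ = [
    "SecondLevelDesign",
    "SecondBayesResult",
    "build_design",
    "fit_mixed_model",
    "sign_probability",
]


@dataclass
class SecondLevelDesign:
    """Observations and coding for one second-stage comparison."""

    observations: list[ParamSummary]
    dummy: np.ndarray  # per-observation 0/1 factor level
    grouping: np.ndarray  # per-observation community index
    mode: str = "random_intercept"  # or "factorial_dummy"

    def __post_init__(self) -> None:
        self.dummy = np.asarray(self.dummy, dtype=float)
        self.grouping = np.asarray(self.grouping, dtype=np.int64)
        n = len(self.observations)
        if self.dummy.shape != (n,) or self.grouping.shape != (n,):
            raise ValueError("dummy and grouping must have one entry per observation")
        if not set(np.unique(self.dummy)) <= {0.0, 1.0}:
            raise ValueError("dummy must be coded 0/1")
        if np.unique(self.dummy).size < 2:
            raise ValueError("need both dummy levels present")
        if self.mode not in ("random_intercept", "factorial_dummy"):
            raise ValueError(f"unknown mode {self.mode!r}")
        K = np.unique(self.grouping).size
        if self.mode == "random_intercept" and K < 3:
            raise ValueError(
                "random_intercept needs >= 3 communities; use mode='factorial_dummy' "
                "for a two-community design"
            )

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.grouping).size)


@dataclass
class SecondBayesResult:
    """Posterior of the comparison coefficient and its hyperparameters."""

    beta_draws: np.ndarray  # (chains, n_ret)
    alpha_draws: np.ndarray  # (chains, n_ret, K) intercepts or factorial coefficients
    mu_draws: np.ndarray | None
    sigma_alpha_draws: np.ndarray | None
    sigma_eps_draws: np.ndarray
    rhat: dict[str, float] = field(default_factory=dict)
    p: float = 0.5
    mode: str = "random_intercept"
    parameter: str = ""

    @property
    def beta_mean(self) -> float:
        return float(self.beta_draws.mean())

    @property
    def beta_sd(self) -> float:
        return float(self.beta_draws.std(ddof=1))


def build_design(
    summaries: list[ParamSummary],
    factor: str = "continent",
    mode: str | None = None,
) -> SecondLevelDesign:
    """Code a list of stage-1 summaries into a comparison design.

    ``factor='continent'`` codes Europe = 0, NorthAmerica = 1;
    ``factor='guild'`` codes dabbling = 0, diving = 1. Communities are the
    distinct sites; mode defaults to random_intercept when three or more
    communities are present and factorial_dummy otherwise.
    """
    if factor == "continent":
        dummy = [0.0 if s.continent == "Europe" else 1.0 for s in summaries]
    elif factor == "guild":
        dummy = [0.0 if s.guild == "dabbling" else 1.0 for s in summaries]
    else:
        raise ValueError("factor must be 'continent' or 'guild'")
    sites = sorted({s.site for s in summaries})
    grouping = [sites.index(s.site) for s in summaries]
    if mode is None:
        mode = "random_intercept" if len(sites) >= 3 else "factorial_dummy"
    return SecondLevelDesign(
        observations=list(summaries),
        dummy=np.array(dummy),
        grouping=np.array(grouping),
        mode=mode,
    )


def fit_mixed_model(
    design: SecondLevelDesign, config: McmcConfig | None = None
) -> SecondBayesResult:
    """Sample the mixed-model posterior by Gibbs/Metropolis MCMC."""
    if config is None:
        config = McmcConfig()
    obs = design.observations
    p = np.array([o.posterior_mean for o in obs])
    sd = np.array([o.posterior_sd for o in obs])
    if np.any(sd <= 0):
        raise ValueError("all stage-1 posterior SDs must be positive")
    sp2 = sd**2
    c = design.dummy
    z = design.grouping
    K = design.n_communities
    n_ret = config.retained_per_chain
    params = {o.parameter for o in obs}
    parameter = params.pop() if len(params) == 1 else "mixed"

    root = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % np.uint32(2**31 - 1)) for s in root.spawn(config.chains)]
    jitter = np.random.default_rng(root.spawn(1)[0])

    beta = np.empty((config.chains, n_ret))
    sigma_eps = np.empty((config.chains, n_ret))
    if design.mode == "random_intercept":
        alpha = np.empty((config.chains, n_ret, K))
        mu = np.empty((config.chains, n_ret))
        sigma_alpha = np.empty((config.chains, n_ret))
        for ch in range(config.chains):
            alpha0 = np.array([p[z == g].mean() for g in range(K)])
            alpha0 = alpha0 + 0.1 * jitter.standard_normal(K)
            a, b, m, sa, se = _gibbs.run_second_chain_random(
                p,
                sp2,
                c,
                z,
                K,
                int(config.iterations),
                int(config.burn_in),
                int(config.thin),
                chain_seeds[ch],
                alpha0,
                0.1 * jitter.standard_normal(),
                p.mean() + 0.1 * jitter.standard_normal(),
                0.3 * np.exp(0.5 * jitter.standard_normal()),
                0.3 * np.exp(0.5 * jitter.standard_normal()),
            )
            alpha[ch], beta[ch], mu[ch], sigma_alpha[ch], sigma_eps[ch] = a, b, m, sa, se
        rhat = {"beta": gelman_rubin(beta), "mu": gelman_rubin(mu)}
        for g in range(K):
            rhat[f"alpha[{g}]"] = gelman_rubin(alpha[:, :, g])
        rhat["sigma_alpha"] = gelman_rubin(sigma_alpha)
        rhat["sigma_eps"] = gelman_rubin(sigma_eps)
        result = SecondBayesResult(
            beta_draws=beta,
            alpha_draws=alpha,
            mu_draws=mu,
            sigma_alpha_draws=sigma_alpha,
            sigma_eps_draws=sigma_eps,
            rhat=rhat,
            mode=design.mode,
            parameter=parameter,
        )
    else:
        # intercept + (K-1) community contrasts + factor dummy
        P = 1 + (K - 1) + 1
        X = np.zeros((p.size, P))
        X[:, 0] = 1.0
        for g in range(1, K):
            X[z == g, g] = 1.0
        X[:, P - 1] = c
        if np.linalg.matrix_rank(X) < P:
            raise ValueError(
                "factorial design is rank-deficient: the factor dummy must vary "
                "within communities (it is collinear with the community contrasts)"
            )
        theta = np.empty((config.chains, n_ret, P))
        for ch in range(config.chains):
            theta0 = np.zeros(P)
            theta0[0] = p.mean()
            theta0 = theta0 + 0.1 * jitter.standard_normal(P)
            th, se = _gibbs.run_second_chain_factorial(
                p,
                sp2,
                X,
                int(config.iterations),
                int(config.burn_in),
                int(config.thin),
                chain_seeds[ch],
                theta0,
                0.3 * np.exp(0.5 * jitter.standard_normal()),
            )
            theta[ch], sigma_eps[ch] = th, se
        beta = theta[:, :, P - 1]
        rhat = {"beta": gelman_rubin(beta), "sigma_eps": gelman_rubin(sigma_eps)}
        for j in range(P - 1):
            rhat[f"alpha[{j}]"] = gelman_rubin(theta[:, :, j])
        result = SecondBayesResult(
            beta_draws=beta,
            alpha_draws=theta[:, :, : P - 1],
            mu_draws=None,
            sigma_alpha_draws=None,
            sigma_eps_draws=sigma_eps,
            rhat=rhat,
            mode=design.mode,
            parameter=parameter,
        )
    result.p = sign_probability(result.beta_draws.ravel())
    return result


def sign_probability(beta_draws: np.ndarray) -> float:
    """Larger tail mass of the coefficient posterior: max(P(b > 0), P(b < 0))."""
    d = np.asarray(beta_draws, dtype=float).ravel()
    if d.size < 100:
        raise ValueError("need at least 100 draws for a sign probability")
    return float(max((d > 0).mean(), (d < 0).mean()))
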