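"""Stage-1 inference: fit the multispecies Gompertz state-space model.

The model is fit by MCMC with the following priors: an inverse-Wishart
(df = S, identity scale) on the environmental covariance C; a half-normal
(scale 1) on each growth rate r; a uniform on each log carrying capacity k
with data-driven bounds mean(y) +/- 2.576 * SD(y); and Uniform(0, 10) on the
observation and demographic SDs tau and delta. The default schedule runs 4
chains of 20,000 iterations, discards the first 10,000 as burn-in, and thins
to every 20th draw; convergence is judged by the classic Gelman-Rubin
statistic against a 1.1 threshold.

Zero counts are treated as missing observations: the log-count likelihood
is dropped for those years while the latent state remains in the process
chain. Species observed as zero in at least half the years are removed
entirely before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _gibbs
from .core import (
    CommunityCounts,
    density_dependence_index,
    prop_density_dependence,
)

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "FirstBayesPosterior",
    "ParamSummary",
    "filter_series",
    "prepare_log_counts",
    "default_k_bounds",
    "fit_state_space",
    "fit_community",
    "gelman_rubin",
    "summarize",
]

logger = logging.getLogger("commvar")

#: Diffuse SD of the initial-state prior n_1 ~ Normal(mean(y_i), INIT_STATE_SD^2).
INIT_STATE_SD = 10.0

PARAMETER_NAMES = ("C_ii", "I", "Prop(I)")


@dataclass
class PriorSpec:
    """Prior hyperparameters for one community fit."""

    k_bounds: np.ndarray  # (S, 2) per-species (kmin, kmax)
    r_scale: float = 1.0
    sd_prior_upper: float = 10.0
    wishart_df: int | None = None  # defaults to S
    wishart_omega: np.ndarray | None = None  # defaults to identity

    def __post_init__(self) -> None:
        self.k_bounds = np.atleast_2d(np.asarray(self.k_bounds, dtype=float))
        if self.k_bounds.shape[1] != 2:
            raise ValueError("k_bounds must be an (S, 2) array of (kmin, kmax)")
        if np.any(self.k_bounds[:, 0] >= self.k_bounds[:, 1]):
            raise ValueError("each kmin must be strictly below its kmax")
        if self.sd_prior_upper <= 0:
            raise ValueError("sd_prior_upper must be positive")
        S = self.k_bounds.shape[0]
        if self.wishart_df is None:
            self.wishart_df = S
        if self.wishart_df < S:
            raise ValueError("wishart_df must be at least the number of species")
        if self.wishart_omega is None:
            self.wishart_omega = np.eye(S)
        self.wishart_omega = np.asarray(self.wishart_omega, dtype=float)
        if not np.allclose(self.wishart_omega, np.eye(S)):
            raise NotImplementedError("only the identity Wishart scale is supported")


@dataclass
class McmcConfig:
    """MCMC schedule; defaults follow the full analysis schedule."""

    chains: int = 4
    iterations: int = 20000
    burn_in: int = 10000
    thin: int = 20
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for the R-hat diagnostic")
        if not (0 < self.burn_in < self.iterations):
            raise ValueError("burn_in must lie strictly between 0 and iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class ParamSummary:
    """Posterior mean/SD of one parameter for one species at one site."""

    site: str
    species: str
    parameter: str
    posterior_mean: float
    posterior_sd: float
    guild: str = ""
    continent: str = ""


@dataclass
class FirstBayesPosterior:
    """Retained draws, derived quantities, and convergence diagnostics.

    Parameter draws have shape (chains, n_retained, ...); derived draws of
    the density-dependence index I, the environmental variances C_ii, and
    Prop(I) are computed per draw so each has a full posterior.
    """

    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    converged: bool
    species: list[str]
    site: str = "site"
    guild: list[str] = field(default_factory=list)
    continent: str = ""

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one quantity with chains flattened together."""
        d = self.draws[name]
        return d.reshape((-1,) + d.shape[2:])

    def save_draws(self, path) -> None:
        """Write all retained draws to a compressed .npz archive."""
        np.savez_compressed(
            path,
            species=np.array(self.species),
            site=np.array(self.site),
            **self.draws,
        )


def filter_series(counts: CommunityCounts) -> CommunityCounts:
    """Drop species whose zero-count years make up half or more of the series.

    A species is kept only if its zero years are strictly fewer than T/2.
    """
    T = counts.n_years
    zeros = (counts.counts == 0).sum(axis=0)
    keep = zeros * 2 < T
    dropped = [s for s, ok in zip(counts.species, keep) if not ok]
    for sp, nz in zip(counts.species, zeros):
        if nz * 2 >= T:
            logger.info(
                "site %s: dropping species %s (%d zero years of %d)", counts.site, sp, nz, T
            )
    if not keep.any():
        raise ValueError(f"site {counts.site}: all species dropped by the zero-count filter")
    if keep.all():
        return counts
    idx = np.flatnonzero(keep)
    return CommunityCounts(
        counts=counts.counts[:, idx],
        years=counts.years,
        species=[counts.species[i] for i in idx],
        guild=[counts.guild[i] for i in idx],
        site=counts.site,
        continent=counts.continent,
    )


def prepare_log_counts(counts: CommunityCounts) -> np.ndarray:
    """Log counts with zeros marked missing (NaN); latent states stay modeled."""
    y = np.full(counts.counts.shape, np.nan)
    pos = counts.counts > 0
    y[pos] = np.log(counts.counts[pos])
    return y


def default_k_bounds(y: np.ndarray) -> np.ndarray:
    """Per-species k bounds: mean(y) +/- 2.576 * SD(y) over non-missing values.

    A constant series has SD 0; its bounds fall back to mean +/- 0.5.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    S = y.shape[1]
    bounds = np.empty((S, 2))
    for i in range(S):
        yi = y[:, i][np.isfinite(y[:, i])]
        if yi.size < 2:
            raise ValueError(f"species column {i}: need >= 2 observed values for k bounds")
        m = yi.mean()
        sd = yi.std(ddof=1)
        if sd == 0:
            warnings.warn(
                f"species column {i}: constant log counts, widening k bounds by 0.5",
                stacklevel=2,
            )
            bounds[i] = (m - 0.5, m + 0.5)
        else:
            bounds[i] = (m - 2.576 * sd, m + 2.576 * sd)
    return bounds


def gelman_rubin(chains_of_draws: np.ndarray) -> float:
    """Classic potential scale reduction factor (no rank normalization).

    ``chains_of_draws`` is (m, n): m chains of n draws each. Degenerate
    zero-variance chains return 1.0 with a warning.
    """
    x = np.atleast_2d(np.asarray(chains_of_draws, dtype=float))
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 10:
        raise ValueError("need chains of length >= 10")
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        warnings.warn("zero within-chain variance; returning R-hat = 1.0", stacklevel=2)
        return 1.0
    B_over_n = x.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def _initial_values(y, k_bounds, rng, fixed):
    """Data-informed starting point with per-chain lognormal jitter."""
    T, S = y.shape
    mid = k_bounds.mean(axis=1)
    n0 = np.empty((T, S))
    mu0 = np.empty(S)
    for i in range(S):
        yi = y[:, i]
        good = np.isfinite(yi)
        med = np.median(yi[good]) if good.any() else mid[i]
        mu0[i] = yi[good].mean() if good.any() else mid[i]
        n0[:, i] = np.where(good, yi, med)
    n0 = n0 + 0.05 * rng.standard_normal((T, S))
    # residual SD of first differences, split between process and observation
    sd_guess = np.empty(S)
    for i in range(S):
        yi = y[:, i][np.isfinite(y[:, i])]
        d = np.diff(yi)
        sd_guess[i] = max(0.1, d.std(ddof=1) / np.sqrt(2.0)) if d.size > 1 else 0.3
    vals = {
        "r": 0.674 * np.exp(0.3 * rng.standard_normal(S)),  # half-normal prior median
        "k": np.clip(mid + 0.1 * rng.standard_normal(S), k_bounds[:, 0], k_bounds[:, 1]),
        "delta": 0.3 * np.exp(0.3 * rng.standard_normal(S)),
        "tau": sd_guess * np.exp(0.3 * rng.standard_normal(S)),
        "C": np.diag(sd_guess**2 * np.exp(0.3 * rng.standard_normal(S))),
    }
    for name, v in fixed.items():
        vals[name] = v
    return n0, mu0, vals


def fit_state_space(
    y: np.ndarray,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    *,
    fixed: dict[str, np.ndarray] | None = None,
    species: list[str] | None = None,
    site: str = "site",
    guild: list[str] | None = None,
    continent: str = "",
) -> FirstBayesPosterior:
    """Sample the joint posterior of parameters and latent log abundances.

    Parameters
    ----------
    y : (T, S) array
        Log counts with NaN marking missing (zero-count) observations.
    priors, config : optional
        Default priors derive k bounds from the data; the default schedule
        is the full 4 x 20,000 run.
    fixed : dict, optional
        Any of ``r, k, delta, tau, C`` pinned to known values (used for
        reduced-model checks, e.g. the linear-Gaussian special case). Fixed
        parameters are excluded from the R-hat table.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    T, S = y.shape
    if S < 2 and not (fixed and "C" in fixed):
        raise ValueError("need S >= 2 species (inverse-Wishart prior with df = S)")
    if T < 5:
        raise ValueError("need at least 5 years")
    if priors is None:
        priors = PriorSpec(k_bounds=default_k_bounds(y))
    if config is None:
        config = McmcConfig()
    fixed = dict(fixed or {})
    for name, v in fixed.items():
        if name not in ("r", "k", "delta", "tau", "C"):
            raise ValueError(f"cannot fix unknown parameter {name!r}")
        fixed[name] = np.asarray(v, dtype=float)

    obs = np.isfinite(y)
    y_filled = np.where(obs, y, 0.0)
    n_ret = config.retained_per_chain
    if n_ret < 1:
        raise ValueError("schedule retains no draws")

    root = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % np.uint32(2**31 - 1)) for s in root.spawn(config.chains)]
    jitter_rng = np.random.default_rng(root.spawn(1)[0])

    draws = {
        "n": np.empty((config.chains, n_ret, T, S)),
        "r": np.empty((config.chains, n_ret, S)),
        "k": np.empty((config.chains, n_ret, S)),
        "delta": np.empty((config.chains, n_ret, S)),
        "tau": np.empty((config.chains, n_ret, S)),
        "C": np.empty((config.chains, n_ret, S, S)),
    }
    for ch in range(config.chains):
        n0, mu0, vals = _initial_values(y, priors.k_bounds, jitter_rng, fixed)
        out = _gibbs.run_first_chain(
            y_filled,
            obs,
            np.ascontiguousarray(priors.k_bounds[:, 0]),
            np.ascontiguousarray(priors.k_bounds[:, 1]),
            float(priors.r_scale),
            float(priors.sd_prior_upper),
            float(priors.wishart_df),
            int(config.iterations),
            int(config.burn_in),
            int(config.thin),
            chain_seeds[ch],
            n0,
            np.asarray(vals["r"], dtype=float),
            np.asarray(vals["k"], dtype=float),
            np.asarray(vals["delta"], dtype=float),
            np.asarray(vals["tau"], dtype=float),
            np.asarray(vals["C"], dtype=float),
            "r" in fixed,
            "k" in fixed,
            "delta" in fixed,
            "tau" in fixed,
            "C" in fixed,
            mu0,
            INIT_STATE_SD,
        )
        for key, arr in zip(("n", "r", "k", "delta", "tau", "C"), out):
            draws[key][ch] = arr

    # derived quantities, per draw, via the core-model identities
    var_n = draws["n"].var(axis=2, ddof=1)  # (chains, n_ret, S)
    I = np.empty_like(var_n)
    C_ii = np.empty_like(var_n)
    prop = np.empty_like(var_n)
    for ch in range(config.chains):
        for d in range(n_ret):
            for i in range(S):
                I[ch, d, i] = density_dependence_index(
                    draws["r"][ch, d, i], draws["k"][ch, d, i], var_n[ch, d, i]
                )
                C_ii[ch, d, i] = draws["C"][ch, d, i, i]
                prop[ch, d, i] = prop_density_dependence(I[ch, d, i], C_ii[ch, d, i])
    draws["I"] = I
    draws["C_ii"] = C_ii
    draws["Prop(I)"] = prop

    rhat: dict[str, float] = {}
    free = [p for p in ("r", "k", "delta", "tau") if p not in fixed]
    for name in free:
        for i in range(S):
            rhat[f"{name}[{i}]"] = gelman_rubin(draws[name][:, :, i])
    if "C" not in fixed:
        for i in range(S):
            for j in range(i + 1):
                rhat[f"C[{i},{j}]"] = gelman_rubin(draws["C"][:, :, i, j])
    converged = all(v < config.rhat_threshold for v in rhat.values()) if rhat else True
    if not converged:
        logger.warning(
            "site %s: MCMC not converged (max R-hat %.3f)", site, max(rhat.values())
        )

    if species is None:
        species = [f"sp{i + 1}" for i in range(S)]
    return FirstBayesPosterior(
        draws=draws,
        rhat=rhat,
        converged=converged,
        species=list(species),
        site=site,
        guild=list(guild) if guild is not None else [""] * S,
        continent=continent,
    )


def fit_community(
    counts: CommunityCounts,
    config: McmcConfig | None = None,
    priors: PriorSpec | None = None,
) -> FirstBayesPosterior:
    """Convenience wrapper: filter, log-transform, derive priors, and fit."""
    kept = filter_series(counts)
    y = prepare_log_counts(kept)
    if priors is None:
        priors = PriorSpec(k_bounds=default_k_bounds(y))
    return fit_state_space(
        y,
        priors,
        config,
        species=kept.species,
        site=kept.site,
        guild=kept.guild,
        continent=kept.continent,
    )


def summarize(posterior: FirstBayesPosterior, parameter: str) -> list[ParamSummary]:
    """Posterior mean and SD of one derived parameter, one row per species.

    Means are taken over the derived per-draw values (so, e.g., the mean of
    I is the posterior expectation of (r/k)^2 Var(n), not a plug-in of
    posterior means). Degenerate SDs are floored at 1e-6.
    """
    if parameter not in PARAMETER_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETER_NAMES}")
    vals = posterior.pooled(parameter)  # (draws, S)
    out = []
    for i, sp in enumerate(posterior.species):
        sd = float(vals[:, i].std(ddof=1))
        if sd < 1e-6:
            warnings.warn(
                f"{posterior.site}/{sp}: degenerate posterior SD for {parameter}, flooring at 1e-6",
                stacklevel=2,
            )
            sd = 1e-6
        out.append(
            ParamSummary(
                site=posterior.site,
                species=sp,
                parameter=parameter,
                posterior_mean=float(vals[:, i].mean()),
                posterior_sd=sd,
                guild=posterior.guild[i] if posterior.guild else "",
                continent=posterior.continent,
            )
        )
    return out
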