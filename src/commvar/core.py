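"""Core Gompertz state-space model primitives.

The process model, on the natural-log abundance scale, is

    n[i, t] = n[i, t-1] + r[i] * (1 - n[i, t-1] / k[i]) + eps[i, t]

where ``r`` is the intrinsic growth rate, ``k`` the log carrying capacity,
and the community-wide shock vector ``eps[:, t]`` is multivariate normal
with covariance ``Sigma_t = D_t + C``: a diagonal demographic part
``D_t[i, i] = delta[i]**2 / N[i, t-1]`` that shrinks with abundance, plus a
time-constant environmental covariance ``C`` shared across species.

Two derived scalars summarize each species' dynamics:

* the density-dependence index ``I = (r/k)**2 * Var(n)``, and
* its share of the structured variance ``Prop(I) = I / (I + C[i, i])``.

Everything here is a pure function of arrays; the simulator and the MCMC
fitter both build on these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GompertzParams",
    "CommunityCounts",
    "LatentStates",
    "CovarianceDecomposition",
    "gompertz_step",
    "demographic_variances",
    "total_covariance",
    "density_dependence_index",
    "prop_density_dependence",
]

_PSD_TOL = 1e-10


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class GompertzParams:
    """Full generative parameter set for an S-species community.

    Parameters
    ----------
    r : array-like, shape (S,)
        Intrinsic growth rates, strictly positive (dimensionless).
    k : array-like, shape (S,)
        Natural log of carrying capacity per species (log pairs).
    delta : array-like, shape (S,)
        Demographic SD parameters, >= 0; demographic variance at time t is
        ``delta**2 / N[t-1]``.
    tau : array-like, shape (S,)
        Observation SDs on the log scale, >= 0.
    C : array-like, shape (S, S)
        Environmental covariance matrix (symmetric positive semidefinite).
    """

    r: np.ndarray
    k: np.ndarray
    delta: np.ndarray
    tau: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.r = _as_1d(self.r, "r")
        S = self.r.size
        self.k = _as_1d(self.k, "k")
        self.delta = _as_1d(self.delta, "delta")
        self.tau = _as_1d(self.tau, "tau")
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        for name, vec in (("k", self.k), ("delta", self.delta), ("tau", self.tau)):
            if vec.size != S:
                raise ValueError(f"{name} has length {vec.size}, expected {S}")
        if self.C.shape != (S, S):
            raise ValueError(f"C has shape {self.C.shape}, expected ({S}, {S})")
        if np.any(self.r <= 0):
            raise ValueError("intrinsic growth rates r must be strictly positive")
        if np.any(self.delta < 0) or np.any(self.tau < 0):
            raise ValueError("delta and tau must be non-negative")
        if not np.allclose(self.C, self.C.T, atol=1e-12):
            raise ValueError("environmental covariance C must be symmetric")
        eigs = np.linalg.eigvalsh(self.C)
        if eigs.min() < -_PSD_TOL * max(1.0, eigs.max()):
            raise ValueError("environmental covariance C must be positive semidefinite")
        if np.any(np.diag(self.C) < 0):
            raise ValueError("diagonal of C must be non-negative")

    @property
    def n_species(self) -> int:
        return self.r.size


@dataclass
class CommunityCounts:
    """Observed yearly breeding-pair counts for one site.

    ``counts`` is a (T, S) integer matrix; ``years`` are contiguous calendar
    labels (the model itself only uses their order).
    """

    counts: np.ndarray
    years: np.ndarray
    species: list[str]
    guild: list[str]
    site: str = "site"
    continent: str = "Europe"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a T x S matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        T, S = self.counts.shape
        if T < 3:
            raise ValueError(f"need at least 3 years of counts, got {T}")
        self.years = np.asarray(self.years, dtype=np.int64)
        if self.years.size != T:
            raise ValueError("years must have one entry per row of counts")
        if T > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be contiguous (no gaps, no duplicates)")
        self.species = list(self.species)
        self.guild = list(self.guild)
        if len(self.species) != S or len(self.guild) != S:
            raise ValueError("species and guild labels must match the number of columns")

    @property
    def n_years(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]


@dataclass
class LatentStates:
    """True log abundances n = log N on the same (T, S) grid as the counts."""

    n: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.ndim != 2:
            raise ValueError("latent states must be a T x S matrix")
        if not np.all(np.isfinite(self.n)):
            raise ValueError("latent states must be finite")


@dataclass
class CovarianceDecomposition:
    """One year's shock covariance split into demographic + environmental parts."""

    D_diag: np.ndarray
    C: np.ndarray
    Sigma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.D_diag = _as_1d(self.D_diag, "D_diag")
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if np.any(self.D_diag < 0):
            raise ValueError("demographic variances must be non-negative")
        self.Sigma = total_covariance(self.D_diag, self.C)


def gompertz_step(n_prev, params: GompertzParams, eps) -> np.ndarray:
    """One deterministic-plus-shock step of the log-scale Gompertz map.

    Returns ``n_prev + r * (1 - n_prev / k) + eps`` elementwise. At
    ``n_prev == k`` with no shock the map is at its fixed point.
    """
    n_prev = _as_1d(n_prev, "n_prev")
    eps = _as_1d(eps, "eps")
    S = params.n_species
    if n_prev.size != S or eps.size != S:
        raise ValueError("n_prev and eps must have one entry per species")
    if np.any(params.k == 0):
        raise ValueError("k must be nonzero (growth term divides by k)")
    return n_prev + params.r * (1.0 - n_prev / params.k) + eps


def demographic_variances(delta, N_prev) -> np.ndarray:
    """Demographic variance ``delta**2 / N_prev`` per species.

    ``N_prev`` is the latent abundance exp(n) of the previous year and must be
    strictly positive; the demographic covariance is diagonal by assumption.
    """
    delta = _as_1d(delta, "delta")
    N_prev = _as_1d(N_prev, "N_prev")
    if delta.size != N_prev.size:
        raise ValueError("delta and N_prev must have equal length")
    if np.any(N_prev <= 0):
        raise ValueError("N_prev must be strictly positive (latent abundance)")
    return delta**2 / N_prev


def total_covariance(D_diag, C) -> np.ndarray:
    """Total shock covariance ``Sigma = diag(D_diag) + C``."""
    D_diag = _as_1d(D_diag, "D_diag")
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape != (D_diag.size, D_diag.size):
        raise ValueError(
            f"dimension mismatch: D_diag has length {D_diag.size}, C has shape {C.shape}"
        )
    return np.diag(D_diag) + C


def density_dependence_index(r: float, k: float, var_n: float) -> float:
    """Density-dependence index ``I = (r/k)**2 * Var(n)``.

    ``var_n`` is the temporal variance of the species' log abundance; the
    index measures how much of the year-to-year change is a pullback toward
    the carrying capacity.
    """
    if k == 0:
        raise ValueError("k must be nonzero")
    if var_n < 0:
        raise ValueError("var_n must be non-negative")
    return (r / k) ** 2 * var_n


def prop_density_dependence(I: float, C_ii: float) -> float:
    """Share of structured variance due to density dependence, I / (I + C_ii)."""
    if I < 0 or C_ii < 0:
        raise ValueError("I and C_ii must be non-negative")
    denom = I + C_ii
    if denom == 0:
        raise ValueError("I + C_ii is zero; proportion undefined")
    return I / denom
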