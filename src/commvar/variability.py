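"""Descriptive population-variability metrics.

The PV index is the mean proportional difference over all unordered year
pairs of an abundance series: for abundances z_i, z_j the pair contributes
``D = 1 - min(z_i, z_j) / max(z_i, z_j)``. PV = 0 for a perfectly constant
series and approaches 1 as fluctuations grow without bound. Because D
depends only on ratios, PV is invariant to rescaling the series.

Zero counts need explicit rules: a pair of zeros is "no change" (D = 0),
while a zero paired with a positive count is a maximal change (D = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AbundanceSeries", "population_variability", "lag1_autocorrelation"]


@dataclass
class AbundanceSeries:
    """A single species' abundance time series at one site."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("need a 1-D series with at least 2 years")
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")


def population_variability(series: AbundanceSeries | np.ndarray) -> float:
    """Mean pairwise proportional difference over all T(T-1)/2 year pairs."""
    z = series.values if isinstance(series, AbundanceSeries) else AbundanceSeries(series).values
    lo = np.minimum.outer(z, z)
    hi = np.maximum.outer(z, z)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - lo / hi
    D[hi == 0] = 0.0  # both zero: no change
    iu = np.triu_indices(z.size, k=1)
    return float(D[iu].mean())


def lag1_autocorrelation(series: AbundanceSeries | np.ndarray) -> float:
    """Pearson correlation between the series and itself shifted one year."""
    z = series.values if isinstance(series, AbundanceSeries) else AbundanceSeries(series).values
    if z.size < 3:
        raise ValueError("need at least 3 years for lag-1 autocorrelation")
    a, b = z[:-1], z[1:]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("lag-1 autocorrelation undefined: a slice has zero variance")
    return float(np.corrcoef(a, b)[0, 1])
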