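"""Exponential growth fitting and doubling time.

The dilution null model for stored-lipid decay needs the population
doubling time Td of the actual experiment, derived from its growth
curve.  Growth is fitted log-linearly: ln(density) regressed on time by
ordinary least squares, which is the maximum-likelihood fit under
multiplicative (lognormal) density noise.  mu is the slope (h^-1) and
Td = ln2/mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GrowthCurve", "DoublingTime", "fit_exponential_growth", "doublings_elapsed"]


@dataclass(frozen=True)
class GrowthCurve:
    """Cell-density time series (hours, cells/ml)."""

    timepoints_h: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if t.size != d.size:
            raise ValueError("timepoints and densities must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if d.size and d.min() <= 0:
            raise ValueError("densities must be > 0")
        object.__setattr__(self, "timepoints_h", t)
        object.__setattr__(self, "densities", d)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GrowthCurve":
        return cls(
            timepoints_h=frame["time_h"].to_numpy(),
            densities=frame["density_cells_per_ml"].to_numpy(),
        )

    def truncate_at_maximum(self) -> "GrowthCurve":
        """Drop points after the density maximum (stationary phase)."""
        i = int(np.argmax(self.densities))
        return GrowthCurve(self.timepoints_h[: i + 1], self.densities[: i + 1])


@dataclass(frozen=True)
class DoublingTime:
    """Fitted specific growth rate and doubling time."""

    mu: float  # h^-1
    td: float  # hours, ln2/mu
    residual_se: float  # on the ln(density) scale

    def __post_init__(self) -> None:
        if not math.isclose(self.td * self.mu, math.log(2.0), rel_tol=1e-9):
            raise ValueError("td and mu must satisfy td * mu = ln 2")


def fit_exponential_growth(
    curve: GrowthCurve, exclude_stationary: bool = False
) -> DoublingTime:
    """Least-squares line fit of ln(density) vs time.

    Raises if fewer than 3 points remain or the fitted slope is not
    positive ("non-growing population").  ``exclude_stationary`` first
    drops points after the density maximum.
    """
    if exclude_stationary:
        curve = curve.truncate_at_maximum()
    t, d = curve.timepoints_h, curve.densities
    if t.size < 3:
        raise ValueError("need at least 3 timepoints to fit growth")
    fit = stats.linregress(t, np.log(d))
    mu = float(fit.slope)
    if mu <= 0:
        raise ValueError(f"non-growing population (fitted slope {mu:.3g} <= 0)")
    resid = np.log(d) - (fit.intercept + mu * t)
    residual_se = float(np.sqrt(np.sum(resid**2) / (t.size - 2)))
    return DoublingTime(mu=mu, td=math.log(2.0) / mu, residual_se=residual_se)


def doublings_elapsed(dt: DoublingTime, t: float) -> float:
    """Number of population doublings in ``t`` hours: t / Td."""
    return t / dt.td
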