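"""Growth-dilution null model and kinetic extension for stored-lipid decay.

After substrate (oleate) withdrawal the stored TAG/LD signal per cell
falls.  In a growing population, preformed droplets partitioned to
daughter cells dilute the per-cell signal by half each division even
with no catabolism at all.  The null model is therefore pure dilution,

    T(t) = T0 * 2^(-t/Td),

with Td the population doubling time of the same experiment.  The
kinetic extension adds basal synthesis/uptake ``s`` and a first-order
catabolic rate ``k``:

    dT/dt = s - (mu + k) * T,   s = B * (mu + k),

whose solution is T(t) = B + (T0 - B) * exp(-(mu + k) t): decay at rate
mu + k toward the basal plateau B.  With B = 0 and k = 0 this nests the
pure-dilution curve.  Net catabolism is declared only when the measured
series falls significantly *below* the dilution prediction (one-sided
per-timepoint tests, Holm-adjusted): values at or above the prediction
— including the late plateau above it — are consistent with no net
catabolism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .growth import DoublingTime

__all__ = [
    "DecaySeries",
    "TurnoverParams",
    "predict_dilution",
    "predict_with_basal",
    "fit_turnover",
    "net_catabolism_test",
    "NetCatabolismVerdict",
    "decay_report",
    "DecayReport",
]


@dataclass(frozen=True)
class DecaySeries:
    """Replicated stored-signal time series after withdrawal.

    Signals are normalized so the t = 0 replicate mean is 1 (done at
    construction unless the data already satisfy it).
    """

    timepoints_h: np.ndarray  # (n_time,)
    replicate_signals: np.ndarray  # (n_time, n_replicates)

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        s = np.asarray(self.replicate_signals, dtype=float)
        if s.ndim != 2 or s.shape[0] != t.size:
            raise ValueError("replicate_signals must be (n_time, n_replicates)")
        if t[0] != 0:
            raise ValueError("decay series must include t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if s.min() <= 0:
            raise ValueError("signals must be > 0")
        anchor = s[0].mean()
        if not math.isclose(anchor, 1.0, rel_tol=1e-9):
            s = s / anchor
        object.__setattr__(self, "timepoints_h", t)
        object.__setattr__(self, "replicate_signals", s)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DecaySeries":
        """Build from the tidy ``time_h, replicate, signal`` schema."""
        wide = frame.pivot(index="time_h", columns="replicate", values="signal")
        if wide.isna().any().any():
            raise ValueError("every timepoint needs every replicate")
        return cls(wide.index.to_numpy(dtype=float), wide.to_numpy())

    @property
    def means(self) -> np.ndarray:
        return self.replicate_signals.mean(axis=1)

    @property
    def sems(self) -> np.ndarray:
        n = self.replicate_signals.shape[1]
        if n < 2:
            return np.zeros(self.timepoints_h.size)
        return self.replicate_signals.std(axis=1, ddof=1) / math.sqrt(n)

    @property
    def n_replicates(self) -> int:
        return self.replicate_signals.shape[1]


@dataclass(frozen=True)
class TurnoverParams:
    """Kinetic parameters of the basal-synthesis/catabolism model."""

    s0: float  # initial signal, 1 by normalization
    b: float  # basal asymptote
    mu: float  # growth rate, h^-1, fixed from the growth fit
    k: float  # catabolic rate, h^-1
    b_ci: tuple[float, float] | None = None
    k_ci: tuple[float, float] | None = None
    rss: float | None = None  # weighted RSS of the full fit
    rss_k0: float | None = None  # weighted RSS with k pinned to 0
    b_k0: float | None = None  # basal estimate of the k = 0 fit
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.b < 0 or self.k < 0 or self.mu <= 0:
            raise ValueError("require b >= 0, k >= 0, mu > 0")

    @property
    def synthesis_rate(self) -> float:
        """s = B * (mu + k), the uptake/synthesis inflow in signal/h."""
        return self.b * (self.mu + self.k)

    def to_dict(self) -> dict:
        return {
            "s0": self.s0,
            "b": self.b,
            "mu": self.mu,
            "k": self.k,
            "synthesis_rate": self.synthesis_rate,
            "b_ci": list(self.b_ci) if self.b_ci else None,
            "k_ci": list(self.k_ci) if self.k_ci else None,
            "rss": self.rss,
            "rss_k0": self.rss_k0,
        }


def predict_dilution(s0: float, td, times) -> np.ndarray:
    """Pure division-dilution decay: s0 * 2^(-t/Td).

    ``td`` may be a :class:`~tryplipid.growth.DoublingTime` or the
    doubling time in hours.  This is the 'calculated' curve of the
    null model: each division halves the per-cell content because
    preformed droplets are split between daughters.
    """
    td_h = td.td if isinstance(td, DoublingTime) else float(td)
    if td_h <= 0:
        raise ValueError("doubling time must be > 0")
    times = np.asarray(times, dtype=float)
    return s0 * np.exp2(-times / td_h)


def predict_with_basal(params: TurnoverParams, times) -> np.ndarray:
    """Kinetic model: B + (s0 - B) * exp(-(mu + k) t).

    Reduces to :func:`predict_dilution` when B = 0 and k = 0; constant
    at B when s0 = B (steady state); tends to B as t -> infinity.
    """
    times = np.asarray(times, dtype=float)
    rate = params.mu + params.k
    return params.b + (params.s0 - params.b) * np.exp(-rate * times)


def _wls_fit(
    t: np.ndarray,
    means: np.ndarray,
    weights: np.ndarray,
    mu: float,
    fix_k_zero: bool,
) -> tuple[float, float, float]:
    """Bounded weighted least squares over (b, k); returns (b, k, rss)."""
    sw = np.sqrt(weights)

    if fix_k_zero:

        def resid(p):
            b = p[0]
            return sw * (b + (1.0 - b) * np.exp(-mu * t) - means)

        x0, lb, ub = [min(max(means[-1], 0.0), 0.99)], [0.0], [np.inf]
    else:

        def resid(p):
            b, k = p
            return sw * (b + (1.0 - b) * np.exp(-(mu + k) * t) - means)

        x0, lb, ub = [min(max(means[-1], 0.0), 0.99), 0.0], [0.0, 0.0], [np.inf, np.inf]

    sol = optimize.least_squares(
        resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if not sol.success:
        raise RuntimeError(f"turnover fit did not converge: {sol.message}")
    rss = float(np.sum(sol.fun**2))
    # snap estimates sitting on the non-negativity bound to exactly 0
    b_hat = float(sol.x[0])
    if b_hat < 1e-10:
        b_hat = 0.0
    if fix_k_zero:
        return b_hat, 0.0, rss
    k_hat = float(sol.x[1])
    if k_hat < 1e-10:
        k_hat = 0.0
    return b_hat, k_hat, rss


def fit_turnover(
    series: DecaySeries,
    mu: float | DoublingTime,
    n_boot: int = 1000,
    seed: int = 0,
) -> TurnoverParams:
    """Fit (B, k) of the kinetic model with mu fixed from the growth fit.

    Weighted least squares with weights 1/SEM^2 (equal weights when any
    timepoint SEM is zero, as with noise-free or single-replicate
    data), constrained to B >= 0, k >= 0.  Also fits the nested k = 0
    model and reports both weighted residual sums of squares.
    Percentile bootstrap CIs for B and k come from resampling
    replicates within timepoints; bootstrap refits reuse the original
    weights (resampled SEMs of n = 3 replicates can degenerate to 0).
    """
    mu_h = mu.mu if isinstance(mu, DoublingTime) else float(mu)
    if mu_h <= 0:
        raise ValueError("mu must be > 0")
    t = series.timepoints_h
    if t.size < 4:
        raise ValueError("need at least 4 timepoints to fit turnover")
    means, sems = series.means, series.sems
    weights = 1.0 / sems**2 if np.all(sems > 0) else np.ones_like(means)

    b_hat, k_hat, rss = _wls_fit(t, means, weights, mu_h, fix_k_zero=False)
    b_k0, _, rss_k0 = _wls_fit(t, means, weights, mu_h, fix_k_zero=True)

    b_ci = k_ci = None
    if n_boot > 0 and series.n_replicates > 1:
        rng = np.random.default_rng(seed)
        n_rep = series.n_replicates
        b_boot = np.empty(n_boot)
        k_boot = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(n_rep, size=(t.size, n_rep))
            boot_means = np.take_along_axis(
                series.replicate_signals, idx, axis=1
            ).mean(axis=1)
            boot_means = boot_means / boot_means[0]  # re-anchor t = 0
            b_boot[i], k_boot[i], _ = _wls_fit(
                t, boot_means, weights, mu_h, fix_k_zero=False
            )
        b_ci = tuple(np.quantile(b_boot, [0.025, 0.975]))
        k_ci = tuple(np.quantile(k_boot, [0.025, 0.975]))

    return TurnoverParams(
        s0=1.0,
        b=b_hat,
        mu=mu_h,
        k=k_hat,
        b_ci=b_ci,
        k_ci=k_ci,
        rss=rss,
        rss_k0=rss_k0,
        b_k0=b_k0,
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class NetCatabolismVerdict:
    """Outcome of the measured-vs-dilution comparison."""

    detected: bool
    per_timepoint: pd.DataFrame = field(repr=False)
    alpha: float = 0.05

    @property
    def verdict(self) -> str:
        return "net catabolism detected" if self.detected else "no net catabolism"

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "alpha": self.alpha,
            "per_timepoint": self.per_timepoint.to_dict(orient="records"),
        }


def net_catabolism_test(
    series: DecaySeries, dilution_prediction, alpha: float = 0.05
) -> NetCatabolismVerdict:
    """Is the measured signal ever significantly below pure dilution?

    Per timepoint, a one-sided test of measured mean < predicted using
    the normal approximation on the replicate mean (p = Phi((mean -
    pred)/SEM)); Holm's procedure controls multiplicity across
    timepoints.  Net catabolism is declared only if at least one
    adjusted test rejects — a plateau *above* the prediction never
    triggers it.
    """
    pred = np.asarray(dilution_prediction, dtype=float)
    if pred.shape != series.timepoints_h.shape:
        raise ValueError("prediction must align with the series timepoints")
    means, sems = series.means, series.sems
    pvals = np.where(
        sems > 0,
        stats.norm.cdf((means - pred) / np.where(sems > 0, sems, 1.0)),
        np.where(means < pred, 0.0, 1.0),
    )
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    table = pd.DataFrame(
        {
            "time_h": series.timepoints_h,
            "measured_mean": means,
            "measured_sem": sems,
            "predicted": pred,
            "below_prediction": means < pred,
            "p_value": pvals,
            "p_holm": p_adj,
            "significant": reject,
        }
    )
    return NetCatabolismVerdict(
        detected=bool(reject.any()), per_timepoint=table, alpha=alpha
    )


@dataclass(frozen=True)
class DecayReport:
    """Full decay analysis: dilution curve, kinetic fit, verdict."""

    growth: DoublingTime
    series: DecaySeries = field(repr=False)
    dilution_prediction: np.ndarray = field(repr=False)
    params: TurnoverParams
    verdict: NetCatabolismVerdict

    def to_dict(self) -> dict:
        return {
            "doubling_time_h": self.growth.td,
            "mu": self.growth.mu,
            "growth_residual_se": self.growth.residual_se,
            "turnover": self.params.to_dict(),
            **self.verdict.to_dict(),
        }


def decay_report(
    series: DecaySeries,
    growth_fit: DoublingTime,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> DecayReport:
    """Run the complete decay analysis for one experiment.

    Computes the dilution prediction from the growth-derived doubling
    time, fits the kinetic model with mu fixed, and tests for net
    catabolism against the dilution curve.
    """
    pred = predict_dilution(1.0, growth_fit, series.timepoints_h)
    params = fit_turnover(series, growth_fit, n_boot=n_boot, seed=seed)
    verdict = net_catabolism_test(series, pred, alpha=alpha)
    return DecayReport(
        growth=growth_fit,
        series=series,
        dilution_prediction=pred,
        params=params,
        verdict=verdict,
    )
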