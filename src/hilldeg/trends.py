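"""Replicative-passage trend analysis.

Per-passage posterior estimates of (alpha, theta, gamma) are tested for a
linear trend across passages with inverse-variance weighted least squares;
gamma is analyzed on the log-odds scale log((1-gamma)/gamma), which
linearizes and symmetrizes its (0,1) range (a DECREASING log-odds slope
means gamma is INCREASING over time).  The centrality measures (mean,
median, mode) of the fitted stationary law are tracked across passages and
summarized by a four-parameter logistic fit (floor, ceiling, steepness,
transition passage) with bootstrap confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .distributions import DegradationParams, centralities, stationary_pmf
from .inference import PosteriorChain, posterior_summary

__all__ = [
    "InsufficientDataError",
    "DegenerateFitError",
    "ParamTrajectory",
    "TrendFit",
    "LogisticFit",
    "log_odds_gamma",
    "inverse_log_odds",
    "wls_slope_test",
    "centrality_trajectory",
    "logistic4_fit",
]


class InsufficientDataError(ValueError):
    """Too few passages for the requested trend fit."""


class DegenerateFitError(RuntimeError):
    """The logistic fit failed to converge; a linear fit may be preferable."""


@dataclass(frozen=True)
class ParamTrajectory:
    """One parameter's estimates and posterior sds across passages."""

    passages: np.ndarray
    estimates: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.passages) == len(self.estimates) == len(self.sds)):
            raise ValueError("trajectory fields must have equal length")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError("sds must be positive")


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    slope_se: float
    p_value: float


@dataclass(frozen=True)
class LogisticFit:
    y_min: float
    y_max: float
    steepness: float
    midpoint: float
    x: np.ndarray = field(repr=False)
    band_50: np.ndarray = field(repr=False)  # shape (2, len(x))
    band_95: np.ndarray = field(repr=False)

    def curve(self, x) -> np.ndarray:
        return _logistic4(np.asarray(x, float), self.y_min, self.y_max,
                          self.steepness, self.midpoint)


def log_odds_gamma(gamma: float, sd: float | None = None):
    """log((1 - gamma) / gamma), with optional delta-method sd propagation.

    Strictly decreasing in gamma; zero at gamma = 1/2.  Returns the value,
    or a (value, sd) pair when an input sd is given
    (sd_out = sd_in / (gamma (1 - gamma))).
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must lie strictly in (0, 1), got {gamma!r}")
    val = float(np.log((1.0 - gamma) / gamma))
    if sd is None:
        return val
    return val, float(sd / (gamma * (1.0 - gamma)))


def inverse_log_odds(lam: float) -> float:
    """Inverse of :func:`log_odds_gamma`: gamma = 1 / (1 + exp(lam))."""
    return float(1.0 / (1.0 + np.exp(lam)))


def wls_slope_test(trajectory: ParamTrajectory) -> TrendFit:
    """Weighted least-squares test of zero slope across passages.

    Weights are 1/sd^2; the p-value is the two-sided t test of the slope
    with (number of passages - 2) degrees of freedom.
    """
    x = np.asarray(trajectory.passages, float)
    y = np.asarray(trajectory.estimates, float)
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 passages, got {len(x)}")
    w = 1.0 / np.asarray(trajectory.sds, float) ** 2
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    return TrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
    )


def centrality_trajectory(
    passages: np.ndarray,
    chains: list[PosteriorChain],
    n_max: int = 1000,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean/median/mode of the fitted pmf per passage, with 95% intervals.

    The point value uses the posterior point estimate; the uncertainty is
    the central 95% of each centrality over posterior parameter draws
    pushed through the stationary pmf (the mode is discrete, so the delta
    method would not apply).
    """
    if len(passages) < 2:
        raise InsufficientDataError("need >= 2 passages")
    if len(passages) != len(chains):
        raise ValueError("one chain per passage required")
    rng = np.random.default_rng(seed)
    rows = []
    for p, chain in zip(passages, chains):
        summ = posterior_summary(chain)
        cent = centralities(stationary_pmf(summ["point"], n_max, check_tail=False))
        idx = rng.choice(len(chain), size=min(n_draws, len(chain)), replace=False)
        draws = {"mean": [], "median": [], "mode": []}
        for a, t, g in chain.samples[idx]:
            c = centralities(stationary_pmf(DegradationParams(a, t, g), n_max,
                                            check_tail=False))
            for k in draws:
                draws[k].append(c[k])
        row = {"passage": int(p)}
        for k in ("mean", "median", "mode"):
            lo, hi = np.quantile(draws[k], [0.025, 0.975])
            row[k] = cent[k]
            row[f"{k}_lo"] = float(lo)
            row[f"{k}_hi"] = float(hi)
            row[f"{k}_sd"] = float(np.std(draws[k], ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def _logistic4(x, y_min, y_max, steepness, midpoint):
    return y_min + (y_max - y_min) / (1.0 + np.exp(-steepness * (x - midpoint)))


def logistic4_fit(
    x: np.ndarray,
    y: np.ndarray,
    y_sd: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
) -> LogisticFit:
    """Weighted four-parameter logistic fit with bootstrap confidence bands.

    Fits y = y_min + (y_max - y_min) / (1 + exp(-steepness (x - midpoint)))
    by weighted nonlinear least squares; the 50% and 95% per-passage bands
    come from refitting ``n_boot`` parametric resamples y* ~ N(y, y_sd).
    The fit is canonicalized so y_min <= y_max (the sign of the steepness
    carries the direction).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    y_sd = np.asarray(y_sd, float)
    if len(x) < 5:
        raise InsufficientDataError(f"need >= 5 points, got {len(x)}")

    p0 = [y.min(), y.max(), 1.0, float(np.median(x))]
    try:
        popt, _ = optimize.curve_fit(
            _logistic4, x, y, p0=p0, sigma=y_sd, absolute_sigma=True,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise DegenerateFitError(
            "logistic fit did not converge; consider a linear fit"
        ) from exc
    if popt[0] > popt[1]:  # same curve with ends swapped and slope negated
        popt = [popt[1], popt[0], -popt[2], popt[3]]

    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_boot):
        y_b = y + rng.standard_normal(len(y)) * y_sd
        try:
            pb, _ = optimize.curve_fit(
                _logistic4, x, y_b, p0=popt, sigma=y_sd, absolute_sigma=True,
                maxfev=5000,
            )
            curves.append(_logistic4(x, *pb))
        except RuntimeError:
            continue
    if len(curves) < max(20, n_boot // 10):
        raise DegenerateFitError(
            f"only {len(curves)}/{n_boot} bootstrap refits converged"
        )
    curves_arr = np.array(curves)
    band_50 = np.quantile(curves_arr, [0.25, 0.75], axis=0)
    band_95 = np.quantile(curves_arr, [0.025, 0.975], axis=0)
    # enforce nesting exactly (quantile crossings can occur at float precision)
    band_95 = np.vstack([
        np.minimum(band_95[0], band_50[0]), np.maximum(band_95[1], band_50[1])
    ])
    return LogisticFit(
        y_min=float(popt[0]),
        y_max=float(popt[1]),
        steepness=float(popt[2]),
        midpoint=float(popt[3]),
        x=x,
        band_50=band_50,
        band_95=band_95,
    )
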