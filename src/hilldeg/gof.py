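"""Parametric-bootstrap r-squared goodness of fit.

A model family is fitted to the counts by maximum likelihood and its fit
quality summarized by an r^2 between observed and model bin probabilities
on a fixed-width histogram.  The null distribution of that r^2 — "how well
does the family fit data it actually generated, after refitting?" — is
obtained by resampling datasets of the same size from the fitted pmf and
refitting the same family.  Small observed r^2 relative to this null gives
a small p-value.  This avoids the bias a Kolmogorov-Smirnov test incurs
when the tested parameters are estimated from the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import StationaryPMF, stationary_pmf
from .inference import FitFailureError, fit_ml

__all__ = [
    "UndefinedStatisticError",
    "UnreliableResultError",
    "GoFResult",
    "r2_statistic",
    "bootstrap_gof",
]


class UndefinedStatisticError(ValueError):
    """Too few non-empty bins to define the r^2 statistic."""


class UnreliableResultError(RuntimeError):
    """Too many bootstrap refits failed for the p-value to be trusted."""


@dataclass(frozen=True)
class GoFResult:
    family: str
    r2_observed: float
    r2_null: np.ndarray = field(repr=False)
    p_value: float
    B: int
    seed: int


def _bin_probs(values: np.ndarray, bin_width: int, n_bins: int) -> np.ndarray:
    """Sum a per-count vector into fixed-width bins over [0, n_max]."""
    edges = np.arange(0, n_bins * bin_width + 1, bin_width)[:-1]
    return np.add.reduceat(values, edges)


def r2_statistic(
    counts: np.ndarray, pmf: StationaryPMF, bin_width: int = 20
) -> float:
    """r^2 between observed bin relative frequencies and model bin probabilities.

    The support [0, n_max] is cut into fixed-width bins; r^2 = 1 -
    SS_res/SS_tot with SS_tot taken around the mean observed bin frequency.
    Depends on the counts only through their histogram.
    """
    counts = np.asarray(counts)
    if counts.min() < 0 or counts.max() > pmf.n_max:
        raise ValueError(f"counts outside pmf support [0, {pmf.n_max}]")
    n_bins = int(np.ceil((pmf.n_max + 1) / bin_width))
    obs_hist = np.bincount(counts // bin_width, minlength=n_bins).astype(float)
    if np.count_nonzero(obs_hist) < 3:
        raise UndefinedStatisticError(
            f"only {np.count_nonzero(obs_hist)} non-empty bins; need >= 3"
        )
    obs = obs_hist / counts.size
    model = _bin_probs(pmf.probs, bin_width, n_bins)
    ss_res = float(np.sum((obs - model) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        # perfectly flat observed histogram: the statistic degenerates to
        # an all-or-nothing comparison
        if ss_res == 0.0:
            return 1.0
        raise UndefinedStatisticError(
            "observed bin frequencies are all equal; r^2 undefined"
        )
    return 1.0 - ss_res / ss_tot


def _sample_from_pmf(pmf: StationaryPMF, n: int, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(pmf.probs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n)).astype(int)


def bootstrap_gof(
    counts: np.ndarray,
    family: str = "gnb",
    B: int = 1000,
    seed: int = 0,
    bin_width: int = 20,
    n_max: int = 1000,
    max_failure_frac: float = 0.05,
) -> GoFResult:
    """Parametric-bootstrap p-value for the fit of one model family.

    Fit by ML, compute the observed r^2, then for b = 1..B draw a dataset
    of the same size from the fitted pmf, refit the SAME family (seeded at
    the original fit, standard parametric-bootstrap practice) and record
    its r^2.  The one-sided lower-tail p-value with add-one correction is

        p = (1 + #{b : r2_null[b] <= r2_observed}) / (B + 1)

    so a fit much worse than the family achieves on its own data gives a
    small p.  Deterministic under a fixed seed.
    """
    counts = np.asarray(counts)
    fit = fit_ml(counts, family, n_max=n_max)
    pmf_hat = stationary_pmf(fit.params_hat, n_max, check_tail=False)
    r2_obs = r2_statistic(counts, pmf_hat, bin_width)

    rng = np.random.default_rng(seed)
    r2_null = []
    failures = 0
    for _ in range(B):
        sample = _sample_from_pmf(pmf_hat, counts.size, rng)
        try:
            refit = fit_ml(sample, family, n_max=n_max, starts=[fit.params_hat])
            pmf_b = stationary_pmf(refit.params_hat, n_max, check_tail=False)
            r2_null.append(r2_statistic(sample, pmf_b, bin_width))
        except (FitFailureError, UndefinedStatisticError):
            failures += 1
    if failures > max_failure_frac * B:
        raise UnreliableResultError(
            f"{failures}/{B} bootstrap refits failed (> {max_failure_frac:.0%})"
        )
    r2_null_arr = np.array(r2_null)
    b_eff = len(r2_null_arr)
    p = (1.0 + np.sum(r2_null_arr <= r2_obs)) / (b_eff + 1.0)
    return GoFResult(
        family=family,
        r2_observed=r2_obs,
        r2_null=r2_null_arr,
        p_value=float(p),
        B=b_eff,
        seed=seed,
    )
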