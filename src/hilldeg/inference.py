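"""Likelihood, maximum-likelihood fitting and adaptive-Metropolis sampling.

Two model families are fitted to count data: the standard negative
binomial ("nb", Michaelis-Menten degradation, alpha pinned at 1, k=2 free
parameters) and the generalized negative binomial ("gnb", Hill degradation,
k=3).  The likelihood is the truncated stationary pmf evaluated once per
parameter triple and shared across the whole dataset through its count
histogram.

The posterior is explored with an adaptive random-walk Metropolis sampler:
Gaussian proposals whose covariance is learned from the chain history
during burn-in (scaled by 2.38^2/3, the standard optimal-scaling factor
for a 3-dimensional target) and frozen afterwards to preserve ergodicity.
The prior is flat on a bounded box (gamma in (0,1), theta in (0, 2000),
alpha in (0, 10]), which makes the flat prior proper without constraining
realistic fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .distributions import (
    DEFAULT_N_MAX,
    DegradationParams,
    StationaryPMF,
    log_weight_sequence,
)
from scipy.special import logsumexp

__all__ = [
    "SupportError",
    "FitFailureError",
    "FitResult",
    "MCMCSettings",
    "PosteriorChain",
    "ALPHA_MAX",
    "THETA_MAX",
    "log_likelihood",
    "fit_ml",
    "information_criteria",
    "delta_criteria",
    "run_adaptive_metropolis",
    "posterior_summary",
]

ALPHA_MAX = 10.0
THETA_MAX = 2000.0


class SupportError(ValueError):
    """Counts fall outside the truncated support of the model."""


class FitFailureError(RuntimeError):
    """No optimizer start converged to a finite maximum."""


# ---------------------------------------------------------------------------
# likelihood

# small cache of log-pmfs keyed by quantized parameters; mostly pays off in
# bootstrap refits and multi-start optimization revisiting identical triples
_PMF_CACHE: dict[tuple, np.ndarray] = {}
_PMF_CACHE_MAX = 2048


def _log_pmf(alpha: float, theta: float, gamma: float, n_max: int) -> np.ndarray:
    key = (round(alpha, 12), round(theta, 12), round(gamma, 12), n_max)
    hit = _PMF_CACHE.get(key)
    if hit is not None:
        return hit
    lw = log_weight_sequence(DegradationParams(alpha, theta, gamma), n_max)
    lp = lw - logsumexp(lw)
    if len(_PMF_CACHE) >= _PMF_CACHE_MAX:
        _PMF_CACHE.clear()
    _PMF_CACHE[key] = lp
    return lp


def _histogram(counts: np.ndarray, n_max: int) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    if counts.min() < 0 or counts.max() > n_max:
        raise SupportError(
            f"counts must lie in [0, {n_max}]; got range "
            f"[{counts.min()}, {counts.max()}]"
        )
    return np.bincount(counts.astype(int), minlength=n_max + 1).astype(float)


def log_likelihood(
    counts: np.ndarray, params: DegradationParams, n_max: int = DEFAULT_N_MAX
) -> float:
    """Sum of log stationary-pmf values over the dataset.

    One pmf evaluation is shared across all observations via the count
    histogram, so the cost is O(n_max + len(counts)).
    """
    hist = _histogram(counts, n_max)
    return float(hist @ _log_pmf(*params.as_tuple(), n_max))


# ---------------------------------------------------------------------------
# maximum likelihood

def _to_unconstrained(alpha: float, theta: float, gamma: float) -> np.ndarray:
    return np.array(
        [logit(alpha / ALPHA_MAX), logit(theta / THETA_MAX), logit(gamma)]
    )


def _from_unconstrained(x: np.ndarray) -> tuple[float, float, float]:
    return (
        float(ALPHA_MAX * expit(x[0])),
        float(THETA_MAX * expit(x[1])),
        float(expit(x[2])),
    )


def _nb_moment_init(counts: np.ndarray) -> tuple[float, float]:
    """Method-of-moments start for (theta, gamma) of the alpha=1 family.

    The negative binomial has mean m = gamma (theta+1) / (1-gamma) and
    variance v = m / (1-gamma), so gamma = 1 - m/v.
    """
    m = float(np.mean(counts))
    v = float(np.var(counts))
    if v > m > 0:
        gamma0 = float(np.clip(1.0 - m / v, 0.02, 0.98))
    else:
        gamma0 = 0.5
    theta0 = m * (1.0 - gamma0) / gamma0 - 1.0
    theta0 = float(np.clip(theta0, 0.5, THETA_MAX * 0.95))
    return theta0, gamma0


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit with information criteria."""

    family: str  # "nb" | "gnb"
    params_hat: DegradationParams
    log_likelihood: float
    k: int
    n: int
    aic: float
    bic: float
    aicc: float

    def to_dict(self) -> dict:
        a, t, g = self.params_hat.as_tuple()
        return {
            "family": self.family,
            "alpha": a,
            "theta": t,
            "gamma": g,
            "log_likelihood": self.log_likelihood,
            "k": self.k,
            "n": self.n,
            "aic": self.aic,
            "bic": self.bic,
            "aicc": self.aicc,
        }


def _make_fit_result(
    family: str, params: DegradationParams, ll: float, n: int
) -> FitResult:
    k = 2 if family == "nb" else 3
    aic = 2 * k - 2 * ll
    bic = float(k * np.log(n) - 2 * ll)
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n > k + 1 else float("nan")
    return FitResult(family, params, ll, k, n, aic, bic, aicc)


def fit_ml(
    counts: np.ndarray,
    family: str = "gnb",
    n_max: int = DEFAULT_N_MAX,
    starts: list[DegradationParams] | None = None,
) -> FitResult:
    """Constrained maximum-likelihood fit by multi-start Nelder-Mead.

    The nb family pins alpha = 1 and optimizes (theta, gamma); the gnb
    family optimizes all three parameters.  Default starts: a
    method-of-moments negative-binomial initialization for (theta, gamma),
    crossed with alpha in {1, 2, 3} for gnb (the alpha=1 start seeded at
    the nb solution, which also enforces the nested-model inequality
    max ll(gnb) >= max ll(nb)).

    Parameters
    ----------
    starts : optional explicit list of starting parameter triples
        (bootstrap refits pass the original fit as a single start).
    """
    counts = np.asarray(counts)
    if family not in ("nb", "gnb"):
        raise ValueError(f"family must be 'nb' or 'gnb', got {family!r}")
    if counts.size < 10:
        raise ValueError(f"need >= 10 observations, got {counts.size}")
    hist = _histogram(counts, n_max)
    n = int(counts.size)

    if family == "nb":

        def neg_ll(x2: np.ndarray) -> float:
            theta = THETA_MAX * expit(x2[0])
            gamma = expit(x2[1])
            if not (0 < theta < THETA_MAX and 0 < gamma < 1):
                return np.inf
            return -float(hist @ _log_pmf(1.0, theta, gamma, n_max))

        if starts is None:
            theta0, gamma0 = _nb_moment_init(counts)
            start_list = [(theta0, gamma0), (theta0 * 2, gamma0 * 0.8)]
        else:
            start_list = [(p.theta, p.gamma) for p in starts]
        best = None
        for theta0, gamma0 in start_list:
            x0 = np.array([logit(theta0 / THETA_MAX), logit(gamma0)])
            res = optimize.minimize(
                neg_ll, x0, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None or not np.isfinite(best.fun):
            raise FitFailureError(f"nb fit failed from all starts (n={n})")
        theta = float(THETA_MAX * expit(best.x[0]))
        gamma = float(expit(best.x[1]))
        params = DegradationParams(1.0, theta, gamma)
        return _make_fit_result("nb", params, -float(best.fun), n)

    # gnb
    def neg_ll3(x: np.ndarray) -> float:
        alpha, theta, gamma = _from_unconstrained(x)
        if not (0 < alpha <= ALPHA_MAX and 0 < theta < THETA_MAX and 0 < gamma < 1):
            return np.inf
        return -float(hist @ _log_pmf(alpha, theta, gamma, n_max))

    if starts is None:
        theta0, gamma0 = _nb_moment_init(counts)
        try:
            nb_fit = fit_ml(counts, "nb", n_max=n_max)
            nb_start = (1.0, nb_fit.params_hat.theta, nb_fit.params_hat.gamma)
        except FitFailureError:
            nb_start = (1.0, theta0, gamma0)
        start_list = [nb_start, (2.0, theta0, gamma0), (3.0, theta0, gamma0)]
    else:
        start_list = [p.as_tuple() for p in starts]

    best = None
    for a0, t0, g0 in start_list:
        x0 = _to_unconstrained(min(a0, ALPHA_MAX * 0.99), t0, g0)
        res = optimize.minimize(
            neg_ll3, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitFailureError(f"gnb fit failed from all starts (n={n})")
    params = DegradationParams(*_from_unconstrained(best.x))
    return _make_fit_result("gnb", params, -float(best.fun), n)


def information_criteria(fit: FitResult) -> dict[str, float]:
    """AIC, BIC and small-sample-corrected AICc of a converged fit."""
    if fit.n <= fit.k + 1:
        raise ValueError(f"AICc undefined for n={fit.n} <= k+1={fit.k + 1}")
    return {"aic": fit.aic, "bic": fit.bic, "aicc": fit.aicc}


def delta_criteria(fit_gnb: FitResult, fit_nb: FitResult) -> dict[str, float]:
    """Differences gnb - nb; negative values favor the generalized model."""
    return {
        "delta_aic": fit_gnb.aic - fit_nb.aic,
        "delta_bic": fit_gnb.bic - fit_nb.bic,
        "delta_aicc": fit_gnb.aicc - fit_nb.aicc,
    }


# ---------------------------------------------------------------------------
# adaptive Metropolis

@dataclass(frozen=True)
class MCMCSettings:
    """Settings of the adaptive Metropolis run (defaults: 2e5 steps,
    1e5 burn-in, thinning 10)."""

    steps: int = 200_000
    burn_in: int = 100_000
    thin: int = 10
    seed: int = 0
    adapt_interval: int = 100
    adapt_scale: float = 2.38**2 / 3.0

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.steps):
            raise ValueError("require 0 < burn_in < steps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def reduced(cls, seed: int = 0, steps: int = 10_000, burn_in: int = 5_000,
                thin: int = 5) -> "MCMCSettings":
        """Short-chain profile for simulation studies and tests."""
        return cls(steps=steps, burn_in=burn_in, thin=thin, seed=seed)


@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples of (alpha, theta, gamma)."""

    samples: np.ndarray  # shape (n_retained, 3)
    log_likelihoods: np.ndarray
    acceptance_rate: float
    settings: MCMCSettings

    def __len__(self) -> int:
        return len(self.samples)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=["alpha", "theta", "gamma"])
        df.insert(0, "step", np.arange(len(df)))
        df["loglik"] = self.log_likelihoods
        return df


# The likelihood surface of the three-parameter model is a long, curved
# ridge: (alpha, theta, gamma) combinations sharing the same balance point
# theta (gamma/(1-gamma))^(1/alpha) and local width are nearly equally
# likely.  A random walk directly on (alpha, theta, gamma) mixes poorly
# along that ridge, so the sampler walks in ridge-aligned coordinates
#   v = (log alpha, log m, log s2),
#   m  = theta (gamma/(1-gamma))^(1/alpha)      (deterministic balance point)
#   s2 = m / (alpha (1 - gamma))                (local Gaussian variance)
# with the Jacobian correction that keeps the prior flat on the original
# parameters inside the bounded box.


def _v_to_params(v: np.ndarray) -> tuple[float, float, float] | None:
    alpha = np.exp(v[0])
    m = np.exp(v[1])
    s2 = np.exp(v[2])
    one_m_g = m / (alpha * s2)
    if not 0.0 < one_m_g < 1.0:
        return None
    gamma = 1.0 - one_m_g
    theta = m * ((1.0 - gamma) / gamma) ** (1.0 / alpha)
    if not (0 < alpha <= ALPHA_MAX and 0 < theta < THETA_MAX):
        return None
    return float(alpha), float(theta), float(gamma)


def _params_to_v(alpha: float, theta: float, gamma: float) -> np.ndarray:
    m = theta * (gamma / (1.0 - gamma)) ** (1.0 / alpha)
    s2 = m / (alpha * (1.0 - gamma))
    return np.array([np.log(alpha), np.log(m), np.log(s2)])


def _log_jacobian(v: np.ndarray, eps: float = 1e-5) -> float:
    """log |det d(alpha,theta,gamma)/dv| by central differences."""
    J = np.empty((3, 3))
    for j in range(3):
        vp = v.copy()
        vp[j] += eps
        vm = v.copy()
        vm[j] -= eps
        pp = _v_to_params(vp)
        pm = _v_to_params(vm)
        if pp is None or pm is None:
            return -np.inf
        J[:, j] = (np.array(pp) - np.array(pm)) / (2.0 * eps)
    sign, logdet = np.linalg.slogdet(J)
    return logdet if sign > 0 else -np.inf


def run_adaptive_metropolis(
    counts: np.ndarray,
    settings: MCMCSettings,
    init: DegradationParams | None = None,
    n_max: int = DEFAULT_N_MAX,
) -> PosteriorChain:
    """Adaptive random-walk Metropolis targeting the flat-prior posterior.

    Gaussian proposals in ridge-aligned coordinates (see module comment);
    the proposal covariance is re-estimated from the second half of the
    chain history every ``adapt_interval`` steps during burn-in (scaled by
    2.38^2/3) and frozen afterwards to preserve ergodicity.  Proposals
    outside the bounded prior box are rejected.  Deterministic under a
    fixed seed.

    ``init`` defaults to the gnb maximum-likelihood fit.
    """
    counts = np.asarray(counts)
    hist = _histogram(counts, n_max)
    if init is None:
        init = fit_ml(counts, "gnb", n_max=n_max).params_hat

    def log_post(v: np.ndarray):
        p = _v_to_params(v)
        if p is None:
            return -np.inf, None, np.nan
        ll = float(hist @ _log_pmf(*p, n_max))
        return ll + _log_jacobian(v), p, ll

    rng = np.random.default_rng(settings.seed)
    # a boundary MLE (theta or gamma saturated) breaks the Jacobian
    # stencil; try progressively safer interior starts — the burn-in walks
    # back to the high-density region in any case
    m0 = float(np.mean(counts)) if np.mean(counts) > 1 else 2.0
    theta_mm, gamma_mm = _nb_moment_init(counts)
    candidates = [
        (np.clip(init.alpha, 1e-2, ALPHA_MAX * 0.99),
         np.clip(init.theta, 1e-1, THETA_MAX * 0.999),
         np.clip(init.gamma, 1e-4, 1 - 1e-4)),
        (np.clip(init.alpha, 0.05, 9.5),
         np.clip(init.theta, 1.0, THETA_MAX * 0.9),
         np.clip(init.gamma, 1e-2, 1 - 1e-2)),
        (1.0, theta_mm, gamma_mm),
        (2.0, m0, 0.5),
    ]
    lp = -np.inf
    for cand in candidates:
        v = _params_to_v(*(float(c) for c in cand))
        lp, p_cur, ll_cur = log_post(v)
        if np.isfinite(lp):
            break
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")

    chol = np.linalg.cholesky(np.diag([0.05, 0.001, 0.01]))
    history = np.empty((settings.steps, 3))
    n_keep = (settings.steps - settings.burn_in) // settings.thin
    kept = np.empty((n_keep, 3))
    kept_ll = np.empty(n_keep)
    accepted_post = 0
    post_steps = 0
    k = 0
    jitter = 1e-10 * np.eye(3)

    for step in range(settings.steps):
        prop = v + chol @ rng.standard_normal(3)
        lp_prop, p_prop, ll_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            v, lp, p_cur, ll_cur = prop, lp_prop, p_prop, ll_prop
            if step >= settings.burn_in:
                accepted_post += 1
        history[step] = v
        if step >= settings.burn_in:
            post_steps += 1
            if (step - settings.burn_in) % settings.thin == 0 and k < n_keep:
                kept[k] = p_cur
                kept_ll[k] = ll_cur
                k += 1
        elif (
            step + 1 >= 2 * settings.adapt_interval
            and (step + 1) % settings.adapt_interval == 0
        ):
            # second half of the history: discards the initial transient
            lo = (step + 1) // 2
            emp = np.cov(history[lo: step + 1].T)
            try:
                chol = np.linalg.cholesky(settings.adapt_scale * emp + jitter)
            except np.linalg.LinAlgError:
                pass  # keep previous proposal on degenerate history

    acc_rate = accepted_post / max(post_steps, 1)
    if acc_rate < 0.01:
        warnings.warn(
            f"post-burn-in acceptance rate {acc_rate:.3%} < 1%: chain may "
            "not have mixed", stacklevel=2,
        )
    return PosteriorChain(
        samples=kept[:k],
        log_likelihoods=kept_ll[:k],
        acceptance_rate=acc_rate,
        settings=settings,
    )


def _hpd_interval(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the samples."""
    xs = np.sort(x)
    m = int(np.ceil(prob * len(xs)))
    if m >= len(xs):
        return float(xs[0]), float(xs[-1])
    widths = xs[m:] - xs[: len(xs) - m]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + m])


def posterior_summary(chain: PosteriorChain) -> dict:
    """Point estimate (highest-likelihood retained sample), per-parameter
    sd, central and highest-posterior-density 95% intervals, and the
    parameter correlation matrix.

    The HPD interval is reported alongside the central one because the
    ridge-shaped posterior leaves the marginals strongly skewed; the
    equal-tailed interval then cuts into the high-density edge.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    s = chain.samples
    i_best = int(np.argmax(chain.log_likelihoods))
    point = DegradationParams(*s[i_best])
    names = ("alpha", "theta", "gamma")
    sd = {nm: float(np.std(s[:, j], ddof=1)) if len(s) > 1 else 0.0
          for j, nm in enumerate(names)}
    ci = {
        nm: (float(np.quantile(s[:, j], 0.025)), float(np.quantile(s[:, j], 0.975)))
        for j, nm in enumerate(names)
    }
    hpd = {nm: _hpd_interval(s[:, j]) for j, nm in enumerate(names)}
    if len(s) > 1 and all(v > 0 for v in sd.values()):
        corr = np.corrcoef(s.T)
    else:
        corr = np.eye(3)
    return {"point": point, "sd": sd, "ci95": ci, "hpd95": hpd, "corr": corr,
            "log_likelihood": float(chain.log_likelihoods[i_best])}


def profile_interval(
    counts: np.ndarray,
    fit: FitResult,
    param: str,
    level: float = 0.95,
    n_max: int = DEFAULT_N_MAX,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one gnb parameter.

    The interval is the set of values whose profile deviance
    ``2 (ll_max - max_other ll)`` stays below the chi-square(1) quantile;
    endpoints are found by stepping outward from the MLE and bisecting.
    Ends clipped at the prior box count as open (the bound is returned).
    """
    from scipy.stats import chi2

    counts = np.asarray(counts)
    hist = _histogram(counts, n_max)
    names = ("alpha", "theta", "gamma")
    if param not in names:
        raise ValueError(f"param must be one of {names}")
    idx = names.index(param)
    crit = chi2.ppf(level, df=1)
    hat = np.array(fit.params_hat.as_tuple())
    lo_bound, hi_bound = {
        "alpha": (1e-3, ALPHA_MAX),
        "theta": (1e-2, THETA_MAX * (1 - 1e-9)),
        "gamma": (1e-6, 1 - 1e-6),
    }[param]

    free = [j for j in range(3) if j != idx]

    def profile_ll(value: float, start: np.ndarray) -> float:
        # free parameters optimized on log scale (alpha, theta) or logit
        # scale (gamma) so the search stays inside the domain
        def neg(x2):
            p = np.empty(3)
            p[idx] = value
            for pos, j in enumerate(free):
                p[j] = expit(x2[pos]) if j == 2 else np.exp(x2[pos])
            alpha, theta, gamma = p
            if not (0 < alpha <= ALPHA_MAX and 0 < theta < THETA_MAX
                    and 0 < gamma < 1):
                return np.inf
            return -float(hist @ _log_pmf(alpha, theta, gamma, n_max))

        x0 = np.array([
            logit(start[j]) if j == 2 else np.log(start[j]) for j in free
        ])
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-7,
                                         "maxiter": 1500})
        return -float(res.fun)

    def deviance(value: float) -> float:
        return 2.0 * (fit.log_likelihood - profile_ll(value, hat))

    def find_end(direction: int) -> float:
        bound = hi_bound if direction > 0 else lo_bound
        step = 1.15 if direction > 0 else 1 / 1.15
        x_in = hat[idx]
        x = x_in * step
        for _ in range(120):
            if (direction > 0 and x >= bound) or (direction < 0 and x <= bound):
                if deviance(bound) < crit:
                    return bound
                x = bound
                break
            if deviance(x) > crit:
                break
            x_in = x
            x *= step
        try:
            return float(optimize.brentq(
                lambda t: deviance(t) - crit, min(x_in, x), max(x_in, x),
                xtol=1e-4 * max(abs(hat[idx]), 1e-3)))
        except ValueError:
            return float(x)

    lo_end, hi_end = find_end(-1), find_end(+1)
    # numerical root finding can land an endpoint a hair inside the MLE
    return min(lo_end, hat[idx]), max(hi_end, hat[idx])
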