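"""Stationary-distribution module: closed forms, invariants, oracles."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from scipy.special import gammaln

from hilldeg.distributions import (
    DegradationParams,
    GammaBurstParams,
    ParameterError,
    StationaryPMF,
    TruncationError,
    centralities,
    closed_form_pmf_alpha1,
    deterministic_mode,
    gamma_burst_density,
    log_weight_sequence,
    stationary_pmf,
)


# ---------------------------------------------------------------------------
# log-weight recurrence

def test_log_weight_empty_product_is_zero():
    lw = log_weight_sequence(DegradationParams(3.0, 7.0, 0.4), 0)
    assert lw.shape == (1,)
    assert lw[0] == 0.0


def test_log_weight_single_term_hill():
    # one step of the recurrence: w_1 = gamma * (theta^a + 1) / 1
    lw = log_weight_sequence(DegradationParams(2.0, 100.0, 0.9), 1)
    assert lw[1] == pytest.approx(np.log(0.9) + np.log(100.0**2 + 1.0), rel=1e-12)


def test_log_weight_alpha1_binomial_closed_form():
    # alpha=1, integer theta: w_n = C(theta+n, n) gamma^n
    theta, gamma = 2.0, 0.5
    lw = log_weight_sequence(DegradationParams(1.0, theta, gamma), 5)
    for n in range(6):
        expected = (
            gammaln(theta + n + 1) - gammaln(n + 1) - gammaln(theta + 1)
            + n * np.log(gamma)
        )
        assert lw[n] == pytest.approx(expected, abs=1e-10)
    assert lw[2] == pytest.approx(np.log(6 * 0.25), abs=1e-12)


# ---------------------------------------------------------------------------
# stationary pmf

GRID = [
    DegradationParams(a, t, g)
    for a, t, g in [
        (1.0, 1.0, 0.3), (1.0, 2.0, 0.5), (1.0, 5.0, 0.8),
        (2.0, 50.0, 0.6), (2.0, 250.0, 0.8), (3.0, 40.0, 0.7),
    ]
]


@pytest.mark.parametrize("params", GRID, ids=str)
def test_pmf_normalized_and_detailed_balance(params):
    pmf = stationary_pmf(params, 2000)
    assert pmf.probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(pmf.probs >= 0)
    n = np.arange(1, 2001, dtype=float)
    r_n = 1.0 / (1.0 + (params.theta / n) ** params.alpha)
    lhs = pmf.probs[1:] * r_n
    rhs = pmf.probs[:-1] * params.gamma
    mask = rhs > 1e-300  # below that, both sides are numerically zero
    assert np.max(np.abs(lhs[mask] - rhs[mask]) / rhs[mask]) < 1e-9


@pytest.mark.parametrize("theta", [1.0, 2.0, 5.0])
@pytest.mark.parametrize("gamma", [0.3, 0.5, 0.8])
def test_p0_matches_appendix_closed_form(theta, gamma):
    # summing the negative binomial weights gives P0 = (1-gamma)^(theta+1)
    pmf = stationary_pmf(DegradationParams(1.0, theta, gamma), 2000)
    expected = (1.0 - gamma) ** (theta + 1.0)
    assert abs(pmf.probs[0] - expected) <= pmf.truncation_tail_mass + 1e-12


@pytest.mark.parametrize("theta", [1.0, 2.5, 5.0])
@pytest.mark.parametrize("gamma", [0.3, 0.8])
def test_alpha1_recurrence_equals_closed_form(theta, gamma):
    # the general recurrence at alpha=1 must reproduce the negative
    # binomial elementwise (gamma-function form admits real theta)
    pmf = stationary_pmf(DegradationParams(1.0, theta, gamma), 1500)
    cf = closed_form_pmf_alpha1(theta, gamma, 1500)
    np.testing.assert_allclose(pmf.probs, cf, rtol=1e-9, atol=1e-300)


def test_alpha1_matches_scipy_nbinom():
    # independent route: nbinom(r=theta+1, p=1-gamma) on integer theta
    theta, gamma = 4.0, 0.6
    pmf = stationary_pmf(DegradationParams(1.0, theta, gamma), 1500)
    n = np.arange(301)
    expected = stats.nbinom.pmf(n, theta + 1.0, 1.0 - gamma)
    np.testing.assert_allclose(pmf.probs[:301], expected, rtol=1e-8)


def test_truncation_error_when_support_too_small():
    # mean ~4500 cannot fit in 200 states
    with pytest.raises(TruncationError):
        stationary_pmf(DegradationParams(1.0, 500.0, 0.9), 200)


def test_check_tail_false_returns_renormalized_pmf():
    pmf = stationary_pmf(DegradationParams(1.0, 500.0, 0.9), 200,
                         check_tail=False)
    assert pmf.probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert pmf.tail_flagged


@pytest.mark.parametrize(
    "alpha,theta,gamma",
    [(0.0, 1.0, 0.5), (-1.0, 1.0, 0.5), (1.0, 0.0, 0.5), (1.0, -2.0, 0.5),
     (1.0, 1.0, 0.0), (1.0, 1.0, 1.0), (1.0, 1.0, 1.2), (np.nan, 1.0, 0.5)],
)
def test_invalid_params_rejected(alpha, theta, gamma):
    with pytest.raises(ParameterError):
        DegradationParams(alpha, theta, gamma)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    alpha=st.floats(0.8, 4.0),
    theta=st.floats(1.0, 150.0),
    gamma=st.floats(0.05, 0.85),
)
def test_detailed_balance_property(alpha, theta, gamma):
    params = DegradationParams(alpha, theta, gamma)
    assume(deterministic_mode(params) < 1200)
    pmf = stationary_pmf(params, 4000)
    n = np.arange(1, 4001, dtype=float)
    r_n = 1.0 / (1.0 + (theta / n) ** alpha)
    lhs = pmf.probs[1:] * r_n
    rhs = pmf.probs[:-1] * gamma
    mask = rhs > 1e-280
    assert np.max(np.abs(lhs[mask] - rhs[mask]) / rhs[mask]) < 1e-9


def test_mean_strictly_increasing_in_gamma():
    means = []
    for gamma in (0.3, 0.45, 0.6, 0.75, 0.9):
        pmf = stationary_pmf(DegradationParams(2.0, 60.0, gamma), 2000)
        means.append(centralities(pmf)["mean"])
    assert np.all(np.diff(means) > 0)


# ---------------------------------------------------------------------------
# mode and centralities

def test_deterministic_mode_examples():
    assert deterministic_mode(DegradationParams(1.0, 200.0, 0.6)) == pytest.approx(300.0)
    assert deterministic_mode(DegradationParams(2.0, 200.0, 0.9)) == pytest.approx(600.0)
    for alpha in (0.7, 1.0, 3.0):
        assert deterministic_mode(
            DegradationParams(alpha, 123.0, 0.5)
        ) == pytest.approx(123.0)


@pytest.mark.parametrize(
    "params", [DegradationParams(2.0, 200.0, 0.9),
               DegradationParams(2.0, 250.0, 0.8),
               DegradationParams(1.0, 50.0, 0.7)], ids=str,
)
def test_pmf_argmax_agrees_with_deterministic_mode(params):
    pmf = stationary_pmf(params, 1000)
    # ties at the balance point resolve to the smaller index
    assert abs(np.argmax(pmf.probs) - deterministic_mode(params)) <= 1.0 + 1e-9


def test_centralities_degenerate_point_mass():
    probs = np.zeros(11)
    probs[5] = 1.0
    pmf = StationaryPMF(
        params=DegradationParams(1.0, 1.0, 0.5), n_max=10,
        probs=probs, log_probs=np.log(probs + 1e-300),
        truncation_tail_mass=0.0,
    )
    c = centralities(pmf)
    assert c == {"mean": 5.0, "median": 5, "mode": 5, "fano": 0.0}


def test_fano_factor_alpha1_is_one_over_one_minus_gamma():
    # negative binomial: variance/mean = 1/(1-gamma) in the untruncated limit
    theta, gamma = 10.0, 0.6
    pmf = stationary_pmf(DegradationParams(1.0, theta, gamma), 1000)
    assert centralities(pmf)["fano"] == pytest.approx(1.0 / (1.0 - gamma), rel=1e-6)


def test_median_is_smallest_n_reaching_half_mass(nb_pmf):
    med = centralities(nb_pmf)["median"]
    cdf = np.cumsum(nb_pmf.probs)
    assert cdf[med] >= 0.5
    assert med == 0 or cdf[med - 1] < 0.5


# ---------------------------------------------------------------------------
# Gamma burst null model

def test_gamma_burst_density_exponential_limit():
    # a=1 reduces to Exp(1/b); density at the origin is 1/b
    assert gamma_burst_density(GammaBurstParams(1.0, 1.0), 1e-12) == pytest.approx(1.0)


def test_gamma_burst_density_normalized():
    params = GammaBurstParams(2.5, 30.0)
    total, _ = integrate.quad(lambda x: gamma_burst_density(params, x), 0, np.inf)
    assert total == pytest.approx(1.0, abs=1e-8)


def test_gamma_burst_matches_scipy():
    params = GammaBurstParams(3.0, 2.0)
    x = np.linspace(0.1, 30, 50)
    np.testing.assert_allclose(
        gamma_burst_density(params, x), stats.gamma.pdf(x, a=3.0, scale=2.0)
    )


def test_gamma_sum_property_monte_carlo():
    # sums of independent Gamma(a_i, b) variates follow Gamma(sum a_i, b)
    rng = np.random.default_rng(7)
    a_parts = [0.5, 1.2, 2.3]
    b = 3.0
    sums = sum(rng.gamma(a, b, size=20000) for a in a_parts)
    ks = stats.kstest(sums, "gamma", args=(sum(a_parts), 0, b))
    assert ks.pvalue > 0.01


def test_gamma_burst_invalid_params():
    with pytest.raises(ParameterError):
        GammaBurstParams(0.0, 1.0)
    with pytest.raises(ParameterError):
        GammaBurstParams(1.0, -1.0)
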