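"""Likelihood, ML fitting, information criteria and the posterior sampler."""

import numpy as np
import pytest

from hilldeg.distributions import DegradationParams, stationary_pmf
from hilldeg.inference import (
    MCMCSettings,
    SupportError,
    delta_criteria,
    fit_ml,
    information_criteria,
    log_likelihood,
    posterior_summary,
    profile_interval,
    run_adaptive_metropolis,
)
from hilldeg.inference import PosteriorChain
from hilldeg.synthetic import sample_counts

REF = DegradationParams(2.0, 250.0, 0.8)


@pytest.fixture(scope="module")
def ref_counts():
    return sample_counts(REF, 700, seed=31)


# ---------------------------------------------------------------------------
# likelihood

def test_log_likelihood_single_count(nb_pmf):
    params = nb_pmf.params
    ll = log_likelihood(np.array([7]), params, n_max=nb_pmf.n_max)
    assert ll == pytest.approx(nb_pmf.log_probs[7])


def test_log_likelihood_additive(nb_pmf):
    params = nb_pmf.params
    a = np.array([1, 5, 9])
    b = np.array([2, 2, 30])
    both = np.concatenate([a, b])
    assert log_likelihood(both, params, 300) == pytest.approx(
        log_likelihood(a, params, 300) + log_likelihood(b, params, 300)
    )


def test_log_likelihood_matches_naive_sum(nb_pmf):
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 200, size=50)
    naive = sum(float(nb_pmf.log_probs[c]) for c in counts)
    assert log_likelihood(counts, nb_pmf.params, 300) == pytest.approx(naive)


def test_log_likelihood_support_error(nb_pmf):
    with pytest.raises(SupportError):
        log_likelihood(np.array([301]), nb_pmf.params, 300)


# ---------------------------------------------------------------------------
# maximum likelihood

def test_fit_requires_min_observations():
    with pytest.raises(ValueError, match="10 observations"):
        fit_ml(np.arange(5), "nb")


def test_nb_fit_and_gnb_nesting(ref_counts):
    f_nb = fit_ml(ref_counts, "nb")
    f_gnb = fit_ml(ref_counts, "gnb")
    assert f_nb.params_hat.alpha == 1.0
    assert f_nb.k == 2 and f_gnb.k == 3
    # nested models: the gnb maximum can never fall below the nb maximum
    assert f_gnb.log_likelihood >= f_nb.log_likelihood - 1e-6


def test_mle_beats_generating_parameters(ref_counts):
    f = fit_ml(ref_counts, "gnb")
    assert f.log_likelihood >= log_likelihood(ref_counts, REF)


def test_fit_result_information_criteria_formulas(ref_counts):
    f = fit_ml(ref_counts, "gnb")
    assert f.aic == pytest.approx(2 * 3 - 2 * f.log_likelihood)
    assert f.bic == pytest.approx(3 * np.log(700) - 2 * f.log_likelihood)
    assert f.aicc == pytest.approx(f.aic + 24 / (700 - 4))
    ic = information_criteria(f)
    assert set(ic) == {"aic", "bic", "aicc"}


def test_information_criteria_direct_formula():
    # k=3, loglik=-100, n=100
    from hilldeg.inference import _make_fit_result

    fr = _make_fit_result("gnb", DegradationParams(2, 10, 0.5), -100.0, 100)
    assert fr.aic == pytest.approx(206.0)
    assert fr.bic == pytest.approx(3 * np.log(100) + 200.0)
    assert fr.aicc == pytest.approx(206.0 + 24 / 96)


def test_aicc_undefined_for_tiny_n():
    from hilldeg.inference import _make_fit_result

    fr = _make_fit_result("gnb", DegradationParams(2, 10, 0.5), -10.0, 4)
    with pytest.raises(ValueError, match="AICc"):
        information_criteria(fr)


def test_delta_criteria_signs(ref_counts):
    f_nb = fit_ml(ref_counts, "nb")
    f_gnb = fit_ml(ref_counts, "gnb")
    d = delta_criteria(f_gnb, f_nb)
    # deltas differ only through the parameter penalties
    assert d["delta_bic"] - d["delta_aic"] == pytest.approx(np.log(700) - 2)


def test_profile_interval_contains_mle(ref_counts):
    f = fit_ml(ref_counts, "gnb")
    for name in ("alpha", "theta", "gamma"):
        lo, hi = profile_interval(ref_counts, f, name)
        val = getattr(f.params_hat, name)
        assert lo <= val <= hi


# ---------------------------------------------------------------------------
# adaptive Metropolis

def test_settings_validation():
    with pytest.raises(ValueError):
        MCMCSettings(steps=100, burn_in=100)
    with pytest.raises(ValueError):
        MCMCSettings(thin=0)
    s = MCMCSettings()
    assert (s.steps, s.burn_in, s.thin) == (200_000, 100_000, 10)


def test_chain_length_and_determinism(ref_counts):
    f = fit_ml(ref_counts, "gnb")
    settings = MCMCSettings(steps=3000, burn_in=1000, thin=4, seed=9)
    chain1 = run_adaptive_metropolis(ref_counts, settings, init=f.params_hat)
    chain2 = run_adaptive_metropolis(ref_counts, settings, init=f.params_hat)
    assert len(chain1) == (3000 - 1000) // 4
    np.testing.assert_array_equal(chain1.samples, chain2.samples)
    np.testing.assert_array_equal(chain1.log_likelihoods, chain2.log_likelihoods)
    assert chain1.acceptance_rate == chain2.acceptance_rate
    # every retained sample satisfies the parameter constraints
    a, t, g = chain1.samples.T
    assert np.all((a > 0) & (a <= 10) & (t > 0) & (t < 2000) & (g > 0) & (g < 1))


def test_posterior_summary_argmax_and_intervals(ref_counts):
    f = fit_ml(ref_counts, "gnb")
    chain = run_adaptive_metropolis(
        ref_counts, MCMCSettings(steps=4000, burn_in=2000, thin=4, seed=2),
        init=f.params_hat,
    )
    s = posterior_summary(chain)
    # the point estimate is the retained sample of highest likelihood
    best_ll = s["log_likelihood"]
    assert best_ll == chain.log_likelihoods.max()
    mean_params = DegradationParams(*chain.samples.mean(axis=0))
    assert best_ll >= log_likelihood(ref_counts, mean_params)
    for name in ("alpha", "theta", "gamma"):
        lo, hi = s["ci95"][name]
        hlo, hhi = s["hpd95"][name]
        assert lo <= hi and hlo <= hhi
        assert hhi - hlo <= hi - lo + 1e-9  # HPD is the narrowest interval
    assert s["corr"].shape == (3, 3)


def test_posterior_summary_degenerate_chain():
    samples = np.tile([2.0, 100.0, 0.5], (50, 1))
    chain = PosteriorChain(
        samples=samples, log_likelihoods=np.full(50, -10.0),
        acceptance_rate=0.0,
        settings=MCMCSettings(steps=100, burn_in=50, thin=1),
    )
    s = posterior_summary(chain)
    assert s["point"].as_tuple() == (2.0, 100.0, 0.5)
    assert all(v == 0.0 for v in s["sd"].values())


def test_gnb_fit_with_alpha_pinned_matches_nb(ref_counts):
    f_nb = fit_ml(ref_counts, "nb")
    pinned = fit_ml(ref_counts, "gnb", starts=[f_nb.params_hat])
    # seeded at the nb optimum, the gnb fit can only do as well or better
    assert pinned.log_likelihood >= f_nb.log_likelihood - 1e-6
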