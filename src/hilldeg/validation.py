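"""Simulation-based validation studies of the whole pipeline.

Each function runs one self-contained study at the package's reference
conditions — closed-form agreement, detailed balance, stochastic-simulation
equivalence, parameter recovery, bootstrap calibration, model selection and
trend detection — and returns plain numbers.  They power both the
acceptance script and the acceptance test suite.

All randomness is derived from a single seed argument.
"""

from __future__ import annotations

import numpy as np

from .distributions import (
    DegradationParams,
    centralities,
    stationary_pmf,
)
from .gof import bootstrap_gof
from .inference import (
    MCMCSettings,
    delta_criteria,
    fit_ml,
    posterior_summary,
    profile_interval,
    run_adaptive_metropolis,
)
from .preprocess import scale_to_counts, select_passage
from .synthetic import (
    StudyDesign,
    generate_study,
    sample_counts,
    ssa_stationary_sample,
)
from .trends import ParamTrajectory, wls_slope_test

__all__ = [
    "REFERENCE_PARAMS",
    "closed_form_agreement",
    "detailed_balance_error",
    "ssa_equivalence",
    "recovery_study",
    "gof_calibration_study",
    "model_selection_study",
    "trend_study",
]

#: cooperative reference parameters for the recovery study (late-passage
#: regime: high gamma, over-dispersed)
REFERENCE_PARAMS = DegradationParams(2.0, 250.0, 0.8)

#: cooperative parameters for the model-selection study (early/mid-passage
#: regime: low gamma).  With alpha=2 and small gamma the stationary law is
#: narrower than Poisson (Fano = 1/(alpha (1-gamma)) < 1), which no
#: negative binomial can emulate, so the information criteria separate the
#: families decisively; at high gamma the best nb approximation is nearly
#: indistinguishable (KL ~ 4e-4) and no selection procedure could prefer
#: the cooperative model reliably at n=700.
MODEL_SELECTION_PARAMS = DegradationParams(2.0, 200.0, 0.3)

#: parameter sets for the stochastic-simulation cross-check, spanning the
#: cooperativity range; the last one sits at the reference scale and
#: dominates the runtime (its chain mixes slowly)
SSA_TEST_SETS = (
    DegradationParams(1.0, 30.0, 0.5),
    DegradationParams(1.0, 60.0, 0.8),
    DegradationParams(2.0, 50.0, 0.6),
    DegradationParams(3.0, 40.0, 0.7),
    DegradationParams(2.0, 250.0, 0.8),
)

#: small-theta negative binomial used for the bootstrap calibration study
CALIBRATION_PARAMS = DegradationParams(1.0, 50.0, 0.75)
CALIBRATION_N = 200
CALIBRATION_N_MAX = 320


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def closed_form_agreement() -> dict:
    """Max |P0 - (1-gamma)^(theta+1)| over the alpha=1 grid, and the
    largest truncation tail mass that bounds the discrepancy."""
    max_err = 0.0
    max_tail = 0.0
    for theta in (1.0, 2.0, 5.0):
        for gamma in (0.3, 0.5, 0.8):
            pmf = stationary_pmf(DegradationParams(1.0, theta, gamma), 2000)
            err = abs(pmf.probs[0] - (1.0 - gamma) ** (theta + 1.0))
            max_err = max(max_err, err)
            max_tail = max(max_tail, pmf.truncation_tail_mass)
    return {"max_abs_err": max_err, "max_tail_mass": max_tail}


def detailed_balance_error(n_max: int = 2000) -> float:
    """Max relative detailed-balance violation across a parameter grid."""
    grid = [
        (1.0, 2.0, 0.5), (1.0, 5.0, 0.8), (1.0, 50.0, 0.3),
        (2.0, 50.0, 0.6), (2.0, 250.0, 0.8),
        (3.0, 40.0, 0.7), (3.0, 100.0, 0.5), (0.8, 20.0, 0.4),
    ]
    worst = 0.0
    for a, t, g in grid:
        pmf = stationary_pmf(DegradationParams(a, t, g), n_max)
        n = np.arange(1, n_max + 1, dtype=float)
        r_n = 1.0 / (1.0 + (t / n) ** a)
        lhs = pmf.probs[1:] * r_n
        rhs = pmf.probs[:-1] * g
        mask = rhs > 1e-280
        worst = max(worst, float(np.max(np.abs(lhs[mask] - rhs[mask]) / rhs[mask])))
    return worst


def ssa_equivalence(seed: int = 0, t_total: float = 2e7) -> list[float]:
    """Total-variation distance between the analytic pmf and a long
    Gillespie run (time-weighted occupancy), one value per test set."""
    seeds = _spawn_seeds(seed, len(SSA_TEST_SETS))
    out = []
    for params, s in zip(SSA_TEST_SETS, seeds):
        pmf = stationary_pmf(params, 1000)
        emp = ssa_stationary_sample(
            params, t_burn=t_total * 5e-4, t_total=t_total, seed=s
        )
        k = min(len(emp), 1001)
        tv = 0.5 * float(np.abs(emp[:k] - pmf.probs[:k]).sum()) \
            + 0.5 * float(emp[k:].sum() + pmf.probs[k:].sum())
        out.append(tv)
    return out


def recovery_study(
    n_reps: int = 20,
    n: int = 700,
    seed: int = 0,
    mcmc_steps: int = 30_000,
) -> dict:
    """Parameter recovery at the reference parameters.

    Per replicate: the generating (alpha, theta, gamma) must fall inside
    the ML fit's 95% profile-likelihood intervals and inside the posterior
    95% HPD intervals (reduced chains).  Returns per-check and joint
    counts.
    """
    truth = REFERENCE_PARAMS
    seeds = _spawn_seeds(seed, n_reps)
    ml_ok = post_ok = joint_ok = 0
    for i, s in enumerate(seeds):
        counts = sample_counts(truth, n, seed=s)
        fit = fit_ml(counts, "gnb")
        ok_prof = True
        for name in ("alpha", "theta", "gamma"):
            lo, hi = profile_interval(counts, fit, name)
            ok_prof &= bool(lo <= getattr(truth, name) <= hi)
        chain = run_adaptive_metropolis(
            counts,
            MCMCSettings(steps=mcmc_steps, burn_in=mcmc_steps // 2, thin=10,
                         seed=s + 1),
            init=fit.params_hat,
        )
        summ = posterior_summary(chain)
        ok_hpd = all(
            summ["hpd95"][name][0] <= getattr(truth, name) <= summ["hpd95"][name][1]
            for name in ("alpha", "theta", "gamma")
        )
        ml_ok += ok_prof
        post_ok += ok_hpd
        joint_ok += ok_prof and ok_hpd
    return {
        "n_reps": n_reps,
        "ml_profile_covered": ml_ok,
        "posterior_hpd_covered": post_ok,
        "joint_covered": joint_ok,
    }


def gof_calibration_study(
    n_reps: int = 100, B: int = 199, seed: int = 0
) -> dict:
    """Type-I calibration of the bootstrap GoF p-value under the null.

    Data are drawn from a fitted-family null (small-theta negative
    binomial, n=200) and tested against the same family; returns the
    rejection rate at level 0.05 and the p-values.
    """
    pmf = stationary_pmf(CALIBRATION_PARAMS, CALIBRATION_N_MAX)
    seeds = _spawn_seeds(seed, n_reps)
    pvals = []
    for s in seeds:
        rng = np.random.default_rng(s)
        cdf = np.cumsum(pmf.probs)
        cdf[-1] = 1.0
        counts = np.searchsorted(cdf, rng.random(CALIBRATION_N)).astype(int)
        res = bootstrap_gof(counts, "nb", B=B, seed=s + 1,
                            n_max=CALIBRATION_N_MAX)
        pvals.append(res.p_value)
    pvals_arr = np.array(pvals)
    return {
        "n_reps": n_reps,
        "rejection_rate": float(np.mean(pvals_arr <= 0.05)),
        "p_values": pvals_arr,
    }


def model_selection_study(
    n_reps: int = 20, n: int = 700, seed: int = 0
) -> dict:
    """Fraction of replicates preferring the cooperative model by AIC on
    data generated with cooperativity (alpha=2)."""
    seeds = _spawn_seeds(seed, n_reps)
    negative_aic = negative_bic = 0
    deltas = []
    for s in seeds:
        counts = sample_counts(MODEL_SELECTION_PARAMS, n, seed=s)
        f_nb = fit_ml(counts, "nb")
        f_gnb = fit_ml(counts, "gnb")
        d = delta_criteria(f_gnb, f_nb)
        deltas.append(d["delta_aic"])
        negative_aic += d["delta_aic"] < 0
        negative_bic += d["delta_bic"] < 0
    return {
        "n_reps": n_reps,
        "delta_aic_negative": negative_aic,
        "delta_bic_negative": negative_bic,
        "mean_delta_aic": float(np.mean(deltas)),
    }


def trend_study(
    n_reps: int = 20, seed: int = 0, mcmc_steps: int = 20_000
) -> dict:
    """End-to-end trend detection on synthetic studies.

    Each study uses the default design: constant (alpha, theta) and a
    linearly ramped log-odds gamma across passages.  A replicate counts as
    correct when the weighted regression flags the gamma trend at 0.05 and
    flags neither alpha nor theta.
    """
    seeds = _spawn_seeds(seed, n_reps)
    gamma_sig = only_gamma = 0
    alpha_fp = theta_fp = 0
    for i, s in enumerate(seeds):
        design = StudyDesign(seed=s)
        records, _ = generate_study(design)
        ds = scale_to_counts(records)
        passages = sorted(set(ds.passages.tolist()))
        pvals = {}
        traj: dict[str, tuple[list, list]] = {
            k: ([], []) for k in ("alpha", "theta", "lam")
        }
        for j, p in enumerate(passages):
            counts = select_passage(ds, p)
            fit = fit_ml(counts, "gnb")
            chain = run_adaptive_metropolis(
                counts,
                MCMCSettings(steps=mcmc_steps, burn_in=mcmc_steps // 2,
                             thin=10, seed=(s + 7 * j + 1) % 2**31),
                init=fit.params_hat,
            )
            smp = chain.samples
            lam = np.log((1.0 - smp[:, 2]) / smp[:, 2])
            for key, vals in (("alpha", smp[:, 0]), ("theta", smp[:, 1]),
                              ("lam", lam)):
                traj[key][0].append(float(np.mean(vals)))
                traj[key][1].append(max(float(np.std(vals, ddof=1)), 1e-12))
        for key, (est, sds) in traj.items():
            tf = wls_slope_test(ParamTrajectory(
                np.array(passages, float), np.array(est), np.array(sds)
            ))
            pvals[key] = tf.p_value
        g_sig = pvals["lam"] < 0.05
        gamma_sig += g_sig
        alpha_fp += pvals["alpha"] < 0.05
        theta_fp += pvals["theta"] < 0.05
        only_gamma += g_sig and pvals["alpha"] >= 0.05 and pvals["theta"] >= 0.05
    return {
        "n_reps": n_reps,
        "gamma_significant": gamma_sig,
        "alpha_false_positive": alpha_fp,
        "theta_false_positive": theta_fp,
        "only_gamma_significant": only_gamma,
    }
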