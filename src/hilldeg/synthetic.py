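"""Synthetic data: model-exact count samples, a Gillespie oracle, and
full synthetic studies in the single-cell table schema.

Three generators with distinct roles:

* :func:`sample_counts` draws i.i.d. counts from the analytic stationary
  pmf (inverse-CDF lookup) — the workhorse for bootstrap and simulation
  studies.
* :func:`ssa_stationary_sample` runs the exact stochastic simulation
  algorithm on the underlying birth-death chain and returns the
  time-weighted occupancy distribution.  It never touches the analytic
  recurrence, so it serves as an independent oracle for the stationary
  pmf.
* :func:`generate_study` emulates a full multi-passage single-cell
  fluorescence study: per-passage counts from the stationary law with
  constant (alpha, theta) and a passage-dependent gamma, mapped to
  continuous fluorescence with sub-count jitter, log-normal nucleus sizes
  and experiment-replicate structure, plus a ground-truth ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .distributions import (
    DegradationParams,
    StationaryPMF,
    deterministic_mode,
    stationary_pmf,
)

__all__ = [
    "StudyDesign",
    "DEFAULT_DESIGN",
    "sample_counts",
    "sample_from_pmf",
    "ssa_stationary_sample",
    "generate_study",
]


# ---------------------------------------------------------------------------
# exact sampling from the stationary law

def sample_from_pmf(pmf: StationaryPMF, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. draws from a truncated stationary pmf by inverse-CDF lookup."""
    cdf = np.cumsum(pmf.probs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n)).astype(int)


def sample_counts(
    params: DegradationParams, n: int, seed: int, n_max: int = 1000
) -> np.ndarray:
    """n i.i.d. stationary counts; deterministic under a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pmf = stationary_pmf(params, n_max)
    return sample_from_pmf(pmf, n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Gillespie SSA oracle

@njit(cache=True)
def _gillespie_occupancy(
    death_rates: np.ndarray,
    birth_rate: float,
    t_burn: float,
    t_total: float,
    n0: int,
    seed: int,
) -> np.ndarray:
    """Time-weighted state occupancy of the birth-death chain on
    0..len(death_rates)-1 over (t_burn, t_total]."""
    np.random.seed(seed)
    n_cap = len(death_rates) - 1
    occ = np.zeros(n_cap + 1)
    n = n0
    t = 0.0
    while t < t_total:
        g = birth_rate if n < n_cap else 0.0
        r = death_rates[n]
        tot = g + r
        dt = -np.log(np.random.random()) / tot
        t_next = t + dt
        lo = t if t > t_burn else t_burn
        hi = t_next if t_next < t_total else t_total
        if hi > lo:
            occ[n] += hi - lo
        if np.random.random() * tot < g:
            n += 1
        else:
            n -= 1
        t = t_next
    return occ


def ssa_stationary_sample(
    params: DegradationParams,
    rate_scale: float = 1.0,
    t_burn: float = 5e3,
    t_total: float = 1e6,
    seed: int = 0,
    n_cap: int | None = None,
) -> np.ndarray:
    """Empirical stationary distribution from an exact Gillespie run.

    Simulates the chain with rates ``g_n = rate_scale * gamma`` and
    ``r_n = rate_scale * n^alpha / (theta^alpha + n^alpha)`` and returns
    the normalized time-weighted occupancy over ``(t_burn, t_total]``
    (time weighting avoids the holding-time bias of event sampling).  The
    returned distribution is invariant to ``rate_scale``, which only
    rescales time.  The chain starts at the deterministic mode to shorten
    the transient.
    """
    if not t_burn < t_total:
        raise ValueError("require t_burn < t_total")
    if rate_scale <= 0:
        raise ValueError("rate_scale must be positive")
    mode = deterministic_mode(params)
    if n_cap is None:
        n_cap = max(int(4 * mode) + 50, 200)
    n = np.arange(n_cap + 1, dtype=float)
    a = params.alpha
    with np.errstate(divide="ignore"):
        log_n_a = a * np.log(n)
    death = np.where(
        n > 0,
        rate_scale / (1.0 + np.exp(a * np.log(params.theta) - log_n_a)),
        0.0,
    )
    occ = _gillespie_occupancy(
        death,
        rate_scale * params.gamma,
        t_burn * 1.0,
        t_total * 1.0,
        int(round(mode)),
        int(seed) % 2**31,
    )
    return occ / occ.sum()


# ---------------------------------------------------------------------------
# full synthetic studies

def _default_gamma_ramp() -> np.ndarray:
    # linear ramp in log-odds lambda = log((1-g)/g) from 2.0 at passage 3
    # to -2.5 at passage 13: gamma rises smoothly from ~0.12 to ~0.92,
    # spanning the several-fold rise in protein content at senescence
    passages = np.array([3, 9, 10, 11, 12, 13], float)
    lam = 2.0 + (passages - 3.0) * (-4.5 / 10.0)
    return 1.0 / (1.0 + np.exp(lam))


def _default_experiment_map() -> dict[int, tuple[str, ...]]:
    # replicate structure: early passage covered by three replicas, the
    # senescence approach by a fourth, the final passage by all four
    return {
        3: ("exp1", "exp2", "exp3"),
        9: ("exp4",),
        10: ("exp4",),
        11: ("exp4",),
        12: ("exp4",),
        13: ("exp1", "exp2", "exp3", "exp4"),
    }


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic multi-passage single-cell study.

    Defaults emulate a replicative-senescence imaging study: six passages
    (3, 9-13)
    with per-passage sample sizes 744, 255, 195, 103, 182, 684 (2163 cells
    in total), constant cooperativity alpha=2 and threshold theta=250, and
    a gamma that rises across passages linearly on the log-odds scale.
    """

    passages: tuple[int, ...] = (3, 9, 10, 11, 12, 13)
    n_per_passage: tuple[int, ...] = (744, 255, 195, 103, 182, 684)
    alpha: float = 2.0
    theta: float = 200.0
    gamma_by_passage: tuple[float, ...] = tuple(_default_gamma_ramp())
    experiments_by_passage: dict[int, tuple[str, ...]] = field(
        default_factory=_default_experiment_map
    )
    fluorescence_unit: float = 50.0
    nucleus_log_mean: float = 4.0
    nucleus_log_sd: float = 0.25
    n_max: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.passages) == len(self.n_per_passage)
                == len(self.gamma_by_passage)):
            raise ValueError("passages, n_per_passage and gamma_by_passage "
                             "must have equal length")
        if any(not 0 < g < 1 for g in self.gamma_by_passage):
            raise ValueError("all gammas must lie in (0, 1)")
        if self.fluorescence_unit <= 0:
            raise ValueError("fluorescence_unit must be positive")


DEFAULT_DESIGN = StudyDesign()


def generate_study(design: StudyDesign = DEFAULT_DESIGN):
    """Generate a synthetic study table plus its ground-truth ledger.

    Per passage, counts are drawn from the stationary pmf at
    (alpha, theta, gamma_passage); fluorescence is ``count *
    fluorescence_unit + Uniform(0, unit)`` so the integer count is
    recoverable to within one unit after rescaling; nucleus sizes are
    log-normal; records are allocated round-robin to the passage's
    experiment replicas.

    Returns
    -------
    records : DataFrame in the single-cell table schema
        (nucleus_size, fluorescence, passage, experiment).
    truth : dict
        Ground-truth parameters, per-record generating counts, and the
        realized maximum count (the scale anchor for count recovery).
    """
    rng = np.random.default_rng(design.seed)
    frames = []
    truth_counts = []
    for p, n_p, g_p in zip(
        design.passages, design.n_per_passage, design.gamma_by_passage
    ):
        params = DegradationParams(design.alpha, design.theta, g_p)
        pmf = stationary_pmf(params, design.n_max)
        counts = sample_from_pmf(pmf, n_p, rng)
        fluor = (counts + rng.random(n_p)) * design.fluorescence_unit
        nuc = rng.lognormal(design.nucleus_log_mean, design.nucleus_log_sd, n_p)
        exps = design.experiments_by_passage.get(p, ("exp1",))
        labels = np.array([exps[i % len(exps)] for i in range(n_p)])
        frames.append(pd.DataFrame({
            "nucleus_size": nuc,
            "fluorescence": fluor,
            "passage": p,
            "experiment": labels,
        }))
        truth_counts.append(counts)
    records = pd.concat(frames, ignore_index=True)
    all_counts = np.concatenate(truth_counts)
    truth = {
        "alpha": design.alpha,
        "theta": design.theta,
        "gamma_by_passage": dict(zip(design.passages, design.gamma_by_passage)),
        "counts": all_counts,
        "max_count": int(all_counts.max()),
        "fluorescence_unit": design.fluorescence_unit,
        "seed": design.seed,
    }
    return records, truth
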