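# Methods

## The model

`hilldeg` models the number *n* of nuclear protein units in a single cell
as a one-step birth–death Markov chain. Production is treated as constant:
the total output of many weakly correlated translation events is
quasi-stationary, so its fluctuations are negligible compared to those of
degradation. Degradation is an active, enzyme-mediated process
(ubiquitination, transport, proteasomal fragmentation) collapsed into a
single saturating step with Hill kinetics. After normalizing all rates to
the production rate, the transition rates are

    g_n = γ                      (production),
    r_n = n^α / (θ^α + n^α)      (degradation),

with three parameters:

| parameter | meaning | domain | default/units |
|---|---|---|---|
| α | Hill cooperativity coefficient of the degradation machinery | α > 0 | dimensionless; α = 1 is non-cooperative (Michaelis–Menten) |
| θ | half-saturation threshold of degradation | θ > 0 | scaled-count units (same scale as the data) |
| γ | production rate over maximal degradation rate | 0 < γ < 1 | dimensionless; the chain is positive recurrent only for γ < 1 |

Detailed balance, `P_n r_n = P_{n-1} g_{n-1}`, holds for every
one-dimensional one-step chain, so the stationary law follows by
recurrence:

    P_n = P_0 · Π_{i=1..n} γ (θ^α + i^α) / i^α.

For α = 1 this is a negative binomial: `P_n = C₀ C(θ+n, n) γ^n` with
`C₀ = (1-γ)^(θ+1)` (factorials generalized to gamma functions for real θ).
For general real α no closed form exists; we accumulate the product as a
log-space cumulative sum on the truncated support 0..n_max and normalize
by log-sum-exp ("generalized negative binomial"). Truncation defaults to
n_max = 1000, the top of the data scale; the geometric decay of the last
terms gives a tail-mass estimate that is reported, flagged above 1e-6 and
fatal above 1e-3 (fits and goodness-of-fit evaluations instead treat the
truncated, renormalized law as the model, because the counts are
constructed to live on [0, 1000]).

The deterministic balance point `g(x) = r(x)` gives the mode,
`x* = θ (γ/(1-γ))^(1/α)`; the α = 1 special case θγ/(1-γ) is the printed
form, and the general expression is our derivation from the same balance
equation. A useful identifiability fact used throughout: near the mode the
law is approximately Gaussian with variance `x*/(α(1-γ))`, so the Fano
factor is ≈ `1/(α(1-γ))` — **sub-Poissonian** whenever α(1-γ) > 1. No
negative binomial (Fano ≥ 1) can imitate that regime; this is where
cooperativity is statistically visible.

The continuous null model is the Gamma density of bursty production,
`p(x) = x^{a-1} e^{-x/b} / (b^a Γ(a))`, with *a* the mean number of bursts
per protein lifetime and *b* the mean burst size; sums of independent
Gamma(aᵢ, b) variables remain Gamma(Σaᵢ, b), which justifies using it for
total protein content.

## Data scaling

Input tables carry one row per cell: nucleus size, raw integrated
fluorescence, replicative passage, experiment replicate. Fluorescence is
mapped to integer counts by assigning 1000 to the single highest value
across **all** experiments and passages and scaling linearly (rounding
half away from zero; the state space is integer). Multiplying all
fluorescence by a constant leaves the counts unchanged, and the model
absorbs any change of the scale ceiling as a rescaling of θ. The raw
integrated signal is analyzed by default — the model concerns the amount
of protein, not its areal density — with `use_density=True` switching to
fluorescence per nucleus area (the source data ship both columns and the
choice is not documented there).

## Likelihood, ML fitting, information criteria

The likelihood of a count vector is the truncated stationary pmf evaluated
once per parameter triple and contracted with the count histogram. ML
fits run derivative-free Nelder–Mead on logit-transformed coordinates
(bounds α ∈ (0, 10], θ ∈ (0, 2000), γ ∈ (0, 1)) from three starts: the
α = 1 start is seeded at the 2-parameter nb optimum — which also enforces
the nested-family inequality max ll(gnb) ≥ max ll(nb) structurally — and
two cooperative starts (α = 2, 3) use a method-of-moments nb
initialization for (θ, γ). AIC, BIC and the small-sample AICc follow the
standard formulas with k = 2 (nb) or 3 (gnb); negative ΔAIC = AIC(gnb) −
AIC(nb) favors the cooperative model.

Profile-likelihood 95% intervals per parameter (deviance below the
χ²₁ quantile, endpoints by outward stepping plus bisection) complement the
Bayesian intervals for recovery checks.

## Posterior sampling

The posterior under a flat prior on the bounded box is explored with an
adaptive random-walk Metropolis sampler (2·10⁵ steps, 10⁵ burn-in,
thinning 10 by default; proposal covariance re-estimated every 100 steps
during burn-in at the 3-dimensional optimal scale 2.38²/3 and frozen
afterwards, preserving ergodicity).

The likelihood surface is a long, *curved* ridge: parameter triples
sharing the balance point x* and the local width x*/(α(1-γ)) are nearly
equally likely, with α only weakly pinned by skewness information of order
1/√x*. A random walk directly in (α, θ, γ) mixes along this ridge at 1–5%
acceptance and effectively explores only a local neighborhood of its
start. The sampler therefore walks in ridge-aligned coordinates
(log α, log x*, log local-variance), with the exact Jacobian (finite
differences of the closed-form inverse map) keeping the prior flat on the
original parameters. Acceptance rises to ~25% and chains traverse the
full ridge; the resulting marginals were validated against a brute-force
three-dimensional grid integration of the same posterior.

Two consequences of the ridge are documented rather than hidden:

* **Skewed marginals.** The θ marginal, in particular, is sharply edged
  near the data scale with a long tail toward the prior bound. Central
  (equal-tailed) 95% intervals then cut into the high-density edge and
  under-cover the generating θ; highest-posterior-density intervals do
  not. `posterior_summary` reports both (`ci95`, `hpd95`); recovery
  checks use the HPD intervals.
* **Attenuated trend trajectories.** Posterior means shrink along the
  ridge, so per-passage trajectories understate the true parameter drift;
  the per-passage posterior sd (0.7–1.1 on the log-odds-γ scale at the
  default sample sizes) is the honest uncertainty that the weighted trend
  regression consumes. The highest-likelihood sample (the point estimate
  the summary reports) is *not* used for trajectories: along a flat ridge
  it is an order of magnitude noisier than the mean.

## Goodness of fit

Fit quality is summarized by r² = 1 − SS_res/SS_tot between observed bin
relative frequencies and model bin probabilities on fixed 20-wide bins
over [0, 1000] (SS_tot around the mean observed frequency; a perfectly
flat observed histogram makes the statistic degenerate and is reported as
such). Its null distribution is obtained by the parametric bootstrap:
resample datasets of the original size from the fitted pmf, refit the
same family (seeded at the original optimum), recompute r², and report
the lower-tail p-value with the add-one correction, `p = (1 + #{r²_b ≤
r²_obs}) / (B + 1)` — always in (0, 1], exact under the null up to the
granularity 1/(B+1). B defaults to 1000; simulation studies use 199.
This construction avoids the estimated-parameter bias that invalidates a
Kolmogorov–Smirnov test here. The binned r² is sensitive to gross shape
mismatch (e.g. a sub-Poissonian sample against the nb family) but has
essentially no power against alternatives that match mean and variance;
family discrimination in ambiguous regimes is the job of the information
criteria, not of this statistic.

## Trends across passages

Per passage, the combined counts are fitted and sampled; trajectories of
α, θ and the log-odds λ = log((1−γ)/γ) (posterior mean ± sd, λ computed
directly on the transformed samples) are tested for linear trend by
weighted least squares with inverse-variance weights; the p-value is the
two-sided t test of zero slope with (passages − 2) degrees of freedom. λ
is strictly decreasing in γ, so a negative λ slope means γ rises with
passage. Centralities (mean, median, mode) of the fitted law are tracked
with uncertainties obtained by pushing posterior draws through the pmf
(the mode is discrete, so no delta method), and their passage profile is
summarized by a four-parameter logistic fit (floor, ceiling, steepness,
transition passage) via weighted nonlinear least squares, with 50%/95%
bands from refitting Gaussian resamples of the trajectory.

## Synthetic data

`generate_study` emulates a multi-passage single-cell fluorescence study:
counts drawn exactly from the stationary law per passage, fluorescence =
(count + Uniform(0,1)) × unit so that rescaling against the realized
maximum count recovers every count to within ±1, log-normal nucleus
sizes, and a fixed experiment-replicate layout (three replicas at the
first passage, one replica through the senescence approach, all four at
the last). Defaults: passages (3, 9, 10, 11, 12, 13) with sample sizes
(744, 255, 195, 103, 182, 684); α = 2 and θ = 200 constant; γ following a
linear log-odds ramp from 2.0 to −2.5 (γ ≈ 0.12 → 0.92). The ramp
endpoints are this package's choice, not values from any dataset: they
span the several-fold rise of protein content at replicative senescence
while keeping the late-passage distribution inside the [0, 1000] count
scale, and the early-passage side sits in the sub-Poissonian regime where
cooperativity is identifiable. What the generator does **not** emulate:
measurement noise beyond sub-count jitter, nucleus-size/fluorescence
correlation, cell-cycle or division effects (the model ignores dilution
by division), or between-replicate batch effects. Passing tests therefore
demonstrate correctness of the machinery under the model's own
assumptions, not robustness to those real-data features.

The independent oracle is a numba-compiled Gillespie simulation of the
birth–death chain; the stationary estimate is the time-weighted state
occupancy after burn-in (event sampling would bias toward short-lived
states), and its distribution is invariant to an overall rate rescaling.

## Validation studies and problem sizes

The `validation` module fixes the simulation studies run by
`scripts/acceptance.py` and the acceptance tests:

* closed-form agreement and detailed balance on parameter grids (exact);
* total-variation distance between the analytic pmf and Gillespie runs of
  2·10⁷ time units for five parameter sets spanning α ∈ {1, 2, 3};
* parameter recovery at (2, 250, 0.8), n = 700, 20 replicates: profile
  and HPD intervals (30 000-step chains);
* bootstrap calibration under a fitted-null negative binomial
  (θ = 50, γ = 0.75, n = 200, support 320), 100 replicates at B = 199;
* model selection at (2, 200, 0.3), n = 700, 20 replicates — the low-γ
  regime; at high γ the best nb approximation of the cooperative law is
  within KL ≈ 4·10⁻⁴ and no criterion could separate the families at
  this sample size;
* end-to-end trend detection on 20 default-design studies with
  20 000-step chains per passage.

Chain lengths and replicate counts were chosen once to keep each study at
desk scale; the known hard case is the trend study, where the joint
requirement (γ flagged, α and θ not) runs against the ridge-limited
identifiability of per-passage γ — see the discussion of attenuation
above. Every numerical tolerance is stated next to the code that
enforces it.

## Known limitations

* α, θ and γ are jointly weakly identified at realistic sample sizes;
  only functions like the balance point and local width are sharply
  estimated. Reported single-parameter intervals are honest but wide,
  and equal-tailed intervals on θ are additionally skew-biased.
* The binned r² statistic cannot reject alternatives matching the first
  two moments.
* The truncated support treats [0, 1000] as exhaustive; parameter values
  pushing noticeable mass beyond the ceiling are either rejected (guard
  on) or silently renormalized (guard off), which biases fits toward
  lighter tails in extreme regimes.
* Fits assume i.i.d. cells within a passage; replicate structure is
  carried through but not modeled hierarchically.
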