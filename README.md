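# hilldeg

Stochastic modeling of nuclear protein content in cells approaching
replicative senescence — and the statistical machinery to fit, check and
track that model on single-cell fluorescence data.

Senescent cells accumulate nuclear protein. `hilldeg` asks *why* through
a deliberately minimal model: protein number *n* follows a birth–death
chemical master equation with **constant production** and **cooperative
enzymatic degradation** (Hill kinetics),

    ∂t P_n = (E⁻ − 1) g_n P_n + (E⁺ − 1) r_n P_n,
    g_n = γ,    r_n = n^α / (θ^α + n^α),

whose stationary law — by the detailed-balance recurrence
P_n r_n = P_{n−1} g_{n−1} — is a **generalized negative binomial**,

    P_n = P₀ · Π_{i=1..n} γ (θ^α + i^α)/i^α,

reducing for α = 1 to the negative binomial with P₀ = (1−γ)^(θ+1). The
three parameters are the Hill cooperativity α, the degradation
half-saturation threshold θ, and γ, the ratio of production to maximal
degradation rate (the distribution exists only for γ ∈ (0,1)). A Gamma
density of bursty production serves as the continuous null model.

The package is for quantitative cell biologists and modelers who have
per-cell integrated fluorescence tables (nucleus size, fluorescence,
passage, replicate) and want to know which kinetic ingredient changes as
cells age. Its pipeline: rescale fluorescence to counts on [0, 1000] →
maximum-likelihood and adaptive-Metropolis Bayesian fits of the α = 1 and
general families per passage → parametric-bootstrap r² goodness of fit →
AIC/BIC family comparison → weighted-regression trends of (α, θ,
log-odds γ) across passages → logistic summary of the centrality
transition. A synthetic-study generator with a known ground truth makes
every stage testable end to end.

## Worked example

Simulate one passage in the early (low-γ) regime, fit both families and
compare them:

```python
import hilldeg as hd

params = hd.DegradationParams(alpha=2.0, theta=200.0, gamma=0.3)
print(hd.deterministic_mode(params))          # 130.93
print(hd.centralities(hd.stationary_pmf(params, 1000)))
# {'mean': 131.00, 'median': 131, 'mode': 130, 'fano': 0.717}

counts = hd.sample_counts(params, 700, seed=42)
fit_nb  = hd.fit_ml(counts, "nb")     # alpha pinned at 1
fit_gnb = hd.fit_ml(counts, "gnb")
print(hd.delta_criteria(fit_gnb, fit_nb))
# {'delta_aic': -56.18, 'delta_bic': -51.63, 'delta_aicc': -56.17}

gof = hd.bootstrap_gof(counts, "nb", B=199, seed=0)
print(gof.p_value, round(gof.r2_observed, 4))   # 0.005 0.9691
gof = hd.bootstrap_gof(counts, "gnb", B=199, seed=0)
print(gof.p_value, round(gof.r2_observed, 4))   # 0.71 0.9998
```

What the numbers mean: with α = 2 and γ = 0.3 the stationary law has a
Fano factor of 0.72 — *narrower than Poisson*, something no negative
binomial (Fano ≥ 1) can produce. Both criteria therefore prefer the
cooperative family decisively (ΔAIC = −56), and the bootstrap rejects
the α = 1 family (p = 0.005, the 1/(B+1) floor) while the cooperative fit
is comfortably compatible with its own data (p = 0.71). The discrete mode
130 sits within one count of the deterministic balance point
θ(γ/(1−γ))^{1/α} = 130.93.

The full pipeline runs from the shell:

```bash
hilldeg simulate --seed 3 --outdir study/        # synthetic per-cell table
hilldeg report --input study/study.csv --fast --outdir report/
```

writing per-passage fits, the goodness-of-fit p-value matrix, ΔAIC/ΔBIC
rows with dataset sizes, parameter trajectories with trend tests, and
centrality trajectories with the four-parameter logistic fit as CSV/JSON.

## Layout

| module | contents |
|---|---|
| `hilldeg.distributions` | stationary pmf (log-space recurrence + α=1 closed form), mode, centralities, Gamma burst null |
| `hilldeg.preprocess` | table reading/validation, fluorescence→count rescaling, passage selection |
| `hilldeg.inference` | likelihood, ML fits, AIC/BIC/AICc, profile intervals, adaptive Metropolis, posterior summaries |
| `hilldeg.gof` | binned r² statistic, parametric-bootstrap p-values |
| `hilldeg.trends` | log-odds transform, weighted trend tests, centrality trajectories, 4-parameter logistic |
| `hilldeg.synthetic` | exact samplers, Gillespie oracle, study generator with ground truth |
| `hilldeg.pipeline` / `hilldeg.cli` | orchestration, report writing, `hilldeg` command |
| `hilldeg.validation` | the simulation studies behind the acceptance script |

`docs/methods.md` documents the model, the numerical choices (log-space
recurrences, ridge-aligned posterior sampling, interval conventions) and
the known identifiability limits.
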