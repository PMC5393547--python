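# Methods

## Process model

The package models each lake's plankton community as a discrete-time
Lotka–Volterra pair observed with error. States advance one step per
sampling interval (visits are treated as unit time steps; all rates are
per interval, since the discrete equations carry no Δt):

    x' = x + ψ x − c x y        (phytoplankton, chlorophyll-a µg/L)
    y' = y + c e x y − m y      (zooplankton biomass, µg/L dry mass)

Assumptions worth stating plainly:

- **Deterministic latent dynamics.** All stochasticity is observation
  error; there is no process noise. The likelihood of a lake is therefore
  a function of its initial state and rates only.
- **Clipping at zero.** The raw map can go negative for large rates;
  abundances are physical, so updates are clipped at zero and the event is
  logged. Zero is absorbing.
- **Covariate links.** `c = α_c + β_c·ST` (identity link — `c` may go
  negative; the sampler permits this and the pipeline reports the
  posterior mass on negative consumption anywhere in the observed
  temperature range, while the data generator refuses such regimes) and
  `log ψ = α_ψ + β_ψ·SP` (log link, `ψ > 0` guaranteed). Mortality takes
  two levels by fish presence. `e` is a single efficiency shared across
  lakes. Covariates are standardized (mean 0, sd 1, n−1 denominator) over
  exactly the lake set being fitted, so excluding lakes changes ST/SP.
- **Observation model.** Measurements are normal around the latent states
  with spreads σ_x, σ_y. These are interpreted as **standard deviations**
  throughout (the conventional reading of σ), not variances.

The interior equilibrium `(x*, y*) = (m/(c·e), ψ/c)` is exposed both as an
interpretive quantity (predator zero-isocline position) and as a test
identity: `step()` leaves it invariant to machine precision.

## Inference

Estimated quantities: `α_c, β_c, α_ψ, β_ψ, m_fish, m_nofish, e, σ_x, σ_y`
plus per-lake initial states `x1_j, y1_j` — `9 + 2L` parameters.

**Priors** (defaults, all overridable): normal(0, 10) on the link
coefficients; uniform(0, 1) on the mortalities and on `e`; half-normal
with scale set to the data spread on σ_x, σ_y; lognormal centred on the
first observation (log-sd 1) for each initial state. A `fixed` family pins
any parameter, which the test suite uses to carve out one-dimensional
conditional subproblems. Constraints are enforced by rejection
(log-posterior −∞ off support), not by transformation.

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs: the nine
globals are updated single-site, the initial-state vectors with
independent per-lake proposals (valid because lakes are conditionally
independent given the globals), plus one correlated joint proposal over
all nine globals using the empirical covariance accumulated during
burn-in (Haario-style). Proposal scales adapt toward 44% acceptance
(25% for the joint move) during burn-in only, so retained chains are
Markovian.

The deterministic-trajectory likelihood is rugged: small-σ fits produce
knife-edge ridges and well-separated local modes, and plain
Metropolis-within-Gibbs reliably traps chains (R-hat ≫ 1.1). Each chain
therefore runs **replica exchange**: `n_temps` coupled replicas (default
4) whose likelihood is raised to powers on a geometric ladder from 1 down
to `min_temp = 0.02`, with adjacent-pair swap proposals every iteration;
only the cold replica is retained. Chains start from overdispersed prior
draws (spread-shrunk for the unbounded coefficients so initial
trajectories are finite-scale), retried until the log-posterior is finite.

Default desk-scale protocol: 3 chains × 20,000 iterations, 8,000 burn-in,
thinning 2 — sized so a 40-lake, 12-visit fit takes on the order of a
minute. `MCMCConfig.paper_protocol()` (or `--paper-mcmc`) restores the
original survey's 3 × 250,000 / 100,000 / thin 3.

**Diagnostics and summaries.** Split R-hat (each chain halved, classic
between/within ratio, **no rank normalization**; the split form is more
conservative than the unsplit original). Effective sample size comes from
arviz. Summaries report the posterior mean, equal-tailed 95% interval
using linear-interpolation (type-7) quantiles, the fraction of draws below
zero, R-hat and ESS. Pipeline runs with any R-hat ≥ 1.1 are flagged, never
silently accepted. A dense-grid evaluator (`grid_posterior`, trapezoid
weights, masses summing to 1) serves as the independent oracle for
one-parameter marginals; the suite requires total-variation agreement
< 0.05 on 25 cells.

## Synthetic survey generator

The generator emulates the study design the analysis assumes:

- ~20 lakes × 4 visits (`paper` preset); vegetation cover uniform on
  [0, 100]%; log totN, totP and TOC linear in cover with normal noise,
  **redrawn into the printed ranges** (totP 2.2–18 µg/L, totN 40–400 µg/L,
  TOC 1–10 mg/L); temperature uniform on 10–13 °C; fish presence
  Bernoulli(0.5).
- Noise sds on the log scale (0.51 / 0.58 / 0.53 for totN / totP / TOC)
  were calibrated once by large-sample Monte-Carlo so the OLS r² of
  log-nutrient on cover approaches 0.58 / 0.42 / 0.54. The range-redraw
  truncation attenuates the *observable* regression slope ~20–30% below
  the generating line slope; tests assert the attenuation band, not the
  raw line.
- Generating rates use the reported central estimates (`m_fish = 0.44`,
  `m_nofish = 0.03`, `β_ψ = 0.559`, `β_c = −0.003`) with values the
  original report does not state chosen once for dynamical plausibility:
  `α_c = 0.04` (so the temperature effect spans ~26% of the consumption
  rate across the covariate range), `α_ψ = log 0.35`, `e = 0.3`,
  `σ_x = 0.15`, `σ_y = 0.75`, initial states lognormal around medians
  (1, 5) with log-sd 0.3.
- Observation noise is redrawn until positive (a truncated normal);
  redraws are counted and logged. At the default design the truncation
  changes the empirical noise sd by < 2%.
- `outlier_lakes` inflates a listed lake's nutrients ×8, mimicking a
  bird-fertilized pond, for exercising the exclusion flag.

The `high_info` preset (40 lakes × 12 visits) exists for recovery studies
and differs deliberately: `α_ψ = log 0.12` (the survey-replica growth
rates explode over 12 steps — the discrete map spirals outward), initial
medians (1.5, 4.0), and small noise `σ_x = 0.05`, `σ_y = 0.02`. σ_y was
set small enough that late-season zooplankton in fish lakes (which decays
to ~10⁻² µg/L) stays clear of the positivity truncation; at larger σ_y
the truncated observations bias `m_fish` downward by about one CI
half-width. An `init_near_equilibrium` option draws initial states around
each lake's equilibrium instead; it keeps trajectories bounded but was
*not* adopted for the preset because near-equilibrium data make `m` and
`e` nearly collinear (`c·e·x ≈ m`) and destroy identifiability —
transient dynamics are what identify this model.

**What the generator does not emulate:** seasonal temperature
trajectories, spatial structure among lakes, process (demographic)
stochasticity, and saturating (Holling II/III) functional responses.
Passing recovery tests therefore show the estimator is correct *under the
model's own assumptions*, not that field data satisfy them.

## Correlative layer

OLS (statsmodels) with the slope F-test, df (1, n−2), on per-lake values;
random-intercept linear mixed models (statsmodels MixedLM, ML) for
per-visit chlorophyll on per-lake nutrients, tested by likelihood-ratio
chi-square with df 1 — reported as df 1 even though field reports
sometimes print F-style "1, n−2" bookkeeping next to a χ². All variables
are natural-log transformed. Degenerate fits (zero random-intercept
variance, non-convergence) are flagged in the result rather than raised.
Null calibration: with the per-lake covariate shuffled across lakes the
LRT rejects at ≈5–6% over 200 replicates (the suite enforces ≤ 7%).

## Numerical choices

- Likelihood kernel JIT-compiled with numba (pure-numpy fallback kept).
- Replicate seeds in recovery experiments are `base_seed + index`;
  generator and sampler streams come from `numpy.random.SeedSequence`
  spawning, so every artifact is reproducible byte-for-byte given a seed.
- Quantiles: linear interpolation (type 7). Zero-variance R-hat is defined
  as 1 with a warning.
- Problem sizes in the shipped tests are scaled to desk hardware: the
  recovery calibration uses 20 replicates of a 12-lake × 8-visit design
  with 2 × 6,000 iterations; the headline recovery run uses the full
  40 × 12 preset with 3 × 20,000.

## Known limitations

- No process noise: environmental stochasticity in the dynamics is
  absorbed into observation error, which can overstate precision on real
  data.
- The plain-normal observation model ignores the positivity of
  concentrations; strongly truncated regimes (latent states ≪ σ) bias
  rate estimates (quantified above for `m_fish`).
- Replica exchange multiplies likelihood evaluations by `n_temps`; the
  paper-scale protocol (3 × 250k) takes tens of minutes.
- Identity-link consumption can imply negative grazing within the
  posterior; this is reported (`negative_consumption_rate_mass` in
  `run_meta.json`) rather than forbidden.
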