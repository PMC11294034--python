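# Methods

This note documents the model, the synthetic-data generator, the sampler
and the analysis definitions, including the choices made where several
defensible options existed.

## Population model

A pre-breeding census with three age classes and explicit breeder /
non-breeder stages per sex (stages 1–5 for females, plus an immigrant
stage 6 for males; everybody aged 3+ breeds). Transitions are the
Poisson/binomial equations given in the README. Three structural points
deserve spelling out:

- **Recruitment is a destination-year rate.** The transition from year
  `t` uses survival and productivity of year `t` but recruitment
  probabilities `α` and the immigration expectation `ω` of year `t + 1`:
  whether a surviving bird starts to breed, and how many immigrants
  arrive, is decided in the year of arrival. All code carries this
  one-step lookahead explicitly.
- **The floater split is a trinomial.** Writing the stage-3 and stage-4
  inflows from the 1-year floaters as two independent binomials on the
  same pool can produce more survivors than floaters. We instead split
  each floater trinomially into (still floater, recruit, dead), which has
  the same marginals and cannot violate the pool. Internally stage 4 is
  carried as two components — recruits from stage 1 and surviving stage-2
  breeders — so every transition density is a simple Poisson, binomial or
  trinomial pmf; the public 11-stage state merges them, and the public
  transition density sums the split out (populations are small, the
  convolution is cheap).
- **Immigrants are transient in stage 6.** Stage 6 holds only the current
  year's arrivals; survivors join the 3y+ pool (stage 5) the following
  year, because the adult-survival binomial pools stages 3–6.

Temporal random effects sit on every rate's link scale: logit for
probabilities, identity for brood size `ρ`, log for `ω`. Link-scale draws
are clamped to (−20, 20) before inverse-linking (probabilities of exactly
0/1 are representable in simulation but excluded from link-scale
sampling); identity-link draws of `ρ` are floored at 0.

"Breeding pairs" always means breeding females (stages 2 + 4 + 5): the
female pre-breeding census is what a territory survey counts. The growth
rate analysed by the perturbation machinery uses all individuals aged ≥ 1
of both sexes; the pair series is used for count-style summaries (CV,
geometric mean). Both definitions are switchable
(`Trajectory.totals(population=...)`).

## Synthetic data generator

`simulate_individuals` realizes the model at the individual level: each
bird carries sex, cohort, stage per year, death year and (for breeding
females) per-brood outcomes. Brood size of a successful brood is drawn
from a zero-truncated Poisson with rate `ρ` — matching the productivity
likelihood — whose mean `ρ/(1−e^{−ρ})` slightly exceeds the `η·ρ`
production expectation used in the aggregated projection; this small
internal approximation is inherent to modelling success and brood size
separately, and is shared by the fitted model. Aggregating individuals
reproduces a valid stage trajectory exactly (tested), which makes the
generator an internal consistency oracle for the projection.

The observation layer is independent of the demographic layer: Poisson
noise on territory counts (exact census optional — whether real territory
counts carry observation error is not knowable from count data alone, so
both are supported with Poisson as default); annual feather
identification of each breeder with probability `p[sex]` (generating both
the breeder class counts and the capture histories, which is why the
likelihood shares `p` between those two components); broods monitored with
probability `brood_obs_frac`, fledglings sexed per brood with
`brood_sexed_frac` (so the sex-ratio table can be smaller than the
brood-size table, as in real data); nestlings ringed with `ring_frac`;
each death of a ringed bird reported with probability `r[sex]`.

**The goshawk-like preset** (`presets/goshawk.yaml`, versioned) encodes
the study conditions: 47 years, 40 initial pairs, male-biased fledgling
sex ratio (ξ ≈ 0.43–0.47), female first-year survival above male (0.29 vs
0.23), adult survival ≈ 0.79, age-increasing productivity with η·ρ ≈
1.17 / 1.80 / 2.10 fledglings per initiated brood, and ω = 2 male
immigrants per year. First-year survival was calibrated once, by
simulation with the individual-based generator, so the realized long-run
geometric growth of pairs is ≈ 0.99 and the CV of pairs a few tens of
percent; temporal SDs are largest for first-year survival (0.35 on logit)
and smallest for adult survival (0.12), making first-year survival the
dominant source of environmental variance by construction. Detection
parameters (p ≈ 0.70 female / 0.35 male, r ≈ 0.10, 90% ringing) reproduce
the rough sample sizes of a half-century field effort (thousands of
ringed nestlings, hundreds of identified adults).

What the generator does **not** emulate: feather misidentification,
within-season timing, dispersal distances and spatially varying recovery
effort, individual quality or senescence beyond the three age classes.
Parameter-recovery results on these data therefore demonstrate the
estimator's correctness under the model's own assumptions, not robustness
to those violations.

## Likelihoods

The component forms are the standard IPM choices: Poisson count
observation on pairs; binomial thinning of true breeder classes (class
1 = stage 2, class 2 = stage 4, class 3+ = stage 5, plus stage 6 for
males) sharing `p` with the CJS component; Bernoulli brood success;
zero-truncated Poisson brood size (counts ≥ 1 by the definition of
success); binomial brood sex counts; CJS conditioned on first
identification with age advancing deterministically along the history
(class 1 → 2 → 3+, so interval survival uses s2 then s3); and a
Seber-style recovery model in which a bird ringed as nestling in year
`t0` is recovered in interval `k` with probability
`(∏_{j<k} s_{age(j)}) (1 − s_{age(k)}) r`, with the complement for birds
never recovered within the horizon. Recovery probabilities are indexed by
the interval's starting year. Recruitment `α` is informed through the
state-space breeder counts, not through the CJS (which conditions on
being a breeder). Data impossible under a latent state return `−∞`, never
an exception.

The CJS component is evaluated on its m-array sufficient statistics
grouped by (sex, age class at release) — exactly equivalent to the
individual-history product, which is kept as an independent
implementation and tested against it.

## Sampler

No general-purpose probabilistic-programming backend is used; the sampler
is a purpose-built adaptive Metropolis-within-Gibbs over the exact
discrete model, with one "iteration" being a full scan:

1. **Latent abundances**: integer random walks on each of the 13 internal
   stage components, updating even and odd years as two vectorized
   batches (sites two years apart share no likelihood terms, so
   element-wise acceptance is valid). Each site's conditional touches
   only its adjacent transition terms and same-year observation terms.
2. **Year-local rates** (`η, ρ, ξ, α, ω`): all years of one rate proposed
   and accepted element-wise the same way.
3. **Survival, resighting, recovery**: year-by-year Metropolis against
   cached full CJS/recovery evaluations (these likelihoods couple years
   through the never-seen-again and cumulative-survival terms); caches
   are kept per sex, and transition terms are restricted to the term
   families the rate actually enters.
4. **Hyperparameters**: conjugate Normal updates for the link-scale means
   `μ_θ` (prior Normal(0, 10²)), slice sampling for the temporal SDs
   `σ_θ` (prior Uniform(0, 10)), and conjugate updates for the
   density-dependence slopes `β_θ` (prior Normal(0, 10²)) when active.

Initial latent states are built from the observed counts and breeder
classes (inflated by a detection guess so binomial observations are
feasible), followed by a single backward feasibility pass that raises
unobserved pools where a transition would otherwise be impossible;
initialization retries with fresh jitter if the joint density is not
finite, and errors after bounded retries. Initial-year abundances carry a
discrete-uniform prior on [0, 3 × initial estimate]. Proposal scales
adapt during burn-in toward ~0.42 acceptance. Split-R̂ and effective
sample sizes (via ArviZ) are reported for all hyperparameters with a
warning above 1.05.

Priors, like the component likelihood forms, are this package's own
reconstruction of standard vague IPM choices; both are switchable
(`FitConfig`, `components=...`) so alternatives (e.g. normal instead of
Poisson count observation) can be slotted in.

**Problem sizes.** The replication configuration (3 chains × 110,000
iterations, 10,000 burn-in, thin 50) is available via
`FitConfig.paper_replication()` / `--replicate-paper`, but a full scan of
this sampler moves every unknown once, so far fewer scans are needed than
single-site iterations. The desk configuration used throughout the tests
and the acceptance script runs hundreds to a couple of thousand scans on
12–47-year data sets; parameter-recovery experiments use 16-year data
with perfect detection and 10 replicates. These sizes are the package's
default experiment design; all of them are arguments, not constants.

## Perturbation analyses

Because the expected one-step map is linear in the stage vector, the
realized growth rate at rates `θ` and relative structure `u` is
`λ(θ, u) = 1′M(θ)u + ω/N` (immigration is an absolute influx, hence the
`1/N`). Derivatives are exact (complex-step; matched against central
finite differences to 10⁻³ in the tests).

- **Elasticities**: `(x/λ) ∂λ/∂x` per posterior draw, at the draw's
  temporal means of rates and structure — a real-time (transient)
  formulation; no asymptotic eigen-analysis anywhere.
- **LTRE contributions**: first-order decomposition
  `var(λ_t) ≈ Σ_ij s_i s_j cov(x_i, x_j)` over the 20 rates (lookahead
  rates aligned to the transition they act on) and 11 structure
  proportions, with sensitivities at temporal means and covariances over
  years within each draw. Reported as relative row sums (cross-covariances
  split evenly), so the rate ("direct") and structure ("delayed")
  aggregates add to 1 by construction.
- **Stochasticity split**: per draw, the expected trajectory is
  propagated from the realized first-year state under the realized annual
  rates; its growth rates carry environmental variation alone, the
  residual `λ_actual − λ_env` the demographic part, and the environmental
  share is `var(λ_env) / (var(λ_env) + var(λ_dem))`. The variance-ratio
  definition (rather than, say, a covariance attribution) is a documented
  choice; with zero environmental variance a small transient-structure
  residue remains in `λ_env`, which decays with series length.
- **Derived summaries** are all draw-wise: geometric mean and CV of
  pairs, `η_a ρ_a` per maternal age, composition proportions, the
  first-time/experienced/immigrant breeder decomposition (using the
  internal stage-4 split), pooled fledgling sex ratio and adult sex
  ratio. Posterior means are never plugged into nonlinear functions.

## Density dependence

`dd_slope` supports two conventions that differ by exactly 1: the levels
regression (log N_{t+1} on log N_t; no-feedback value 1) and the growth
regression (log λ_t on log N_t; no-feedback value 0). The growth
convention is the default — reported slopes like "observed −0.2 vs null
−0.1" only make sense there. The null reference is a parametric bootstrap
of the fitted density-independent model: one stochastic projection per
posterior draw under that draw's hyperparameters, matched in length and
starting state; the evidence is P(b_obs < b_null) over paired draws. The
null's negative bias (the same noisy N on both sides of the regression)
is verified by simulation in the tests, as is type-I calibration
(≈ 5% rejection at the 0.95 threshold) and power against strong feedback.

The rate-level variant `fit_ipm_dd` replaces `μ_θ` by `μ_θ + β_θ x_t`
with `x_t` the standardized latent female total (centering/scaling
constants fixed from the data — 1.35 × mean count and 30% of that by
default — so `β` is per SD-sized change in female numbers; division by
the scale recovers the raw-scale slope). Density dependence on
immigration is deliberately unsupported (no mechanism to encode). In the
generator's DD mode, survival and productivity respond to the exact
current female total while destination-year rates (recruitment,
immigration) lag one year, since the destination state does not yet exist
when they are needed.

## Numerical details and limitations

- All pmfs are evaluated in log space with clipped logs (≈ −690 per unit
  rather than −∞ inside cumulative sums) so that impossible regions
  reject cleanly without NaNs; explicit supports (negative abundances,
  survivors exceeding pools, ρ < 0) return −∞.
- Zero-truncated Poisson sampling uses inverse-cdf with a deterministic
  fallback at extreme rates.
- The trinomial floater split makes generator and likelihood coherent but
  means the two independent-binomial marginals are correlated
  (negatively) rather than independent; marginal distributions are
  unchanged.
- Extinction during simulation truncates the output with a warning;
  analyses raise on extinct trajectories rather than silently dropping
  years.
- Desk-scale MCMC chains are short; R̂ warnings on weakly identified
  parameters (notably recruitment SDs) are expected there and resolve
  under the replication configuration.
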