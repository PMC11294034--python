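# goshawkipm

A two-sex, stage-structured **integrated population model (IPM)** toolkit
for long-term raptor monitoring studies, built around the demography of a
northern goshawk (*Accipiter gentilis*) population followed for close to
half a century: annual territory counts, feather-based identification of
breeders, brood monitoring and ring recoveries of nestlings.

It is aimed at population ecologists who want to

- **simulate** realistic multi-decade monitoring data with known ground
  truth (an individual-based generator produces all seven data sets);
- **fit** the joint Bayesian model linking counts, capture–recapture,
  dead-recovery and productivity data through an explicit two-sex
  population projection;
- **analyse** the fitted model: transient elasticities, retrospective
  (LTRE) contributions to the variance of realized growth, the
  environmental vs demographic stochasticity split, and density-dependence
  tests.

## The model

The population is censused pre-breeding in stages per sex: 1-year-old
non-breeders and breeders (stages 1, 2), 2-year-old non-breeders and
breeders (3, 4), breeders aged 3+ (5), and — for males only — immigrant
breeders (6). With `N_{a,s,t}` the abundance of stage `a`, sex `s` in year
`t`, the female projection is

```
N1,f,t+1 ~ Poisson( F_t · s1,f,t · (1 − α1,f,t+1) )
N2,f,t+1 ~ Poisson( F_t · s1,f,t · α1,f,t+1 )
N3,f,t+1 ~ Binomial( N1,f,t , s2,f,t (1 − α2,f,t+1) )
N4,f,t+1 ~ Binomial( N1,f,t , s2,f,t α2,f,t+1 ) + Binomial( N2,f,t , s2,f,t )
N5,f,t+1 ~ Binomial( N3,f,t + N4,f,t + N5,f,t , s3,f,t )
```

where `F_t = Σ_a N_breeder(a),f,t · η_a,t · ρ_a,t · ξ_a,t` is expected
female fledgling production from breeding success `η`, brood size `ρ` and
fledgling sex ratio `ξ` (proportion female) by maternal age class. Males
follow the same template with `1 − ξ`, plus `N6,m,t+1 ~ Poisson(ω_t+1)`
immigrants who breed as 3y+ birds on arrival. Every rate `θ` carries a
temporal random effect on its link scale, `g(θ_t) ~ Normal(μ_θ, σ_θ²)`
(logit for probabilities, identity for brood size, log for immigration).

The joint likelihood multiplies seven data components — Poisson territory
counts, binomially thinned breeder class counts, Bernoulli brood success,
zero-truncated-Poisson brood sizes, binomial brood sex counts, a
Cormack–Jolly–Seber likelihood for the feather-identified adults (sharing
the resighting probability `p` with the breeder counts), and a Seber-style
dead-recovery likelihood for ringed nestlings — with the exact discrete
transition densities above. Sampling is by adaptive
Metropolis-within-Gibbs with direct integer updates of the latent
abundances (see `docs/methods.md`).

## A worked example

```bash
python examples/05_density_dependence.py
```

```
no feedback        observed slope -0.10  null mean -0.17  P(obs < null) = 0.33
strong DD on s1f   observed slope -0.54  null mean -0.17  P(obs < null) = 0.97
```

Two 30-year populations from the goshawk-like preset. The slope is the
regression of log growth rate on log female population size; it is
negative even without feedback (the same noisy `N_t` sits on both sides),
which is why the test compares against a simulated exponential-growth
null. The density-independent population is unremarkable (P = 0.33);
the one with strong density dependence on female first-year survival is
flagged clearly (P = 0.97).

The other example scripts cover stochastic projection
(`01_project_population.py`), data generation (`02…`), model fitting
(`03…`, a few minutes of MCMC) and the perturbation analyses (`04…`).
There is also a thin command-line pipeline:

```bash
goshawkipm simulate --out data/ --seed 1
goshawkipm fit      --data data/ --out post/          # desk-scale MCMC
goshawkipm analyze  --posterior post/ --out analysis/
goshawkipm report   --dir analysis/
```

`goshawkipm fit --replicate-paper` switches to the full three-chain,
110,000-iteration configuration.

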