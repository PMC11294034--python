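# "goshawk-like" study conditions: a 47-year monitoring series of a
# declining-to-stable raptor population of roughly 30-70 breeding pairs,
# with male-biased fledgling sex ratio, higher female first-year survival,
# age-increasing productivity and moderate male-only immigration.
# Natural-scale long-term means; temporal SDs live on each rate's link
# scale (logit for probabilities, identity for brood size, log for the
# immigration expectation).
version: 1
years: 47
initial_state:
  females: [10, 4, 4, 6, 30]       # stages 1..5 (40 breeding pairs)
  males: [8, 2, 3, 5, 28, 2]       # stages 1..6
means:
  s1f: 0.292
  s1m: 0.233
  s2f: 0.632
  s2m: 0.612
  s3f: 0.798
  s3m: 0.789
  eta1: 0.55
  eta2: 0.72
  eta3: 0.82
  rho1: 2.12
  rho2: 2.50
  rho3: 2.56
  xi1: 0.43
  xi2: 0.46
  xi3: 0.47
  alpha1f: 0.45
  alpha1m: 0.12
  alpha2f: 0.55
  alpha2m: 0.55
  omega: 2.0
sigmas:
  s1f: 0.35
  s1m: 0.35
  s2f: 0.20
  s2m: 0.20
  s3f: 0.12
  s3m: 0.12
  eta1: 0.35
  eta2: 0.30
  eta3: 0.25
  rho1: 0.20
  rho2: 0.20
  rho3: 0.20
  xi1: 0.12
  xi2: 0.12
  xi3: 0.12
  alpha1f: 0.25
  alpha1m: 0.25
  alpha2f: 0.25
  alpha2m: 0.25
  omega: 0.40
observation:
  pf: 0.70          # annual feather-identification probability, females
  pm: 0.35          # males roam while hunting: fewer feathers found
  rf: 0.10          # dead-recovery probability per death
  rm: 0.10
  sigma_p: 0.30     # temporal SD of p on the logit scale
  sigma_r: 0.30
  brood_obs_frac: 0.85
  brood_sexed_frac: 0.95
  ring_frac: 0.90
  exact_census: false
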