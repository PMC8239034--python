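# Methods

## The observation problem

Two endoparasitoid species attack the same host species in sequential
24-hour exposures.  Only three things are observable per arena: the
number of hosts offered (itself realized with up to 10% error around
the nominal density), and the number of adult wasps of each species
that eventually emerge.  Multiparasitism, larval contests, host
feeding-site rejection and oviposition-induced host death all happen
inside hosts less than half a millimetre long.  The package therefore
models the *expected emergence* of each species as a composition of
mechanisms, and lets model selection decide which mechanisms the counts
support.

## Model composition

For an arena with `p` hosts, first release species *i*, second species
*j*:

1. **Rejection** (optional): a shared proportion `s` of hosts is
   unsuitable; the searchable pool is `p_avail = p(1−s)`.
2. **Functional responses**: `R_i = R(p_avail; b_i, c_i, H_i)` under the
   family and depletion choice of the model (see below).
3. **Overlap**: the expected multiparasitized count is
   `R_ij = overlap(R_i, R_j, p_avail, θ_j)`, governed by the *second*
   female's multiparasitism index only — she is the one encountering
   parasitized hosts.  `overlap` interpolates linearly between the
   Fréchet lower bound (θ=0), the independence product `R_iR_j/p_avail`
   (θ=0.5) and the Fréchet upper bound (θ=1).  This one-parameter
   family is the minimal continuum containing "avoids / random /
   prefers" with a Uniform(0,1) prior and random behavior at the
   midpoint.
4. **Contest**: the first-arriver's larva wins a multiparasitized host
   with probability `w = link((s_first − s_second)/√(σ²_first + σ²_second))`,
   where effective strengths add the first-arrival term `h` for the
   species that oviposited first.  The link is the probit (Thurstone)
   by default; the logistic (Bradley–Terry) is available via the
   `link` entry of the parameter mapping.  Identifiability is fixed by
   anchoring species 1 at strength 0 and deviation 1 — strengths are an
   interval scale, so only differences are meaningful.
5. **Mortality** (optional): a host attacked `n` times produces nothing
   with probability `1 − (1−m)ⁿ`; expectations are thinned by `(1−m)`
   for singly- and `(1−m)²` for doubly-attacked hosts, i.e. mortality
   is applied after contest resolution.  The printed compounding form
   fixes the per-attack structure; whether the original analysis
   applied it before or after the contest is indistinguishable from
   emergence means, and "after" keeps conservation exact.

Expected emergences are then
`E_i = (R_i − R_ij)(1−m) + R_ij·w·(1−m)²` and symmetrically for the
second species.  Conservation holds by construction: `E_i + E_j` plus
expected dead and empty hosts equals `p` exactly.

### Functional-response families

| family | attack rate a(p) | parameters/species |
|---|---|---|
| FRI | b (no handling) | 1 |
| FRII | b | 2 (b, H) |
| FRIII_G | b + c·p | 3 |
| FRIII_GP | b + c·p² | 3 |

Without depletion the Holling disc form `R = a·p·T/(1 + a·p·H)` is
used, truncated at `p` (the form can exceed `p` in extreme corners of
the prior box; the truncation is logged at DEBUG level).  With
depletion the Rogers random-predator equation
`R = p(1 − exp(−a(T − H·R)))` is solved with the principal-branch
Lambert-W closed form; when the W argument overflows (deep-depletion
corner, `a·H·p` large) an asymptotic start refined by Newton iterations
on `w + ln w = y` keeps full precision.  An independent iterative
solver (`rogers_fixed_point`: damped fixed-point iteration with a
bisection safeguard — the Rogers right-hand side is strictly decreasing
in R, so the root is unique and bracketed by [0, p]) is exposed purely
as a cross-check; the two routes agree to 1e−8 across the prior box.
In the type III + depletion case the density-dependent attack rate is
frozen at the offered density: it keeps the Rogers equation scalar, and
emergence means cannot discriminate the alternative.

The exposure duration is fixed at `T = 1` day (each female searched for
24 h; all rates are per day).

### The 112-model family

Candidate models cross: 4 response families × depletion (the type I
family only exists without depletion — depletion requires a handling
process — giving 7 response rows) × mortality on/off × rejection on/off
× 4 competition tiers (absent; basic strengths; + arrival terms;
+ superposition indices).  7 × 2 × 2 × 4 = 112.  Parameter counts are
additive: 2/4/6 response parameters, +1 mortality, +1 rejection, and
+2/+5/+8 for the competition tiers.  The arrival tier's fifth parameter
and the superposition tier's eighth are shared deviation parameters
(σ_h, σ_θ) of the tier's species effects; they are counted in the
model dimension but held at 1.0 during fitting because the emergence
likelihood does not depend on them.  Their identity is a
reconstruction: the printed counts fix the arithmetic but not the
naming.

Below the superposition tier both θ are pinned at 0.5 (random overlap);
below the arrival tier the h terms are 0; with competition absent the
contest is a coin flip.

## Likelihood and priors

Each species' emergence count in a trial is
`Binomial(n_offered, E/n_offered)` (success probabilities clamped to
[1e−12, 1−1e−12]); single-species baselines contribute only the
released species' term.  A trinomial per-trial alternative
(species 1 / species 2 / neither) is available behind
`kind="trinomial"`; the binomial form is the default.  The
`n_unparasitized` column is used for validation only.

Priors: Uniform(0,1) for b, c, H, θ, s, m; Normal(0, sd 10) for μ₂ and
the h terms; HalfNormal(10) for σ₂ (the "deviance 10" of the vague
competition prior is read as a standard deviation of 10 — either
reading is vague).

## Samplers

**Within-model**: componentwise random-walk Metropolis with boundary
reflection, proposal scales adapted toward 0.35 acceptance during
burn-in only (frozen afterward for detailed balance).  Two additions
matter for this likelihood's geometry:

* an **adaptive block move** (Haario-style): one correlated
  full-vector proposal per sweep with covariance 2.38²/d times the
  running burn-in sample covariance;
* two **ridge moves** exploiting exact mean-invariances of the
  no-depletion likelihood.  Single-curve means are invariant under
  `s → s′, b → b·r, c → c·r²` with `r = (1−s)/(1−s′)`, and under
  `m → m′, b → b·r, c → c·r, H → H/r` with `r = (1−m)/(1−m′)`.  The
  moves propose a new s (or m) and rescale the attack parameters to
  stay on the ridge, with the rescaling Jacobian in the acceptance
  ratio.  Without them, componentwise chains freeze wherever they enter
  the ridge and credible intervals are spuriously narrow.

Split-R̂ is computed (via arviz) from half-chains and reported in every
summary.  Initialization draws from the priors with a finite-likelihood
retry cap.

**Between-model (reversible jump)**: each outer iteration refreshes the
current model with a configurable number of within-model sweeps, then
proposes a uniformly drawn other candidate; shared parameters carry
over, newborn parameters are drawn from their priors, and the move is
accepted on `Δ(logL − 2·k)` with `k` the model's parameter count — the
published penalty of 2 log-likelihood units per parameter.  With zero
penalty and equal dimensions this reduces to plain Metropolis on the
log-likelihood.  Post-burn-in visit frequencies are the model weights;
model-averaged summaries pool the recorded draws over all visits of
models containing a parameter, reporting the visited fraction as the
parameter's weight.

**Chain-length presets.**  The published analysis ran 60,000 outer
iterations (40,000 burn-in) with 10,000 within-model iterations per
jump.  The package's defaults are desk-scale (fits: 1,000 burn-in +
2,000 kept; selection: 1,000 outer × 5 inner), chosen so a full
fit-and-select cycle runs in tens of seconds; the tests use similar
sizes.  All results are reproducible from the seed.

## The synthetic-experiment generator

`simulate_trial` draws one arena host by host: realized density
uniform within ±10% of nominal (rounded, ≥1); a **deterministic**
unsuitable count `round(p·s)` — a binomial draw here would break the
exact agreement between generator means and the analytic expectation
through Jensen's inequality in the nonlinear response; attack totals
`Binomial(p_avail, R/p_avail)`; the second species' attacks placed on
parasitized vs. unparasitized hosts so that the expected double-attack
count equals the analytic overlap — the target is scaled
multiplicatively by the realized/expected attack ratios
(`overlap·(n₁/R₁)(n₂/R₂)`), which preserves the unconditional mean
exactly by independence of the two binomials, then clamped to the
realized Fréchet bounds (clamping is the only, negligible, source of
bias); contests resolved per host by `w`; mortality as independent
survival thinning.  The per-trial accounting identity
`emerged₁ + emerged₂ + dead + untouched + unsuitable = offered` holds
exactly for every simulated arena and is asserted in the generator.

Default design = the laboratory design: sequential exposures in both
orders at densities {10,…,90,110} (one arena each — the published
exposed totals, 582 and 586 nymphs, match a single replicate of the
550-nymph density sum within the 10% jitter), single-species baselines
at {10,20,40,60,80,110} with five replicates.  (The published baseline
exposed totals, 1946 and 1981, exceed the 1600-nymph arithmetic of the
stated design; the discrepancy is unexplained in the source and the
stated design is kept.)

What the generator does *not* emulate: egg limitation across an
exposure, within-exposure re-encounters beyond what the response form
captures, spatial structure of the host patch, and any dependence of
host suitability on density.  Passing recovery tests therefore show
that the inference machinery is correct and calibrated *under the
model's own assumptions*, not that the model is true of real arenas.

## Identifiability, honestly

Without depletion the emergence means constrain only `b(1−s)`,
`c(1−s)²` (rejection) and `b(1−m)`, `c(1−m)`, `H/(1−m)` (mortality):
the proportions are identified solely by saturation curvature and by
the `(1−m)²` thinning of doubly-attacked hosts.  Consequences, all
verified numerically:

* Credible intervals for s and m are honestly wide, and intervals for
  c can sit above a corner truth (small c with small s, m) because the
  vague priors spread mass along the ridge.  The recovery test
  therefore checks *pooled* coverage across parameters and seeds
  (≥80%), not per-parameter nominal coverage.
* A rejection proportion `s = 2m/(1+m)` reproduces a mortality model's
  expectations on both singly- and doubly-attacked hosts exactly for
  near-linear responses, so mortality-vs-rejection selection is
  ill-posed in that regime.  The selection sanity test for the
  mortality direction uses the nested pair {flags-off, mortality-on}
  and a high-overlap design (densities 10–30, attack rates near the
  prior ceiling, 30 interaction replicates per density) where the
  quadratic thinning carries real information.
* The printed contest proportions (≈0.9, ≈0.7) are posterior summaries
  over draws, not point transforms of posterior means, and are not
  treated as deterministic targets.

## Numerical conventions

* Probabilities clamped at ε = 1e−12 in likelihoods.
* Holling responses truncated at p; Rogers solutions clipped to [0, p].
* Overlap inputs validated against their pool (`0 ≤ R ≤ p_avail`);
  a positive attack total with an empty pool raises.
* Percentages print at 2 decimals; the per-protocol total percentage is
  the sum of the rounded per-species percentages (the published
  convention).
* Model strings serialize as `FAMILY:DEPLETION:M?:R?:TIER`, e.g.
  `FRIII_G:NHD:M1:R1:Csup`, and round-trip losslessly.
* Every stochastic entry point takes a seed; same seed, same bytes.
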