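# Methods

## The scientific setting

In staged hermit-crab shell fights a larger attacker raps its shell
against a smaller defender's shell in bouts, and may evict the defender.
Each rap can leave a mark (point of impact, POI) on the defender's body
whorl.  The package analyses the spatial distribution of those marks at
two scales: coarse (which of two anatomical target zones a strike falls
in — zone 1 adjacent to the upward-facing aperture, zone 2 perpendicular
to it) and fine (distance of each POI to two landmarks: the apex, A, and
the junction of outer lip and body whorl, B).

## Preprocessing

- **RWD** = 1 − defender weight / attacker weight.  Positive when roles
  follow convention; a negative value is legal but warned about.
- **Size scaling.**  POI distances are divided by the cube root of the
  defender's shell weight.  Shell weight grows roughly with the cube of
  linear size, so the exponent 1/3 makes the correction dimensionless.
  Distances carry no unit in files; every downstream statistic is
  either scale-free (tau, proportions) or reported on the scaled axis.
- **Zone proportions** use all POIs of a fight as denominator,
  including those outside both zones, so prop₁ + prop₂ ≤ 1.  Zone
  membership is taken from the input label, never recomputed from
  distances: the zones are anatomical regions, not distance thresholds.
- **POI–rap consistency.**  Kendall tau-b between per-fight POI counts
  and rap counts; a clearly positive value is the sanity check that
  marks track actual raps despite over- and under-marking.
- **Outlier protocol.**  No published rule exists for this analysis, so
  the package uses Tukey fences with k = 3 (linear-interpolation
  quartiles) on the zone-1 proportion, and reports every correlation
  and GLM both with and without flagged fights.  k and the variable are
  configurable.

## Coarse-scale model

Binomial GLM with logit link: eviction ~ pz1 * pz2 + RWD, fitted by
IRLS (convergence: score max-norm < 1e-8 or relative deviance change
< 1e-10, ≤ 100 iterations, step-halving so the likelihood never
decreases).  Rank deficiency is an error naming the aliased columns;
|β| > 30 triggers a complete-separation flag rather than an error.
Terms are tested by likelihood-ratio (deviance) χ², not Wald — better
behaved near separation and matching the reporting convention of
χ² with one df per dropped term.  The interaction stays in the fitted
model regardless of significance.

Kendall tau-b uses the tie-corrected denominator
(C − D)/√((N₀−Tx)(N₀−Ty)); two-sided p from the tie-corrected normal
approximation for n > 8, exact permutation enumeration for n ≤ 8.  An
all-ties variable makes the statistic undefined and raises.

## Fine-scale model (DHGLM)

For POI j of individual (fight) i, y the scaled distance to A or B:

    y_ij = β0 + β_RWD RWD_i + β_out out_i + β_vig vig_i + a_i + e_ij
    e_ij ~ N(0, σ_ij²),  log σ_ij = δ0 + γ_RWD RWD_i + γ_out out_i + γ_vig vig_i + b_i
    a_i ~ N(0, σ_a²),  b_i ~ N(0, σ_b²)

Outcome is coded eviction = 1.  Covariates are standardized (mean 0,
SD 1 across individuals) before sampling and every reported draw is
back-transformed, so all summaries are on the raw covariate scale.
Four runs: response A or B, whole shell or zone-1 POIs only.
Individuals with a single POI are retained (they inform the mean model;
their SD information is prior-dominated) and counted in diagnostics.

**Priors.**  Normal(0, 10²) on each standardized-scale fixed effect;
half-Cauchy(2.5) on σ_a and σ_b.  All prior constants are fields of
`DHGLMSpec`, so informative choices can be swapped in.

**Sampler.**  Metropolis-within-Gibbs.  Because all covariates are
per-individual, σ_ij is constant within an individual and the posterior
depends on data only through (n_i, Σy_ij, Σy_ij²); one sweep is
O(individuals).  The mean-model coefficients and a_i have exact
Gaussian conditionals and are Gibbs-updated; γ, b_i, σ_a, σ_b use
scalar random-walk Metropolis on the identity (γ, b) or log (σ) scale,
step sizes adapted by Robbins–Monro toward 0.44 acceptance and frozen
at the end of burn-in.  Defaults: 3 chains with over-dispersed starts,
20 000 iterations, 5 000 burn-in, thinning 5.

**Inference.**  95% central credible intervals; pseudo-P = 2·min(#draws
≤ 0, #draws > 0)/N floored at 2/N (the tail cannot be resolved beyond
one draw); split-chain R-hat and autocorrelation ESS (Geyer's initial
monotone positive-pair truncation).  R-hat > 1.05 or ESS < 400 flags
the run non-converged — the result is still returned, with a warning
and exit code 2 from the CLI.

## Synthetic-data generator

The generator emulates the data structure the analyses assume, with
every latent written to `truth.json`:

- Attacker weight ~ U(0.4, 1.73) g (inside the 0.2–1.73 g range of
  field-collected crabs); RWD ~ U(0.05, 0.6); defender weight derived.
  The defender's shell is sized to the attacker (ratio 2.5 g shell per
  g crab) and the attacker's own shell is 60% of that optimum —
  mirroring the staged-fight design where shell-weight regressions from
  a prior preference experiment set the optimum.  Only the relative
  sizing matters downstream, so a single linear ratio replaces those
  regression equations.
- Bouts ~ 1 + Poisson(11); vigour (raps per bout) ~ Gamma(shape 9,
  mean 8) — pragmatic choices, as no distributional information on rap
  timing is published; total raps = round(bouts·vigour).
- **Strike placement is parameterized on the scaled axis**
  (length·mass^(−1/3)); stored raw distances are scaled draws times
  cbrt(shell weight).  This makes cube-root scaling an exact
  round-trip, so DHGLM recovery targets are the generator's own
  coefficients.  Placement follows exactly the DHGLM above with
  defaults μ_B = 8.6, β_vig = −0.15, β_out = −0.8, δ0 = 0,
  γ_vig = 0.05, γ_out = −0.3, σ_a = 0.8, σ_b = 0.3 (RWD couplings 0),
  truncated at zero — truncation mass is far below 1% at these values,
  so the induced mean bias is negligible.  Distance to A couples to the
  B-deviation with ρ = 0.3; A has no direct covariate effects.
- Zone: "other" with probability 0.05, else zone 1 with probability
  logistic(3.83 − 0.5·scaled dist B) — strikes near landmark B are
  zone-1 strikes; far ones drift into zone 2.
- Outcome ~ Bernoulli(logistic(−1.21 + 3·pz1_latent + 0.15·vigour +
  1·RWD)), where pz1_latent is the *vigour-driven* zone-1 propensity.
  Individual effects a_i are deliberately excluded from pz1_latent so
  that the random effects remain exogenous to the covariates — the
  hierarchical model is then correctly specified on generated data and
  parameter recovery is a fair end-to-end test.
- Marking: n_poi = Binomial(total raps, 0.35) + Poisson(2) — raps may
  leave no discernible mark, or several.

`outcome_b0 = −1.21` and `zone_intercept = 3.83` were calibrated by
Monte-Carlo root-finding at 6 000 fights so that the defaults reproduce
the descriptive anchors of the original experiment: eviction rate
80/94 ≈ 0.851 (measured 0.850), mean zone proportions (0.57, 0.38)
(measured 0.571, 0.379).  The default coupling signs reproduce the
observed phenomenology: positive zone1–vigour and negative
zone2–vigour correlations, and a positive zone-1 effect on eviction.

**What the generator does not emulate:** shell geometry (zones are
labels, not regions of a surface), defender behaviour, bout-level
temporal structure within fights, measurement error in landmark
distances, and any skill–morphology covariance beyond the modelled
couplings.  Passing recovery tests therefore show the estimator is
correct under its own assumptions — not that field data satisfy them.

## Validation design and problem sizes

- Hand-written primitives are tested against independent oracles:
  tau-b vs O(n²) pair enumeration (and scipy as cross-check), IRLS vs a
  BFGS likelihood maximizer (and statsmodels), the posterior density vs
  naive per-observation summation, Gibbs conditionals vs observation-
  level normal-normal algebra, the sampler vs the closed-form Gaussian
  posterior in its conjugate limit, and R-hat/ESS vs arviz.
- Frequency properties use simulation: likelihood-ratio type-I error
  at n = 94 (1 000 replicates), DHGLM recovery at 200 individuals × ~30
  POIs (20 replicates, reduced MCMC lengths of 15 000 iterations / 2
  chains — sizes chosen to keep the full validation suite at a few
  minutes while leaving Monte-Carlo error well below the tolerances
  checked), pseudo-P size on a fully nulled generator, and sign-pattern
  reproduction at the study's own 94-fight scale (50 replicates).
- Determinism: a single seed fixes every byte of generated data and
  every posterior draw; the CLI echoes the config and its hash.

## Known limitations

- The zone-1-only DHGLM refit conditions on a zone label that is itself
  driven by dist_B, so its coefficients are subject to selection
  effects; the whole-shell fits are the ones with a clean causal
  reading, and recovery is validated on those.
- Posterior exactness is Monte-Carlo: very short chains (as used in
  smoke tests) are flagged by the ESS threshold rather than prevented.
- The permutation invariance of results holds up to floating-point
  summation order in the per-individual sufficient statistics.
- Pseudo-P is a posterior tail summary, not a frequentist p-value; its
  "size" on null data is approximately, not exactly, nominal.
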