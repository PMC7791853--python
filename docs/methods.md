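# Methods

## The scoring rubrics as procedures

The Meier examination is encoded as a typed record of criterion levels with
two hard invariants: every field takes exactly one enumerated level, and a
horse with severe difficulty walking is never forced to turn, so the circle
criterion must be recorded `not_assessed` (it scores 0 and the walk's 6
points carry the locomotor severity).  Per-forelimb criteria (foot lift,
digital pulse) contribute the *worse* of the two limbs.  The rubric's table
wording ("each forelimb") could also be read as summing limbs, but summing
would allow totals above 12, contradicting the 0–12 scale; the worse-limb
reading keeps every criterion at its printed maximum.  Exhaustive
enumeration of the 1 152 valid level combinations confirms the attainable
totals are exactly {0, …, 12}, with 12 reachable only through the
severe-walk skip.

The Obel rubric is prose; it is encoded as a decision table with
highest-grade-wins precedence, and an exam matching no grade description is
"normal" (grade 0).  The 0 grade is modelled as a real grade because
longitudinal medians use it.

## The decay model

Scores for horse *i* at day *t*:

y_ij = θ0_i exp(−θ1_i t^θ2_i) + ε_ij, ε ~ N(0, σ²), with
(log θ0_i, log θ1_i, θ2_i)′ ~ N(θ, diag(ω0, ω1, ω2)).

Conventions:

* `0^θ2` is defined as 0 for every θ2, so the day-0 mean is exactly θ0_i.
* θ2_i lives on the natural scale (no log transform), per the random-effect
  vector above.  The generator resamples the rare non-positive θ2 draw
  (and counts them); the fitter does not constrain θ2_i but reports the
  fraction of posterior draws ≤ 0.
* Scores are always *fit* as continuous values.  The generator emits both
  the clipped integer clinical score (`score`) and the continuous model
  draw behind it (`raw_score`); parameter-recovery work fits `raw_score`,
  because clipping at the 0 floor truncates the residual distribution and
  visibly biases late-visit observations (the model's acknowledged
  limitation — see the zero-score diagnostic below).

## Synthetic cohorts

Defaults mirror the study design: 64 fast-improvement horses, visit days
(0, 4, 9, 14, 25, 42), reference population values
(log θ0, log θ1, θ2) = (2.07, −1.95, 1.16), ω = (0.025, 0.361, 0.087),
σ = 0.99; scores clipped to [0, 12] and rounded to integers (clinical
scores are integers).

Slow improvers (default fraction 0.20 when mixed cohorts are requested)
have no known generative mechanism clinically, so the generator uses an
invented one constrained only by the observable pattern: the horse's decay
rate is multiplied by U(0.05, 0.20) and a single Gaussian relapse bump
(amplitude U(1, 3) score points, centre U(18, 34) d, width U(4, 8) d) is
added; draws are rejected until the day-14 score lies in [4, 10] and the
sequence is non-monotone.  Passing tests on these cohorts therefore show
the *machinery* handles waxing/waning trajectories, not that this mechanism
is how real slow improvers arise.

Per-sign decomposition of an integer total uses a fixed per-total table,
validated against the rubric enumerator, that encodes the clinical
resolution order (weight shifting and foot lift resolve first, then the
digital pulse, then walk, then circle: signs stay positive down to totals
10/8/4/2/1 respectively).  A preference rule expressed purely as a
lexicographic ordering cannot produce this pattern because the pulse
criterion only scores 0 or 2; the explicit table was chosen instead.  Real
per-sign scores vary independently of the total, so this deterministic
decomposition reproduces ordering patterns, not per-cell frequencies.

What the generator does **not** emulate: covariate effects (age, breed,
sex, endocrine status), observer effects (25 veterinarians scored the real
cohort), missing visits, and any dependence of residuals on the score
level.

## SAEM estimation

Each iteration: (S) a Metropolis–Hastings sweep updates each horse's
(log θ0_i, log θ1_i, θ2_i) coordinate-wise from its conditional posterior,
with random-walk proposals adapted toward 35% acceptance during burn-in;
(SA) the complete-data sufficient statistics are smoothed with step size
γ_k = 1 during burn-in and 1/(k − k_burnin) afterwards (so smoothing-phase
statistics are plain averages); (M) closed-form updates give θ as the mean
of the smoothed individual statistics, ω as their variances, and σ² from
the smoothed residual sum of squares.  Defaults: 500 burn-in and 200
smoothing iterations with 4 MH sweeps each — at the package's desk-scale
cohorts (≤ a few hundred observations) a fit takes well under a minute, and
the longer exploration phase was adopted after observing occasional chain
wandering along the (log θ1, θ2) likelihood ridge with shorter runs.

Two numerical guards matter:

* **Variance annealing.**  During burn-in a random-effect variance may
  shrink by at most a factor 0.98 per iteration.  Without this standard
  guard the chain can freeze before exploring the individual parameters and
  ω collapses to the floor (10⁻⁴), a degenerate attractor.
* **Ridge awareness.**  With six visits per horse, log θ1 and θ2 are
  strongly anti-correlated both within horses and at the population level
  (an independent Lindstrom–Bates fit of one synthetic cohort shows a
  fixed-effect correlation of about −0.8).  Point estimates of the pair
  therefore wander together across replicates; their replicate means are
  unbiased to within the reported SEs.

Standard errors come from the observed Fisher information assembled by
stochastic approximation of Louis' identity (complete-data gradient and
Hessian are closed-form for this exponential-family hierarchy).  CV% is
100·SE/|estimate|.

The marginal log-likelihood is estimated by importance sampling with a
Gaussian proposal at each horse's posterior mean and 1.3× posterior
variance (accumulated during smoothing); the Monte-Carlo SE is reported,
and when every ω is at the fitting floor the exact closed-form
fixed-effects likelihood is returned instead.  AIC = −2·logLik + 2k with k
counting estimated parameters (7 for the full additive model; 5 when θ2 is
pinned; +1 for the combined error model).

Residual models: additive (default; SD = σ) and additive-plus-proportional
(SD = a + b·|f|, one common convention for a model that is named in the
field but defined differently across tools).  The combined model's M-step
is a small Nelder–Mead minimisation over (log a, log b) on the smoothed
per-observation statistics.

Initialisation uses the two-stage estimates when they are computable, else
moment-based defaults (log mean day-0 score; decay rate from the half-score
day; θ2 = 1).  Degenerate inputs — fewer than two horses, fewer than two
visits for any horse, constant scores — are rejected with diagnostics.

## The two-stage cross-check

`oracle_fit_two_stage` fits each horse separately by nonlinear least
squares and takes population means/variances of the per-horse estimates.
It is deliberately simple and *biased* for noisy or sparse data (per-horse
estimation error inflates the ω estimates — on default-noise cohorts the
two-stage ω1 can exceed the truth by an order of magnitude), but it is
exact on noise-free data and agrees with SAEM on fixed effects at low
noise, which is exactly the regime where it serves as an independent
oracle.  Horses with fewer than four visits are skipped (three-parameter
fit), and per-horse failures are counted, not hidden.

## Cohort summaries

The fast/slow partition uses the day-14 score with threshold 4 (fast
improvers score 0–3 on day 14, slow improvers 4–10); the threshold is
derived from those reported group ranges since no explicit cut is stated in
the source material.  Medians use the midpoint convention for even counts
and quartiles the inclusive (linear-interpolation) convention.  The
Mann–Whitney U test uses midranks for ties; the p-value comes from full
enumeration of rank assignments when both groups have ≤ 8 observations
(scipy's exact method declines ties, so the enumeration is implemented
here) and from the tie-corrected normal approximation otherwise.

## Problem sizes and stochastic checks

The test suite and acceptance script run everything at the study's own
scale: cohorts of 64 horses × 6 visits, with 3–4 replicate cohorts for
parameter-recovery and AIC-preference checks and 5 seeds for
partition-label recovery.  The per-cohort *integer median* at late visits
is genuinely borderline under the reference parameters (about 45% of
day-25 scores are positive after clipping and rounding), so the "typical
cohort median" is measured as the median across replicate cohorts rather
than from a single realisation; the generating parameters, visit days and
partition rule are never adjusted.

## Known limitations

* The Gaussian residual on a clipped 0–12 scale mis-describes observations
  at the floor: `diagnostics` quantifies the systematic standardized
  residual at zero scores and flags it by a one-sample t-test.  An ordinal
  or censored likelihood would remove the artefact but is out of scope.
* SAEM point estimates for (log θ1, θ2) inherit ridge variability; compare
  replicate means, not single fits.
* The importance-sampling likelihood assumes the posterior is roughly
  Gaussian per horse; heavy-tailed weights inflate the reported MC SE
  rather than silently degrading the estimate.
* The slow-improver generator is a phenomenological stand-in constrained
  only by observed day-14 ranges and non-monotonicity.
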