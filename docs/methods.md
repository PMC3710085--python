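# Methods

## The model and the diagnostic

A case-cohort design observes covariates on a simple random subcohort C
of size m (drawn at baseline from a cohort of size n) and on every
incident case. Estimation uses the Prentice pseudolikelihood: each
event's full-cohort risk set is replaced by R̃(t) = C ∪ {i}, the at-risk
subcohort members plus the case itself. In counting-process form a
subcohort member holds the interval (0, tᵢ]; a case outside the
subcohort enters an instant before its own event, (tᵢ − ε, tᵢ], so it
contributes to no foreign risk set. With that construction the
pseudolikelihood has the shape of an ordinary Cox partial likelihood
over the interval data, which is how `cchaz.cox` evaluates it.

The proportional-hazards (PH) diagnostic generalises the Schoenfeld
residual: for the event at t, r(t) = x(t) − E[x(t) | R̃(t)], the
covariate minus its exp(β′x)-weighted mean over the case-cohort risk
set. Conditional on the event history these residuals have mean zero
when PH holds, so a trend of the residuals in time indicates a
time-varying coefficient. `cchaz.phtest` Pearson-correlates each
covariate's residuals with three monotone functions of event time —
the time itself, its rank (average ranks at ties), and the case-cohort
weighted Kaplan–Meier estimate at the event time — and reports
two-sided p-values from the usual t transformation
t = r√((d−2)/(1−r²)) with d−2 degrees of freedom (d = number of
events). The three time scales trade off differently: raw time is
sensitive to the time units and outlying late events, ranks depend only
on the ordering, and the KM scale additionally folds in the censoring
pattern while correcting the case oversampling. No multiplicity
adjustment is applied across covariates or scales; the per-covariate
minimum p-value is exposed, labelled as a minimum, for the conservative
"report the smallest" reading.

## Weighted survival estimation

Because cases are oversampled, the at-risk counts in a case-cohort
sample understate the cohort's. The cumulative-hazard increment is the
weighted Breslow estimator dΛ̂(t) = ΣdN(t) / [(n/m) Σ_{k∈R̃(t)} Yₖ(t)]
and the survival estimate is Ŝ(t) = exp(−Λ̂(t)). This exponentiated
form is the package default; the alternative sometimes seen in
practice — an unweighted product-limit estimate of the sample raised to
the power m/n — differs at O(d/r²) and is available via
`casecohort_km(..., method="product-limit")`. With m = n both reduce to
the standard Nelson–Aalen / Kaplan–Meier pair, which is asserted
against an independent implementation in the tests.

## Fitting: numerical choices

* Newton–Raphson from β = 0 with step-halving (each pseudolikelihood
  term is concave, so the ascent is monotone and the start is safe);
  convergence when max|score| ≤ 1e-9·(1 + |loglik|). The tight default
  matters: the residual columns sum to the score at β̂, and the
  zero-column-sum invariant is asserted at 1e-6 throughout the tests.
* Ties are handled by the Breslow approximation only (tied events share
  a denominator); tie-free simulated data make Breslow and Efron
  coincide anyway.
* Variance is the model-based inverse observed information. A grouped
  dfbeta sandwich (`fit(..., robust=True)`) is available for inference
  on β, but the correlation tests use only β̂ and never touch either
  variance.
* Guard rails: a constant covariate column raises immediately (zero
  information); ‖β‖ > 50 during iteration raises a separation error;
  non-convergence within `max_iter` returns a flagged result rather
  than raising.
* The late-entry offset for outside cases is
  ε = min(Δ/2, t·1e-6) with Δ the smallest gap between distinct
  observed times — small enough to exclude every foreign stop time,
  large enough to stay representable; an unusable policy value falls
  back to t·1e-9 with a warning.
* Scaled residuals follow the standard convention s = β̂ + d·V̂·r with
  the model-based V̂; their lowess smooth (span 0.6, 3 robustness
  iterations) estimates β + G(t). The band is pointwise ±2 local SE
  from tricube kernel weights with a global residual variance — not a
  simultaneous band, so it supports reading the trend, not formal
  testing.

## The simulation laboratory

`cchaz.simulate` registers twelve scenarios on a cohort of n = 2000
with a subcohort of m = 500 (`SCENARIOS`). Event times come from

* piecewise-exponential hazards on the cutpoints 0.3 / 0.5 / 0.8 with
  per-interval rates and per-covariate log hazard ratios that are
  either constant (PH holds) or interval-varying (PH violated), sampled
  by exact inversion of the piecewise-linear cumulative hazard; or
* Weibull hazards, S(t) = exp(−(t/scale)^shape), per exposure group
  (different shapes give a hazard ratio varying as a power of t) or as
  a PH baseline for a continuous covariate.

Covariates are a Bernoulli(0.5) exposure and/or a standard-normal
score. Censoring is Uniform(0, c): the bound c is calibrated once per
scenario by bisection on a fixed pilot sample of 40 000 latent times so
that the cohort event rate hits 7.5%, the midpoint of the 5–10% band
typical of the rare-disease settings that motivate the design (about
150 events per cohort). Using common random numbers in the pilot makes
the event rate a deterministic monotone function of c, so the bisection
is exact to the pilot's resolution; an unattainable target raises with
the achievable range. Each replicate splits its seed into independent
covariate / latent-time / censoring / subcohort-sampling streams, so
every ingredient is reproducible bit-for-bit from one integer.

For the two-group Weibull scenarios the printed shape/scale pairs are
implemented verbatim under the S(t) = exp(−(t/scale)^shape) convention.
Note the hazard-ratio *endpoints* sometimes quoted for such scenarios
are not recoverable from (shape, scale) under any standard
parameterization; the shapes control the t^Δshape rate of change, which
is the feature the tests respond to.

`cchaz.study.run_scenario` ties it together: simulate cohort →
case-cohort sample → counting process → fit → residuals → three tests,
tallying p < α per covariate and per time scale over the replicates.
Replicates whose fit fails are excluded from the denominator and
logged; more than 5% failures flags the result unreliable (at these
sizes failures are in practice absent). `reproduce_tables` lays the
registry out as the two standard summary tables (single-covariate
scenarios; joint binary + continuous scenarios).

## What the generator does and does not emulate

The generator reproduces the structural features the diagnostic cares
about: rare events, oversampled cases, late-entry risk sets, constant
vs drifting hazard ratios, tie-free continuous times. It does not
emulate covariate measurement error, correlated covariates,
time-varying covariates, competing risks, stratified subcohort
sampling, or covariate-dependent censoring. Passing the simulation
suite therefore shows the tests are correctly sized and responsive to
genuine non-proportionality under clean conditions; it does not certify
behaviour under those further real-data complications (left truncation
beyond the ε-device and informative censoring are the notable gaps).

A caution from our own evaluation: in joint models where one covariate
violates PH, the companion covariate's test can inherit mild size
inflation (we observe ~0.07 at α = 0.05 for a PH-true covariate next
to a strongly non-PH one). A small p-value on one covariate is best
followed by the graphical diagnostic before re-modelling everything.

## Problem sizes and determinism

The shipped Monte-Carlo defaults are the study's own: 1000 replicates
per scenario, n = 2000, m = 500 (about 12–15 s per scenario on one
CPU; `--reps` scales the whole harness down for smoke runs). Unit
tests run oracles on small datasets (6–60 subjects) where every risk
set, likelihood term and residual is checkable by hand or by an
independent implementation (`lifelines`, and the piecewise/Weibull
closed forms). All randomness flows through numpy `SeedSequence`
spawning, so any result in the package is reproducible from its seed.
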