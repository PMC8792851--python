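# Methods

## The model chain

`elderhealth` treats elderly health as a discrete-time Markov chain on
five self-rated health states — 1 (healthy), 2 (basically healthy),
3 (unhealthy), 4 (very unhealthy) and 5 (death) — observed at two-year
intervals, the cadence of a biennial panel survey. States 1–4 are
transient, state 5 is absorbing. Three fitted components feed a
projection:

1. a transition model giving the 5×5 kernel P over one two-year step;
2. a two-part expenditure model giving per-capita spending by state;
3. a Chapman–Kolmogorov projection of population counts through powers
   of P, aggregated into total expenditure.

The chain is time-homogeneous: the kernel estimated from one wave pair
is applied unchanged over the whole horizon, which is the standard
assumption when only two waves identify the kernel. Everything that
follows from it (long-run projections especially) inherits that
assumption.

## Transition estimation

The destination state is regressed on the origin state and covariates.
The literal odds formulation — one binary logit of "destination = j"
per j — does not constrain the five destination probabilities to sum
to one, so the canonical parameterization here is a **multinomial
logit** over destinations with destination 1 as the reference and the
origin entering as three indicator variables (origin 1 is the
reference level). Multinomial rows are stochastic by construction,
which the projection requires. A `binary_renormalized` mode fits the
per-destination logits and renormalizes each predicted row; on large
synthetic panels the two modes agree to well under 0.02 per entry, and
both are exposed because either reading of the odds formulation is
defensible.

Two exact identities anchor the tests:

- with an intercept+origin-only design the multinomial MLE is the
  saturated model, so its predicted matrix equals the empirical
  frequency matrix (the counting oracle) to optimizer precision;
- sample-average prediction (averaging predicted rows over the fitting
  panel's covariate rows, not predicting at average covariates) makes
  the covariate model population-averaged, matching the interpretation
  of a cohort-level table.

Origin–covariate interactions are off by default; death enters only as
destination 5 (no separate mortality submodel). Age-group matrices are
empirical frequencies within five-year bins (60–64 … 80+) on the
wave-1 age; bins with fewer than `min_n` (default 30) matched pairs
are flagged rather than silently reported.

## Two-part expenditure model

Whether any spending occurs is a probit in the covariates; the amount,
conditional on occurrence, is linear on the level (yuan) scale with
Gaussian error of standard deviation σ. The joint likelihood
factorizes, so probit MLE plus OLS on the positive observations is the
joint MLE; the joint log-likelihood is reported for completeness. No
log transform or smearing retransformation is used: the level-scale
formulation keeps per-capita values directly interpretable in yuan,
and negative linear predictions are floored at zero in the
unconditional mean E[ME|x] = Φ(x·δ₁)·max(x·δ₂, 0).

Per-state per-capita tables are sample-averaged fitted values: the
mean of E[ME|x] over the covariate rows of panel members in each state
(optionally crossed with age group). Empty cells are missing, never
zero. Two outcomes are carried throughout: family spending per year
and individual spending per month; monthly values annualize by exactly
×12 (spending is assumed stable within the year).

## Projection

One projection step advances each age group's living states through
its kernel, adds the step's deaths to a cumulative state-5 column,
moves a fraction of the bin's living population into the next bin, and
adds exogenous entrants to the 60–64 group.

- **Step length** is 2 years (the kernel's estimation interval).
  Annual series are produced by linear interpolation between grid
  points — transparent and invertible. A `matrix_root` mode instead
  takes genuine one-year steps through the principal square root of
  each kernel (clipped to non-negative entries and renormalized);
  it is provided behind a flag because the root of an empirical matrix
  need not be exactly stochastic.
- **Aging** uses the uniform-within-bin approximation: 2/5 of a
  five-year bin's post-transition living population crosses into the
  next bin per two-year step (1/5 per one-year step in root mode).
  The open 80+ bin retains its members.
- **Entrants** are a required input (a year → count schedule); their
  initial state distribution defaults to the observed baseline shares
  over the transient states and can be overridden. The demo pipeline
  uses an illustrative constant 16 million/year, chosen to be of the
  order of current Chinese birth-cohort sizes reaching 60; it is a
  placeholder, not an estimate.
- **Load-time hygiene**: printed 4-decimal matrices can have row sums
  off by a few 1e-4, and matrix powers amplify drift, so rows are
  rescaled to sum exactly to one at load. Row-sum errors beyond 5e-4
  are rejected. One bundled age-specific table (65–69) carries a typo
  in its printed first row (sum 1.0100); the fixture keeps the printed
  digits and its loader renormalizes that row under an explicit,
  documented tolerance.

Mass accounting is exact: living + cumulative deaths − cumulative
entrants equals the base total at every grid year (interpolated years
inherit it by linearity), and cumulative deaths are non-decreasing.

## Actuarial aggregation

Total expenditure is linear in population: ME_j(t) = N_j(t)·ME̅_j per
state and year, state 5 contributing nothing. Three per-capita bases
are exposed: `monthly` (population × monthly individual value — the
arithmetic behind published national totals built this way), `annual`
(exactly 12 × the monthly totals) and `family_annual`. Discounting and
deflation are out of scope; totals are nominal yuan. Reports print
billions at three decimals with a deterministic (year, age group,
state) ordering.

## Synthetic-data generator

The generator emulates the structure of a two-wave ageing panel:

- baseline covariates from configurable distributions (binary,
  categorical, Gaussian) covering demographic, socioeconomic,
  health-behaviour and social-relation variables. The defaults
  (e.g. P(female)=0.5, BMI ~ N(23, 3), 70 % agricultural household
  registration) are plausible for an elderly Chinese cohort but are
  config defaults, not survey estimates;
- ages uniform over a configurable range (default 60–90), advancing
  two years between waves;
- wave-2 states drawn from a multinomial-logit kernel with arbitrary
  intercepts, origin effects and covariate slopes.
  `TransitionTruth.from_kernel` converts any strictly positive kernel
  into covariate-free coefficients that reproduce it exactly, which is
  how recovery tests plant a known kernel;
- expenditures from the two-part process. A participant whose
  conditional level draw censors to exactly zero is coded as a
  non-participant, so "no care sought ⇔ zero spending" holds exactly;
  under the default truths the level index sits ≥4σ above zero, making
  this a negligible-probability event and keeping the closed-form mean
  valid for oracles.

What the generator deliberately does not emulate: survey weights,
household clustering, attrition and re-entry, measurement error in
self-rated health, and age-dependent transition kernels (unless
planted). Passing recovery tests therefore demonstrate estimator
correctness under a clean data-generating process, not robustness to
those survey features.

## Numerical choices and degenerate inputs

- Matrices validate to row sums within 1e-9 in memory and an exactly
  absorbing death row; powers re-impose both after each product.
- The multinomial fit uses Newton iterations (≤200); perfect
  separation, singular designs, constant covariates, unobserved origin
  states and all-zero/all-positive outcomes raise typed errors naming
  the offender rather than returning silent zeros.
- σ is the maximum-likelihood scaling √(RSS/n₊).
- Ratio and change statistics are reported at the conventional two and
  three decimals respectively; internal precision is full.
- Determinism: every stochastic component runs off a `numpy` Generator
  seeded from the config; identical seeds give byte-identical
  artifacts, and the demo pipeline writes a provenance sidecar
  (version, seed, config hash, row counts) with each run.

## Problem sizes in the test suite

Convergence and recovery checks run at the sizes where their error
bounds are meaningful but cheap: empirical-kernel recovery at a
50,000-person panel against 3-binomial-SE bands; two-part coefficient
coverage over 200 replicates of 5,000-person panels against 99 % Wald
intervals; Monte-Carlo mean oracles at 10⁶ draws (1 % tolerance);
homogeneity of age-stratified matrices by per-bin χ² at α = 0.001.

## Known limitations

- Time-homogeneity of the kernel over a 20-year horizon is a strong
  assumption; nothing in the data can test it with two waves.
- The entrants schedule fully drives long-run population levels; the
  bundled demo schedule is illustrative.
- Linear annual interpolation understates within-step curvature; use
  `matrix_root` when genuinely annual dynamics matter.
- The two-part model has no correlation between participation and
  level equations (no selection-on-unobservables correction).
- Family-level and individual-level totals must not be added together
  (double counting); the aggregation keeps them on separate bases.
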