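# Methods

`phenoshift` estimates long-term shifts in flowering dates from dated,
flowering herbarium specimens, treats those dates as circular data, and
asks whether the magnitude of the shift carries phylogenetic signal.
This note records the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic-data tests do and do
not establish.

## Circular representation of collection dates

A collection date is reduced to its ordinal day-of-year (Jan 1 = 1).
In leap years the ordinal is multiplied by 365/366, so that Dec 31 maps
to day 365 in every year and all years share one 365-day circle; the
difference from the alternative reading (a 366-day denominator in leap
years only) is below 0.01 rad and does not propagate visibly into any
downstream quantity.  Day-of-year `d` in (0, 365] maps to an angle

    theta = 2*pi*d/365 - pi,  theta in (-pi, pi],

a strict bijection whose inverse is used to report results in days.
Records without a complete calendar date (bare years, year-month,
interval event dates) are dropped rather than imputed: imputing a
mid-month day would bias circular means for species flowering near the
calendar wrap.  Only preserved-specimen records are retained;
observation-type occurrence rows are excluded at parse time.

## The regression model

For one species with observations (year x_i, angle theta_i),

    theta_i ~ VonMises(mu_i, kappa),
    mu_i = beta0 + 2*arctan(beta1 * (x_i - x_bar)),

with x_bar the mean collection year (centering is for numerical
stability; the stored `x_center` makes predictions reproducible).  The
tan-half link maps the real line into (-pi, pi), so the mean direction
can never wrap past one full turn from the intercept, which keeps the
"total shift over the observed span" well defined on the link scale.

Priors: beta0 uniform on the circle; kappa flat on (0, inf); beta1 ~
Normal(0, 0.1).  The beta1 prior is the one genuinely open design
choice.  A fully flat beta1 prior produces an *improper* posterior:
as |beta1| grows the link saturates and the likelihood tends to a
positive constant (every enormous slope describes the same step
function), so its integral over beta1 diverges.  On weakly informative
series the impropriety is not academic — chains drift to |beta1| in
the thousands.  The Normal(0, 0.1) scale is vague relative to any
plausible phenological shift (|beta1| = 0.1 corresponds to more than
ten days per decade at the series midpoint, an order of magnitude above
typical herbarium estimates) yet gives step-function regimes negligible
mass.  A flat prior remains available (`beta1_prior_scale=None`) for
sensitivity checks on strongly informative data.

### Sampling

Per chain: a Gibbs update for beta0 (its full conditional is Von
Mises), random-walk Metropolis-Hastings for beta1, and a random walk on
log(kappa).  The beta1 kernel is a mixture: 90% locally scaled steps
(initial scale from the Fisher information 4*kappa*sum(z^2), adapted
toward 44% acceptance during burn-in only, then frozen) and 10% wide
steps at 1.5 prior SDs.  The wide component matters: weak series leave
the posterior multimodal (a central mode plus saturated-link plateaus),
and a purely local walk cannot traverse between the modes.  The mixture
kernel is symmetric, so the acceptance ratio is unchanged and the
retained chain targets the exact posterior.

Defaults mirror the analysis this package operationalizes: 4 chains,
burn-in 200, 2500 retained iterations per chain; chain c is seeded with
`seed + c`.  Convergence is monitored with split Gelman-Rubin R-hat per
parameter (threshold 1.1, flagged not fatal); the circular intercept is
recentered by its overall circular mean before R-hat is computed.
Correctness is established not by trusting the sampler but by a dense
brute-force grid evaluation of the same posterior on small series
(total variation below 0.05 per marginal) plus parameter-recovery and
null-calibration simulations.

### Shifts in days

Per posterior draw, the total shift over the observed span is
`2*arctan(beta1*(x_max - x_bar)) - 2*arctan(beta1*(x_min - x_bar))`
converted at 365/(2*pi) days per radian; days-per-decade divides by
span/10.  Reporting the posterior mean of the per-draw total (rather
than the total at the posterior-mean slope) propagates slope
uncertainty into the reported rate and its posterior SD.  Display
rounding is 3 significant figures for rates and 2 decimals for totals;
files keep full precision.  Exact-zero rates (impossible under a
continuous posterior) are excluded from direction counts and logged.

## Dataset construction

Four rules, combined into six standard rows (`STANDARD_DATASETS`):
a cap on the number of distinct flowering months (pooled over all
years, optionally required to form one contiguous circular block —
December and January are adjacent), a minimum specimen count, a minimum
span of collection years OR a calendar window (records at/after 1960,
or before 1960), and an optional cap of specimens per collection day
(ties broken by lexicographically smallest occurrence id, for
determinism).  When a window applies, month counts, specimen counts and
spans are recomputed on the windowed records.  Filtering is monotone
(tightening a threshold never admits a species) and idempotent; both
properties are tested.

## Phylogenetic signal

Blomberg's K compares the observed trait variance about the GLS root
state with its phylogenetically corrected counterpart, normalized by
the Brownian-motion expectation; K = 1 matches Brownian motion on the
given tree.  The covariance matrix V holds shared root-to-MRCA path
lengths.  Significance is a one-sided permutation test (high K =
signal) shuffling trait values across tips, with the add-one
correction p = (1 + #{K_perm >= K_obs})/(1 + B), so the smallest
attainable p is 1/(B + 1).

Trees lacking usable branch lengths get Grafen lengths (node height
proportional to descendant-clade size minus one, root at 1, tips at 0;
no power transform).  Near-zero branches are raised to a small constant
(default 1e-6 of the maximum root-to-tip height) so V stays
invertible.  Unrooted input trees with branch lengths are
midpoint-rooted; if the midpoint falls degenerately on a leaf
attachment (dendropy then demotes the leaf), the as-parsed rooting is
kept and logged.  The implementation is cross-checked in the tests
against independently computed references from the R packages ape
(`compute.brlen`, Grafen) and picante (`Kcalc`), frozen as constants.

## Synthetic records

The generator emulates the statistical structure the analysis assumes,
with known truth: per-species flowering dates are Von Mises draws about
a mean day that drifts linearly (days/decade) from a reference at the
midpoint of the species' collection window; yearly record counts are
Poisson with an effort-weighted rate, including an optional multiplier
window emulating the depressed collecting of the two world-war decades
(the size of that historical dip is not quantified anywhere we know of,
so the multiplier is user-set, default scenarios use 0.25-0.5); dates
wrap across Dec 31 and are realized as valid Gregorian dates.  Each
species draws from its own RNG stream derived by stable hashing of its
label, so adding a species never perturbs the records of another.

Default study conditions used by the simulation-based checks: kappa =
15 (flowering-date SD of roughly two weeks), 150-300 specimens per
species over a 61-year window, drifts within +/-6 days per decade —
sizes chosen to match what well-collected tropical taxa actually
provide.  Brownian-motion traits for the signal stage are multivariate
normal draws with covariance sigma2 * V.

What the generator does *not* emulate: collector seasonal preference,
spatial structure, taxonomic misidentification, digitization date
errors, or multi-peak flowering.  Passing the recovery and calibration
suites therefore demonstrates that the estimator chain is correct under
its own model, not that real GBIF data satisfy that model.

## Numerical choices and degenerate inputs

- log I0(kappa) is computed via the exponentially scaled Bessel
  function, stable for kappa in the thousands.
- kappa initialization uses the Best-Fisher resultant-length
  approximation with the small-sample correction.
- Fits require >= 3 observations spanning >= 2 distinct years; a
  single-year series raises "no temporal contrast".
- A constant trait vector makes every permutation identical: p = 1
  with a warning rather than an error.
- A singular V raises an error pointing at the branch-repair step.

## Problem sizes in the validation suites

The grid-oracle comparison uses a 10-observation series with 50,000
retained draws against a 140 x 400 x 160 grid; recovery uses 50
species and null calibration 100 species at the default MCMC settings;
K calibration uses 200 Brownian simulations and 200 null permutation
replicates (199 permutations each) on a fixed 33-tip tree.  These sizes
put Monte-Carlo noise well inside each acceptance band while keeping
the full validation run in the tens of seconds on one core.

## Known limitations

- The days-per-decade conversion assumes the fitted drift is monotone
  over the span (the link guarantees it per draw); oscillatory
  phenology is outside the model.
- Slope summaries are link-scale per centered year and only
  approximately radians/year x 1/2 for small slopes; published tables
  from other pipelines may use different slope units, so compare rates
  in days per decade, not raw slopes.
- Blomberg's K is computed for a fixed tree; phylogenetic uncertainty
  is not propagated.
- The month-cap rule pools months across all years; a species with a
  stable 2-month season that shifted by several months over a century
  can legitimately occupy >4 pooled months and be excluded — a
  conservative bias inherent to the rule, not to this implementation.
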