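# phenoshift

Estimation of long-term shifts in flowering dates from herbarium
specimen records, using Bayesian circular regression, with
rule-based dataset construction and a phylogenetic-signal test on the
resulting shift magnitudes.

## The problem

Dated, flowering herbarium specimens are the only systematic record of
flowering phenology reaching back past the instrumental era, and for
most tropical floras they are the *only* record.  Two features make
them statistically awkward.  First, flowering dates live on a circle:
many species' flowering seasons span the new year, so an ordinary
regression of day-of-year on collection year is meaningless for them.
Second, collection effort is uneven across decades, and digitized
occurrence tables (Darwin Core format, as served by aggregators such as
GBIF) mix preserved specimens with field observations and carry
malformed dates.

`phenoshift` is for researchers analysing such occurrence tables: it
parses and filters the records, fits a per-species circular regression
of flowering date on year, converts the fitted slopes into days-per-
decade shifts, aggregates them, and tests whether shift magnitudes are
phylogenetically conserved.  A synthetic-record generator with known
ground truth makes every stage testable offline.

## The model

For each species, with collection-date angles
θ\_i = 2π·d\_i/365 − π (d\_i the leap-rescaled day-of-year) and years
x\_i:

    θ_i ~ VonMises(μ_i, κ),   μ_i = β₀ + 2·arctan(β₁·(x_i − x̄))

The tan-half link keeps the mean direction within one turn of the
intercept, so the total shift over the observed span — the link-scale
difference between the first and last collection year, in days at
365/2π per radian — is well defined; dividing by span/10 gives
ΔDOY/decade, the headline rate.  Posteriors are sampled by MCMC (Gibbs
for β₀, Metropolis–Hastings for β₁ and log κ; 4 chains, burn-in 200,
2500 retained iterations by default) and validated against a
brute-force grid posterior.  Priors and their rationale are in
[docs/methods.md](docs/methods.md).

Phylogenetic signal in |ΔDOY/decade| is quantified with Blomberg's K
(K = 1 matches Brownian motion on the tree) and a one-sided permutation
test; trees without usable branch lengths get Grafen lengths.

## Worked example

Simulate three species with known drifts (+2.5, −1.2 and +0.3
days/decade), then run the full pipeline:

```yaml
# sim.yaml
seed: 11
species:
  - {species_id: "Tabebuia demo", mean_doy_at_ref: 245, drift_days_per_decade: 2.5,
     kappa: 20, records_per_year_rate: 2.2, year_range: [1920, 2010],
     effort_dip: [1914, 1945, 0.4]}
  - {species_id: "Miconia demo",  mean_doy_at_ref: 350, drift_days_per_decade: -1.2,
     kappa: 12, records_per_year_rate: 2.0, year_range: [1930, 2010]}
  - {species_id: "Inga demo",     mean_doy_at_ref: 120, drift_days_per_decade: 0.3,
     kappa: 25, records_per_year_rate: 2.0, year_range: [1925, 2005]}

# run.yaml
simulation: sim.yaml
criteria: {max_months_flowering: 6, min_specimens: 20, min_year_span: 29,
           require_consecutive_months: false}
mcmc: {iterations: 2500, burnin: 200}
seed: 11
output_dir: out
```

```
$ phenoshift run run.yaml
```

`out/estimates.csv` then holds, per species:

```
      species  days_per_decade  days_per_decade_sd  total_shift_days  span_years  n_specimens direction
Tabebuia demo            2.325               0.465            20.692          89          190     later
 Miconia demo           -1.525               0.567           -12.051          79          152   earlier
    Inga demo            0.791               0.356             6.331          80          162     later
```

Each row is the posterior mean rate of change of the mean flowering
date (positive = flowering later in the year), its posterior SD, the
implied total shift over the species' collection span, and the sample
size.  All three true drifts are recovered well within two posterior
SDs, including the "Miconia" species whose flowering season (mean day
350) spans the new year — the case an ordinary linear regression
mishandles.  `out/summary.csv` aggregates the cohort (mean |rate|
1.55 days/decade here, 2 species shifting later vs 1 earlier), and with
a `tree:` entry in the config a `signal.json` with Blomberg's K and its
permutation p-value is written too.

The same stages are available piecemeal (`phenoshift simulate`,
`filter`, `fit`, `summarize`, `signal`) and as library functions.
Darwin Core-style occurrence files are accepted directly via
`occurrences:` in place of `simulation:`; six standard
inclusion-criteria presets (`dataset1` … `dataset6`: caps on flowering
months, specimen minimums, span or era windows, per-day deduplication)
are built in.

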