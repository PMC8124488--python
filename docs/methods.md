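# Methods

## Model

The outcome is the area-level count of respiratory hospitalizations over
a multi-year window, modeled as Poisson with a log link. The linear
predictor contains the log person-period population as an offset
(coefficient fixed at 1, so the model describes hospitalization *rates*),
a flat-prior intercept, six fixed effects for the pollution-source
covariates, and an intrinsic conditional autoregressive (ICAR) spatial
random effect.

Priors follow the BUGS-style conventions of the original analysis:
`(0, 0.1)` for the coefficients is read as mean 0, *precision* 0.1
(variance 10) — `ModelSpec(beta_prior_is_variance=True)` switches the
reading — and `Gamma(0.01, 0.01)` for the ICAR precision `tau` is
shape–rate. The ICAR prior with unit weights is the improper Gaussian
Markov random field with density

    p(s | tau)  ∝  tau^((N-c)/2) · exp( -tau/2 · Σ_{i~j} (s_i - s_j)² )

where `c` is the number of connected components of the neighborhood
graph (the standard rank correction; the study's graph is connected, so
c = 1). The field is defined only up to a level; identification against
the flat intercept uses an explicit sum-to-zero constraint, maintained by
re-centering after every field update with the subtracted mean absorbed
into the intercept. Constant terms of the ICAR density and the Gamma
kernel are omitted consistently (they cancel in every Metropolis ratio);
the Normal coefficient kernels keep their normalizing constants.

Covariates enter exactly as encoded upstream — 0/1 presence flags
(airport, construction, seaport), the raw percentage of area covered by
industrial districts, and ordinal 1–5 quintile scores (traffic, tunnels)
— with no standardization, so exponentiated coefficients are rate ratios
on those scales.

## Sampler

Metropolis-within-Gibbs, one iteration being:

1. componentwise Gaussian random-walk Metropolis on the seven
   coefficients;
2. one joint Gaussian random-walk Metropolis step on all coefficients,
   with proposal covariance `(2.38²/7)·Σ̂` where `Σ̂` is the running
   empirical posterior covariance (classic adaptive Metropolis);
3. a blocked single-site random-walk sweep over the spatial field: areas
   are grouped by a greedy graph coloring, and all areas of one color are
   updated simultaneously — valid because non-adjacent areas have
   conditionally independent full conditionals (site-local Poisson terms
   plus ICAR neighbor terms) — followed by the re-centering step;
4. an exact conjugate Gibbs draw
   `tau ~ Gamma(a + (N-c)/2, b + SS/2)` with `SS` the pairwise quadratic
   form.

Internally the design matrix is centered and the intercept
reparameterized as `b1' = b1 + mean(X)·b[2:]`; this is an exact,
Jacobian-1 change of variables under the flat intercept prior that
decorrelates the intercept from the covariate effects, and draws are
transformed back before storage.

Proposal scales (componentwise, field, and the joint multiplier) adapt
toward an acceptance rate of 0.2–0.5 during burn-in only and are frozen
afterwards, preserving the stationary law. Each chain owns an RNG stream
seeded `base_seed + chain_index`; every run is bit-reproducible. The
original analysis used OpenBUGS's over-relaxation option; that is not
reimplemented here — it affects only autocorrelation, not the stationary
distribution, and the adaptive joint update serves the same purpose.

Run protocol defaults mirror the study: five chains, thinning 10, and
per-stratum burn-ins of 15,000 (total), 22,000 (males), 11,000
(females), and 28,000 / 5,000 / 14,000 for the 0–4, 15–59 and ≥60
age groups (`CONVERGENCE_BURNIN`), with 10,000 kept draws per chain when
a run configuration does not say otherwise. The number of
post-convergence draws the original summaries used is not recoverable;
10,000 per chain is this package's choice. Tests and the acceptance
script use smaller, explicitly stated protocols sized to their graphs
(e.g. 5 chains × 4,000 iterations on a 10×10 lattice, where the counts
are large and mixing fast; 80,000 iterations with 60,000 burn-in on the
10-area fixture, where it is not — see "Fixture collinearity" below).

## Diagnostics and reporting

The Brooks–Gelman–Rubin plot statistic is computed on increasing
prefixes of the kept draws: the width of the central 80% interval of the
pooled chains ("green"), the mean central-interval width within chains
("blue"), and their ratio ("red"), which converges to 1 at stationarity;
0.80 is the conventional plot mass and is configurable. The scalar
companion is the classical potential scale reduction factor
`sqrt(((n-1)/n·W + B/n)/W)`; summaries warn above 1.1 (common practice —
the original criteria were visual).

The summary table reports, per covariate, `exp(mean of the posterior
draws)`, the SD of the exponentiated draws, and the exponentiated
2.5/97.5 percentiles. Two readings of the published "Mean/SD" columns are
possible (moments of `exp(b)` draws vs `exp` of moments); the one
documented here is `exp(mean)`, matching the stated "exponential of the
mean of the posterior beta", and the SD of the exponentiated draws keeps
all four columns on the same scale. An interval excluding 1 flags a
credible association.

## Preprocessing rules

* **Closure correction.** When a facility closure suppresses an area's
  counts, each closure year receives `mean(previous years) ×
  months_closed/12` added to its observed count. The averaging window
  starts two years before the first closure year and grows with the
  cascade (capped at four years), and later closure years average over
  *already corrected* earlier years — forced by the published 2010/2011/
  2012 correction formulas. Whether the 2010 correction should count 2 or
  3 closed months is ambiguous in the source; the operation takes months
  as input and does not adjudicate. Corrected counts stay real-valued;
  rounding (half to even) happens only where a corrected year feeds the
  Poisson outcome.
* **Population.** Non-census years get `census share of each area ×
  city total of the year`, conserving city totals exactly; missing
  age-specific years are imputed recursively as the mean of the three
  preceding years.
* **Ratios.** Crude hospitalization ratio = window count sum / window
  population sum × 1000, pooled over the window (hence invariant to how
  the window is split); the annual series is the same computation
  year-wise.
* **Traffic scoring.** Per-road density is the arithmetic mean over
  monitoring points; roads with data are ranked into quartiles and
  weighted 1–4 (no data → weight 0); per-area weight sums are stratified
  into quintiles giving scores 1–5. "Weighted quartiles" is not defined
  in the source beyond these steps; the rank-based reading (ties share
  the lower category) is an interpretation, and the published per-area
  bins are irregular, so the fixture stores the printed categories
  directly instead of recomputing them.
* **Tunnel scoring.** Entrance/exit counts per area are stratified into
  quintiles; the fixture uses the published bins {0}, 1–5, 6–15, 16–30,
  >30 mapped to scores 1–5.

Strata (total, each sex, three age bands) are analyzed marginally and
independently, as six separate models; no sum-consistency across strata
is enforced (the age bands omit 5–14-year-olds, so strata cannot sum to
the total).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
ICAR fields drawn exactly by spectral decomposition of the graph
Laplacian (independent Normal coordinates with variance `1/(tau·λ_k)` on
the non-null eigenvectors — O(N³), fine at areal scale), Poisson counts
under the offset log-linear predictor with the offset spread evenly
across the window years, rook-lattice graphs as test-scale stand-ins for
real contiguity, and the two data pathologies the preprocessing stage
must face: an epidemic-year count spike (default factor 2.0) and a
facility-closure gap reducing an area's counts proportionally to months
closed.

Default generator conditions: effect sizes on the rate-ratio scale of
1.31 (airport), 1.03 (industry), 1.07 (traffic), 2.76 (construction),
1.28 (seaport), 0.76 (tunnels) — the magnitudes the total-population
analysis reports — a baseline rate of 2 hospitalizations per 1000
person-periods (the middle of the published per-area crude ratios), a
spatial SD scale of 0.5, and area populations log-uniform between 10⁴
and 10⁶ depending on scale.

What the generator does *not* emulate: overdispersion beyond Poisson,
temporal structure within the window (covariates are static, as in the
source data), reporting/coding errors, and real geographic contiguity —
the packaged 10-PA adjacency is a declared ring-with-chords convention
approximating the city map, because deriving true contiguity from
shapefiles is out of scope. Passing tests therefore demonstrate
correctness of the machinery under the stated model, not robustness to
real-data violations of it.

## Fixture collinearity

In the published covariate table the airport and seaport columns are
*identical* (both present in PA1, PA2.1, PA3.1 only). The likelihood
then identifies only the sum of the two coefficients; their difference
is constrained solely by the Normal(0, variance 10) priors, producing a
long flat valley in the posterior. Componentwise random-walk mixing
along this valley is extremely slow — this is why the fixture-scale runs
use long burn-ins and why the package adds the adaptive joint coefficient
update. Exponentiated intervals for airport and seaport on fixture-like
designs are accordingly enormous; narrow intervals for these two
variables on such a design would indicate under-explored chains rather
than information.

## Numerical choices and edge cases

* Quantile binning is rank-based with ties sharing the lower category;
  configurable via explicit bin edges.
* Zero-sum tolerance on the field is 1e-8 (1e-10 at generation);
  degenerate BGR (both widths 0) reports ratio 1 by convention.
* Chains must number ≥ 2 (the diagnostics require it); thinning ≥ 1;
  burn-in < iterations. `fixed_tau` pins the precision for oracle
  studies.
* A non-finite log-posterior at initialization aborts the run with a
  diagnostic; non-finite proposals are rejected.
* GAL files carry binary contiguity only; general weights round-trip
  through the neighbor-list CSV. Area identifiers are strings in every
  interchange file; 0-based indices are internal only.
* All CSV output uses a fixed float format and provenance comment
  headers (input hashes, seeds, version — never timestamps), so
  re-running with unchanged inputs is byte-identical.

## Known limitations

Single-CPU desk-scale sampler: a few hundred areas at most. No
alternative spatial priors (proper CAR, BYM2), no model comparison
(DIC/WAIC), no effective-sample-size stopping rules, no shapefile
ingestion or choropleth mapping. The published posterior summary tables derive
from microdata not printed in the source and are therefore not
reproduction targets; the pipeline's correctness is established against
oracles and simulation instead.
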