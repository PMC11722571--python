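# Methods

This note records the statistical models the package implements, the
choices made where the published analysis description left the design
open, and what the synthetic stand generator does and does not emulate.

## Data model

The unit of observation is a tree ≥ 10 cm dbh inside a 20 × 20 m plot
nested in a forest patch labelled `successional` or `mature`. Liana
records are individual stems (diameter ≥ 1 cm at 130 cm from the
rooting point, species, climbing mechanism `specialized`/`leaning`,
zone `trunk`/`crown`); each record is treated as one stem — the census
convention for multi-stem or re-rooting climbers is not standardized,
so no merging is attempted. Epiphyte records are species × tree
occurrences with a Braun-Blanquet cover class (1 = 1–5%, 2 = 6–25%,
3 = 26–50%, 4 = 51–75%, 5 = 76–100%) and a non-empty zone set. A
"host" is a tree with ≥ 1 record of a guild, regardless of zone.
Liana abundance is measured as basal area, `π(d/200)²` m² for a
diameter in cm.

Size classes use the survey's quartile breakpoints (13.15, 19.75,
33.76 cm). The printed class bounds are open intervals that leave
exact ties undefined; the package uses half-open classes
`[b_{i-1}, b_i)` so the partition is total. Ties at 2-decimal dbh
precision are measure-zero, and the choice does not alter any printed
count.

## Occurrence statistics

Per size class, liana × epiphyte presence forms a 2×2 table tested
with the chi-square for independence, 1 df, with the Yates continuity
correction clamped at zero: `Σ max(|O−E|−0.5, 0)²/E`. The correction
is not optional decoration: the uncorrected statistic on the first
published class row is 0.62 whereas the printed value is 0.44, which
only the corrected form reproduces (all four rows agree to the printed
precision). Clamping makes a perfectly proportional table score
exactly 0.

Shared-host percentages divide by the union of hosts,
`100·shared/(liana_hosts + epi_hosts − shared)`; this is the only
denominator consistent with every printed class- and patch-level
percentage (27/226 = 11.9%, 215/478 = 45.0%).

## Negative-binomial contrasts

All three group comparisons (patch-level liana vs epiphyte host
counts over the patch's plots; trunk vs crown occurrence counts;
epiphyte occurrences on hosts of specialized vs leaning liana species)
use the same two-group NB2 GLM with log link, dispersion by maximum
likelihood (statsmodels), Wald z, two-sided unadjusted p. Because the
design is a single factor, the ML coefficient equals
`log(mean_alt/mean_ref)` exactly for any dispersion; this is used both
as an internal cross-check (agreement to ≥ 6 decimals is asserted) and
to reproduce published estimates from printed totals. When counts are
under-dispersed the ML dispersion collapses to the boundary; the fit
then reduces to the Poisson GLM and is reported with `theta = inf`.
Counting units are per-plot counts (10 per group in the emulated
design); the estimate is invariant to this choice, z and p are not.

The published per-patch table contains rows whose printed estimates
disagree with the closed-form log mean ratio of their own printed host
counts (e.g. one patch prints 0.01 where the totals give 0.03, and one
z/p pair is internally inconsistent); those rows cannot be reproduced
by any standard NB fit and are reported as computed, not matched.

## Host models

Four models relate per-tree responses to forest type and dbh with a
tree-species random intercept:

| response              | family            |
|-----------------------|-------------------|
| liana richness        | hurdle-Poisson    |
| epiphyte richness     | hurdle-Poisson    |
| liana basal area      | hurdle-lognormal  |
| epiphyte cover class  | cumulative logit  |

Hurdle likelihood: `Pr(y=0) = 1 − p` with
`p = logistic(h0 + h1·mature + h2·dbh_z)`; positive outcomes follow a
zero-truncated Poisson (rate renormalized by `1 − e^{−λ}`) or a
lognormal, with linear predictor `b0 + b1·mature + b2·dbh_z +
u[species]`, `u ~ N(0, σ_sp²)`. The hurdle sub-model takes the same
covariates as the positive part (the simplest reading of "forest type
and tree size as explanatory variables") but no species effect, which
keeps the two likelihood factors cleanly separable. The cumulative
model is a proportional-odds logit on the 1–5 classes of colonized
trees only — the cover scale is undefined for a bare tree — with four
ordered cutpoints absorbing the intercept. Cover per tree is the
maximum recorded class over that tree's epiphyte records.

dbh is z-scored on the fitted sample; coefficients are also reported
per cm (`dbh_per_cm = b2/sd(dbh)`), which is the scale used for
parameter-recovery checks so that results do not depend on any one
sample's standardization.

Priors are weakly informative: normal(0, 2.5) on coefficients
(standardized scale), half-normal(1) on σ_sp and the lognormal scale,
normal(0, 5) on the first cutpoint with lognormal(0, 1) gaps. The
original appendix priors were not available; these defaults are
exposed in the code.

Sampling uses an affine-invariant ensemble sampler (emcee) with
differential-evolution moves, initialized at the posterior mode
(L-BFGS on the log posterior) and a non-centered species effect
(`u = σ_sp·ũ`), which keeps the posterior bounded as σ_sp → 0. Each
walker is diagnosed as a chain; convergence is declared iff every
split-Rhat < 1.01 and every bulk ESS > 1000, and non-convergence is a
flag, not an error. The reference analysis protocol is 4 chains of
8000 iterations; the package's own tests use 2000 ensemble steps
(first half discarded), which is enough for stable 95% intervals on
~1000-tree stands while keeping a full recovery study (4 models × 10
stands) around five minutes.

## Interaction networks

Weights: liana × tree = summed basal area; epiphyte × tree = summed
zone occupancies (each record contributes |zones| ∈ {1, 2}; only two
zones are recorded, a finer zonation would slot in here); epiphyte ×
liana = number of trees hosting both species (only co-hosting trees
can contribute; an occurrence-product weighting is available as an
option since the published weighting is not stated). Conservation
invariants (matrix total = record-level total) are asserted in tests.
Rankings sort by marginal weight, ties alphabetical, for determinism.

## Spatial association

Tree positions are fixed; marks (hosting a liana, hosting an
epiphyte) are the random element — random labeling, not point-process
resimulation. The cross-type K uses the translation edge correction,
exact on rectangular windows and easy to mirror in a brute-force
oracle; with foci set 1 and targets set 2 the estimator is

    K̂₁₂(r) = |A|² / (n₁n₂ − n₁₂) · Σ 1(dᵢⱼ ≤ r) / ((W−|dx|)(H−|dy|))

where n₁₂ counts trees carrying both marks (they appear in both sets
but never pair with themselves; with identical mark sets the formula
reduces to the univariate n(n−1) normalization). Every curve is
reported ring-differenced, `K(r) − K(r − w)` with w = 2 m, which
removes the cumulative autocorrelation of K; under CSR the expected
ring value is `π(r² − (r−w)²)`. The default radius grid is 1-m steps
from 2 to 14 m (half the 60-m block side).

The null model reshuffles the target-guild marks with probabilities
fitted by logistic regression of presence on dbh and tree species;
weighted sampling **without** replacement preserves the observed
number of hosts (the random-labeling convention), with independent
Bernoulli draws as an option. If a species level perfectly predicts
the mark the model falls back to dbh-only with a warning. Envelopes
are pointwise alpha/2 and 1−alpha/2 quantiles over simulations
(default 10,000; calibration tests use 999); each guild is reshuffled
in its own analysis, matching the two-panel presentation of the field
study. Pointwise envelopes at ~13 radii imply a multiple-testing
excursion rate near alpha under the null — excursions at isolated
radii are expected noise, not signal.

## Synthetic stand generator

The generator emulates the survey design: 12 patches (8 successional,
4 mature) × 10 plots of 20 × 20 m; per-plot tree counts Poisson (18 /
17.8 expected trees for successional/mature, giving ~2100 trees); dbh
from a lognormal truncated to [10, 90] cm (meanlog/sdlog 2.75/0.45
successional, 3.00/0.55 mature — overall quartiles land near the
13.15/19.75/33.76 breakpoints); a tree-species pool of 11 taxa with
forest-type-specific abundances and fixed per-species effects; and one
patch carrying a contiguous 3 × 3 mapped block at ~120 trees/0.36 ha
(uniform or Thomas-cluster positions). The 90-cm upper bound mirrors
the largest stems such a census records and keeps richness inside the
species pool (see below).

Colonization is Bernoulli-logistic in standardized dbh
(`(dbh − 21)/11` with fixed reference constants), a mature offset and
the species effect; intercepts (−0.90 liana, 0.05 epiphyte) are
calibrated once so a default stand hosts ~34% liana and ~52% epiphyte
trees, the documented survey rates. Conditional on colonization the
generator draws exactly from the families fitted downstream —
zero-truncated Poisson richness, lognormal total basal area (split
over stems via a Dirichlet so stem diameters stay ≥ 1 cm), and a
latent-logistic cover class cut at the model's cutpoints — so
parameter recovery is well posed. Richness cannot exceed the species
pool (8 liana, 12 epiphyte taxa); the richness dbh slopes (0.25, 0.30
per reference-sd) are set so the truncated-Poisson rate stays well
below the pool size over the entire dbh range, keeping the cap
inactive in practice (it binds for roughly one tree per several
stands). Specialized-mechanism liana species receive a dbh bonus in
species selection, reproducing the pattern that epiphytes co-occur
with specialized climbers on large trees; epiphyte zone occupancy is
crown-biased (0.8 crown vs 0.4 trunk inclusion).

What the generator does **not** emulate: real species lists and
abundances, within-patch habitat heterogeneity, spatial correlation of
marks beyond dbh/species (the default marks are conditionally
independent given covariates), observation error of ground-based
cover estimates, or any liana–epiphyte interaction. Passing tests
therefore demonstrate that the estimators recover known structure and
stay calibrated under the null — not that the ecological conclusions
of any particular field dataset are correct.

## Numerical and degenerate-input conventions

Chi-square tables with a zero margin raise a degenerate-table error;
empty size classes yield zero tables, not errors. An all-zero count
group is reported as separation (the log-ratio is infinite). Shared
percentages with an empty host union are not-applicable (`None`/NaN).
Hurdle log-likelihoods clip the Poisson rate to `e^{±30}` to avoid
`log(0)` in the truncation term; the truncated-Poisson normalization
was verified against direct summation to 1e−10. Envelope and
generator randomness flows through `numpy.random.default_rng(seed)`
end to end; identical seeds give bit-identical outputs, including the
sampler (seeded ensemble initial state).

## Problem sizes used in the test suite

Desk-scale table checks run on the printed counts directly. Recovery
studies use ~1000-tree stands (8 patches × 8 plots), 10 seeds, 2000
ensemble steps; envelope calibration uses a ~120-tree mapped block
with 999 reshuffles × 20 replicates; CSR calibration uses 200
simulated 50-point patterns; conservation checks use 100 small
stands. These sizes give comfortable statistical margins (binomial
tolerance for the 5% exceedance rate, ≥ 8/10 interval coverage) while
keeping the whole suite a few minutes long.
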