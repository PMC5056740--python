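# Methods

## Scope and data model

The package operates on per-environment bundles of four sowing date × year
× variety arrays: irrigated grain yield `p`, rainfed grain yield `a`, and
the mean daily drought stress index over the vegetative (`div`) and
reproductive (`dir`) growth stages, each in [0, 1] with 1 meaning no
stress. These are the variables a drought-capable rice growth model writes
per run; the package never simulates crop physiology itself. Invariants
enforced on every bundle: 0 ≤ a ≤ p elementwise, indices in [0, 1], p ≥ 0.

The default experimental design is 24 sowing dates per year at 15-day
intervals from 1 January, 14 years, two water regimes (continuously
flooded vs rainfed), transplanting at 14 days after sowing — 672 runs per
variety per environment.

## Synthetic GEI generator

No run archive ships with the package, so `ricetpe.synthetic` emulates the
output structure with known ground truth. Choices, in order of consequence:

* **Water balance.** Seasonal rainfall is a cosine peaked at
  `monsoon_peak_doy` with peak rate `rain_amplitude` (mm/day); a lognormal
  multiplier with mean 1 and cv `rain_interannual_cv` (default 0.08)
  carries year-to-year variability. A stage's drought index is
  `clip(stage supply / stage demand, 0, 1)`, where supply is the
  closed-form rainfall integral over the stage plus a soil buffer
  (`soil_whc`, mm, allocated to stages pro rata by length) and demand is
  `demand_mm_day` (default 6 mm/day) per stage day. The closed form keeps
  a 300-environment grid simulation under ten seconds.
* **Stage split.** Panicle initiation is fixed at 55% of the variety's
  duration after sowing; vegetative stage runs from transplanting to
  panicle initiation, reproductive from there to maturity. No published
  definition of the split was available to this design; a fixed,
  configurable fraction keeps both stages well-defined for 110–124-day
  varieties.
* **Stress response.** Rainfed yield is
  `a = p · div^εv · dir^εr`; the multiplicative power law guarantees
  a ≤ p, equality exactly at no stress, and independent vegetative and
  reproductive sensitivities per variety.
* **Unsuitable seasons.** Each environment may declare a day-of-year
  window (possibly wrapping the year end) in which sowing gives zero
  irrigated yield. The zero is triggered by the sowing date falling in the
  window, not by cycle overlap: the designed archetypes declare most of
  the year unsuitable, and an overlap rule would then zero every date.
* **Randomness.** One named stream per (environment, year), keyed by a CRC
  of the environment id and the master seed, so adding varieties or
  reordering the grid never changes weather draws; cv = 0 degenerates the
  multiplier to exactly 1.
* **Variety panel.** Eleven varieties mirroring a published GSR evaluation
  panel: maturities 110–124 days as reported, potential yields 7.5–9.5
  t/ha, and sensitivity exponents spread from (0.25, 0.30) for the most
  drought-tolerant line to (1.00, 1.10) for the drought-sensitive
  irrigated check. The spread is what makes f₇₅ a smooth, stable function
  of the environment's stress depth.

### Designed drought regimes

`archetype_environment(label)` builds an environment whose TPE class is
known by construction. Timing is set by the monsoon peak relative to a
30-day suitable sowing window (doys 140–170): a peak near doy 275–300
leaves the vegetative stage dry (timing 1), near doy 150–160 the
reproductive stage (timing 2), and near doy 205 both (timing 3). Severity
is set by target mean stage indices (av̄, ar̄): the rain amplitude and
soil buffer are solved in closed form from the two linear supply
equations at a reference crop geometry (sowing doy 158.5, duration 117
days). Targets are placed well away from the classification boundaries —
e.g. M-class targets give f₇₅ ≈ 0.36 against bounds at 0.25/0.50, and
mixed-timing targets give a realized ar̄/av̄ ≈ 0.95 against bounds at
0.9/1.0 after accounting for the ~+0.05 drift introduced by best-season
selection favouring the milder surviving date. Measured recovery on 300
environments is 97–100% across seeds; residual errors are M-class
environments whose 14-year f₇₅ realisation strays toward a severity
boundary.

What the generator does **not** emulate: real weather autocorrelation,
soil heterogeneity within a cell, nitrogen or biotic stress, phenology
responding to temperature, or the regional geography of any real rice
area. Passing tests therefore demonstrate that the analysis chain
recovers structure that is present in its inputs — not that any real
region has a particular TPE composition.

## Cleaning and best-season selection

A sowing-date row is removed from all four matrices when *any* irrigated
yield in that row is zero (zero rainfed yields are legitimate drought
outcomes and kept). RYᵢ is the mean rainfed yield over years × varieties;
CVᵢ divides the population (1/N) standard deviation by RYᵢ — population
normalisation is used in every moment computation in the package for
internal consistency. The best season is the smallest CV among the three
highest RY; RY ties when forming the top three, and CV ties when choosing
within it, resolve to the earlier sowing date so selection is
deterministic.

## TPE classification

f₇₅ counts (year, variety) pairs with rainfed:irrigated ratio strictly
below 0.75. Severity: S for f₇₅ ≥ 0.5, M for 0.25 ≤ f₇₅ < 0.5, L below;
both lower bounds inclusive. Timing rules are evaluated in order —
vegetative if av̄ < ar̄, else reproductive if ar̄ < 0.9·av̄, else mixed —
so a completely unstressed environment (av̄ = ar̄ = 1) falls through to
"L3"; the taxonomy has no separate no-drought class and none is invented.
All three thresholds are configurable but default to the published values.

The genotype-count sensitivity analysis subsamples varieties without
replacement (default 100 replicates, seeded), re-selects the best season
from the subset alone and reclassifies every environment; reported
dispersion is the standard deviation of class proportions across
replicates. Re-selecting the season per subset matters: with few genotypes
both the season choice and the class flip, which is exactly the
instability the analysis is meant to expose. The full-panel row is
computed once with zero dispersion by construction.

The suitability score for a focal variety (mean best-season rainfed yield
minus the best check's, per environment) is a screening heuristic defined
by this package, not a published metric.

## Stability indicators

All five are root-mean-square forms with population normalisation:
γ = mean(YA); δ = RMS(YP − YA)/mean(YP); λ = popsd(YA)/γ;
φ = popsd(column means)/γ; ψ = popsd(row means)/γ. The λ/φ/ψ triple then
satisfies λ ≥ max(φ, ψ) by the law of total variance, and λ is literally
the coefficient of variation of YA as its verbal definition demands. Each
indicator is one small function, so an alternative normalisation is a
one-line change. Scope restriction is by whole environment columns:
a TPE class, a pooled severity letter, a pooled timing digit, or ALL.

## Ranking

Indicator profiles are oriented (γ negated), z-scored per column
(population sd; zero-variance columns pass through), clustered with Ward
linkage on Euclidean distance and cut at five groups. Duplicate profiles
are collapsed before linkage so ties always share a rank and a degenerate
table collapses to rank 1. Clusters are ordered by mean standardised
desirability, ties broken toward higher mean γ. Ward linkage is the
conventional variance-minimising default where the method is otherwise
unspecified; linkage and group count are configurable. The overall "Sum"
column of the adaptability table is the rank over all environments.

Rank concordance is the Pearson correlation of two rank vectors (equal to
Spearman's ρ for permutations) and its square; on the bundled 11-variety
field-trial vs site-simulation orders it is R² = 0.86.

## Agreement statistics

RMSEn = RMS(Y − X)/mean(X)·100 (%); Meff = 1 − Σ(Y−X)²/Σ(|Y−X̄|+|X−X̄|)²,
a Willmott-style index that is 1 iff Y = X and 0 for the mean predictor.
The t-test is the unequal-variance (Welch) two-sample test, the standard
reading of a mean-comparison test that does not assume equal variances.
Regression is OLS of simulated on measured. Desired calibration
tolerances (5% storage-organ biomass, 10% green leaf and total AGB, 15%
LAI and dead leaf) ship as constants for report consumers. Degenerate
inputs (constant X, zero denominators) raise rather than return NaN.

## Problem sizes and numerical choices

Default analysis sizes: 90-environment demonstration grid, 300
environments for classifier-recovery measurement, 54 environments × 100
replicates for the genotype-count analysis, 200 random 2–7 × 2–8 matrices
for indicator-oracle checks, n = 1000 pairs for noise-scaling checks.
Floating-point: CSV output uses %.17g with round-trip parsing, so write →
read is exact; indicator agreement with the loop oracle is asserted at
1e-10; clip boundaries use closed-form integrals, not day-stepped sums.

## Known limitations

* The generator's drought index is an emulation; no claim is made that it
  matches any particular crop model's internal water-stress formulation.
* Severity and timing margins are tuned for the default 11-variety panel;
  radically different sensitivity spreads will shift realised f₇₅ and may
  demand re-derived archetype targets.
* Indicator scopes require at least one environment; single-environment
  scopes give φ = 0 by construction, which makes clustering on φ
  uninformative there.
* No AMMI/GGE or regression-based stability statistics; only the five
  indicators above.
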