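# Methods

## Model

`heritsim` models a selection-free, mutation-free clonal population of
collectives (cell groups). Each genotype is a clone with a fixed genetic
mean cell size *m* and a genetic mean cell number N̄; the default
population is founded by 10 genotypes with means spaced evenly on [1, 2]
(arbitrary size units). Every collective splits into two offspring each
generation; nothing dies and nothing is selected, so heritability is
measured in isolation from selection.

Phenotypes are perturbed by two non-genetic noise sources:

* **Developmental instability (σ).** A daughter cell's size is drawn from
  Normal(*m*, σ) — centred on the *genetic* mean, not on the parent cell's
  realized size, so developmental deviations are not themselves inherited.
* **Environmental heterogeneity (σ′).** Each collective independently
  draws a multiplicative modifier from Normal(1, σ′) applied to all of its
  cells. Modifiers are redrawn fresh every generation (no parent–offspring
  environmental autocorrelation), including for the founders, so
  generation 0 has the same noise structure as every later generation.
* **Cell-number variation (CV_N).** When enabled, each offspring
  collective's cell count is Normal(N̄, CV_N·N̄), rounded to the nearest
  integer and floored at 1. Cell number is a collective-only trait: its
  variation erodes collective-level heritability while leaving cell-level
  heritability untouched.

Defaults (σ, σ′, CV_N ∈ [0, 0.25]; N̄ = 32; 7 generations; 10 genotypes)
define the reference regime the sweep drivers explore; larger noise values
are accepted but logged as outside that regime.

### Numerical choices

* Size, modifier and count draws are resampled until > ε = 10⁻⁶
  (counts floored at 1 after rounding). In the reference regime
  (means ≥ 1, SD ≤ 0.25) truncation perturbs the distributions negligibly;
  it only matters for deliberately extreme settings.
* True σ = 0 / σ′ = 0 are accepted exactly (the draws collapse to their
  means). The sweep grids instead use a 10⁻⁴ floor because the regression
  estimator needs parental variance; a single-genotype, zero-noise
  population raises a degenerate-variance error, and degenerate sweep
  cells are recorded as missing values rather than dropped.
* RNG streams: each genotype lineage consumes its own `SeedSequence`
  child stream of the run's master seed, and each (sweep combination,
  replicate) derives its own 31-bit seed, so results are independent of
  execution order and bit-reproducible.

### Pedigree and pairing

Each parent cell divides once per collective split, contributing one
daughter to *each* offspring collective; both daughters form (parent,
daughter) regression pairs, giving exactly N cell-division events per
split at fixed N. With CV_N > 0 the offspring's cell slots are matched to
parent cells by cycling through a random permutation of the parent cells
(surplus slots reuse parents, deficits leave some unpaired); division
events then count the distinct parents used. Parent–offspring regressions
pool every recorded event of a run across all generations — the run is
statistically stationary across generations, and pooling maximizes pairs
per run.

## Heritability estimators

**Regression route.** Broad-sense heritability at a level is the OLS slope
of offspring on parent value at that level; the collective value is
produced by a chosen trait map. Slopes are reported unclipped (sampling
noise can push them outside [0, 1]); the headline quantity is the
*ratio* of collective to cell slope, which is scale-invariant.

**ANOVA route.** For balanced designs (*a* clones × *b* collectives × *c*
particles) the nested sums of squares partition total variation into
among-clone (SSA), among-collective-within-clone (SS(B/A)) and
within-collective (SS(C/B)) components; particle heritability is
SSA/SST and collective heritability SSα/(SSα + SS(β/α)) on the collective
values. When the collective trait is any affine function of the cell sum,
the ratio reduces to (SSA + SS(B/A) + SS(C/B))/(SSA + SS(B/A)) ≥ 1 —
the structural "heritability for free" result. Unbalanced tables are
rejected, not approximated: the closed formulas assume constant *b*, *c*,
and silently reweighting unbalanced data would change the estimand.

**SS-ratio vs variance-ratio error.** Heritability is properly a ratio of
variances; the SS ratio is its finite-design approximation. The
`ss_vs_variance_error` diagnostic compares the exact variance-ratio value,
(σ²_A + σ²_B + σ²_C)/(σ²_A + σ²_B + σ²_C/c), with the ratio of closed-form
*expected* sums of squares (E[SSA] = (a−1)(σ²_C + cσ²_B + bcσ²_A), etc.),
so the comparison is deterministic rather than Monte-Carlo. The error is a
degrees-of-freedom effect that vanishes monotonically as *a* and *b* grow;
for the documented reference configuration (σ²_A = 1, σ²_B = 0.1,
σ²_C = 0.1, c = 32) it is ≈ 0.8%, already below 1% at a = b = 10.

## Trait maps and phenotype semantics

The growth model produces a generic positive "cell size"; each map fixes
its own physical reading.

* `volume` reads it as a cell volume: collective volume is the plain sum,
  the canonical linear trait.
* `diameter`, `swim` and `survival` read it as a cell radius. The diameter
  trait treats each cell as a sphere of volume (4π/3)s³ and applies
  d = 2(3V/4π)^{1/3}; swim and survival use the within-collective mean
  radius r.

The radius reading for diameter is a deliberate design choice: it makes
the multiplicative environmental modifier act *linearly* on the diameter
trait (d ∝ modifier), which is what keeps collective diameter heritability
at or above cell-level heritability over the whole noise plane. Reading
sizes as volumes instead passes the modifier through a cube root and
pushes the expected ratio slightly below 1 (≈ 0.98) where environmental
noise dominates developmental noise — a regime the diameter surface is
documented not to enter.

Swim speed defaults to the simplified numeric form
V_up = (0.02/π)r⁻¹ − (400/3)r² for 32-cell undifferentiated colonies; a
general mode exposes the physical constants (per-cell thrust f, viscosity
η_w, density contrast Δρ_c, gravity, N). The two share the shape
c₁/r − c₂r²; no numerical identity between the default coefficients and a
particular constant set is asserted, and the radius scale implied by the
numeric form (zero crossing near r ≈ 0.036) is not reconciled with the
dimensionless genotype-mean scale — sweeps report *relative*
heritabilities, which are scale-invariant, so no unit conversion is
attempted. Survival is used directly as a trait value in (0, 1), not as a
mortality filter: what is measured is the heritability of the survival
phenotype, not a selection response.

## Sweep drivers

* σ × σ′ sweep: 32-cell collectives, CV_N = 0, 7 generations; default grid
  32 × 32 points on [10⁻⁴, 0.25] with 10 replicates per combination.
* Size series: collective sizes {2, 4, …, 256} (powers of two, spanning
  the qualitative range; configurable) at five noise levels
  {10⁻⁴, 0.0625, 0.125, 0.1875, 0.25}, nine generations.
* σ × CV_N sweep: volume trait, N̄ = 32, 7 generations, σ′ held at 0
  (configurable) — cell-number variation is studied in isolation from
  environmental effects.

Aggregates are per-combination means over replicates. Tests exercise
reduced 8 × 8 grids with 5 replicates; the full 32 × 32 × 10-replicate
surfaces are a single-machine batch job via the CLI.

## What the generator does and does not emulate

The synthetic populations realize exactly the assumptions of the analytic
result: clonality, no mutation or within-collective genetic heterogeneity,
no selection, independent environments, and (optionally) fixed cell
number. Passing tests therefore show the estimators and the simulator are
mutually consistent under those assumptions; they do not show that real
nascent multicellular populations — with selection, environmental
autocorrelation, cell–cell interaction, or non-normal noise — would
display the same heritability ratios. The model is a tool for reasoning
about the *structure* of multilevel heritability, not a fitted description
of any organism.

## Known limitations

* Only balanced designs for the ANOVA route; REML/unbalanced estimation is
  out of scope.
* Broad-sense heritability only (asexual reproduction); narrow-sense
  machinery (additive variance under sex) is not implemented.
* The regression and ANOVA routes agree in expectation but are not
  numerically identical on one finite run; cross-route comparisons are
  statistical, not exact.
* Cell counts are i.i.d. around N̄ given the genotype; there is no
  heritable variation in cell number itself.
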