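# Methods notes

This note records the modelling conventions, numerical choices and known
limitations behind `fairdea`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Panel data model

The canonical input is a tidy long CSV, one row per (unit, year), with
resource indicators X1–X6 (health technical personnel, practicing
physicians, registered nurses, beds, total assets in 10⁴ yuan, total
health expenses in 10⁸ yuan), outputs Y1–Y3 (bed utilization %,
outpatient/emergency visits, discharges), resident population, and the
context covariates (GDP per capita, population density, urbanization rate
stored as a fraction in (0, 1]). Validation enforces strict positivity,
exactly three region labels (eastern/central/western), stable unit→region
assignment, and balance (every unit observed in every year, with the
missing pairs listed on failure). Units and years are sorted so that all
downstream matrix orderings are deterministic. Report tables are written
with half-up rounding, 3 decimals by default.

## Theil decomposition

The Theil-T form (resource shares against population shares) is used
because it decomposes additively over a two-level region/province
nesting: T = Tw + Tb with Tw the resource-share-weighted mean of
per-region indices. Natural logarithms; zero-amount terms take the
x ln x → 0 limit; a zero weight paired with a positive amount is a domain
error because the share ratio is undefined. Contribution rates are
Tw/T and Tb/T in percent, reported as NaN when T = 0 (a 0/0 with no
meaningful value). Population weights are whatever the panel's
`population` column holds — the package does not take a position on
year-end versus census population.

## DEA

* **Two-stage solve.** The classical non-Archimedean ε in the objective
  is numerically fragile; the package uses the standard equivalent:
  minimise radial θ, then fix θ* and maximise the slack sum. Slacks and
  peer weights are reported from the max-slack solution, which is the
  canonical choice under multiple optima (peer weights at a slack-optimal
  basis are still not unique in degenerate cases; only θ, and the
  efficient/inefficient classification, are invariants).
* **Scaling.** Radial efficiency is invariant to the measurement units of
  each dimension, so every input/output row is normalised by its
  reference-set mean before the LP — without this, yearbook-scale data
  (persons in 10⁵, assets in 10⁶) triggers simplex failures. Slacks are
  mapped back to original units.
* **Returns to scale** are read from the CCR max-slack λ-sum with
  tolerance 10⁻⁶: Σλ < 1 increasing, > 1 decreasing, else constant; units
  that are CRS-efficient are constant by definition and labelled "-" in
  reports.
* **Effectiveness threshold.** A unit is frontier-effective when
  θ ≥ 1 − 10⁻⁶ and its slack sum is ≤ 10⁻⁶ (relative, post-normalisation).
* **Default technology columns** are X1–X4 plus X6 (expenses) as inputs
  and Y1–Y3 as outputs. Total assets (X5) stays in the fairness block
  rather than the technology because expenses, not assets, are the flow
  input that produces the year's services; the choice is configurable
  (`AnalysisConfig.dea_inputs`).
* **Projections** follow the BCC (pure technical) solution: redundancy
  (1 − PTE)·x₀ + s⁻ per input, insufficiency s⁺ per output, both with
  rates against observed values; efficient units report exact zeros.

## Malmquist

Distances for the index, effch and techch are CRS; pech is the ratio of
same-period VRS distances; sech = effch/pech. This is the standard
catch-up/frontier-shift decomposition whose identities
tfpch = effch·techch = pech·sech·techch hold exactly by construction and
are asserted to 10⁻⁹. Cross-period CRS programs are always feasible for
positive data (values above 1 mean the unit lies outside the other
period's frontier); infeasible VRS cross-period programs are never needed
under this convention. Summary tables use geometric means, the natural
mean for multiplicative indices — it preserves the product identities,
which arithmetic means do not.

## Tobit second stage

Pooled right-censored Gaussian MLE with limit 1: DEA scores are ≤ 1 with
positive mass at 1, and strictly positive, so no lower limit is modelled.
Uncensored rows contribute the density term, censored rows the upper-tail
probability. The optimiser is BFGS on (β, log σ) with an analytic
gradient, started at OLS (β from least squares, σ from the residual RMS);
a second pass at tighter tolerance runs if the gradient is not below
10⁻⁶. Standard errors come from the inverse observed information
(numerical Hessian in the (β, σ) parametrisation), z and two-sided p
values from the normal reference, stars at 5%/1%. With no censored rows
the likelihood collapses to the Gaussian one and the fit equals OLS to
10⁻⁶ (tested). Pooling ignores panel dependence across years of the same
province; a random-effects panel Tobit is a known limitation, not
implemented.

Covariate construction: logs of GDP per capita, population density,
personnel (X1), beds (X4) and assets (X5); urbanization enters
untransformed on the fraction scale. The fairness covariates assign each
unit-year the *within-region* Theil index of its own region for that
indicator-year (`theil_covariate_rule="region"`), so provinces in the
same region-year share the same fairness triple; the national overall
index is available as an alternative rule. On a single-year panel the
three region-level fairness covariates plus the intercept span only the
three region dummies, so the design is structurally rank-deficient; the
pipeline therefore skips the regression stage (with an explicit warning)
when only one year is present.

## Synthetic panels

The generator emulates the study-shaped panel — 31 units split
11/8/12 across three regions, 6 years from 2014 — with every stage's
target planted:

* **Inequality**: per-capita resource levels are region multipliers ×
  lognormal unit dispersion (persistent component, sd 0.25 on the log
  scale, plus a yearly jitter at 30% of that) applied to fixed
  per-capita base rates. Defaults (multipliers 1.15/1.0/0.95) put
  roughly three quarters of measured inequality within regions, the
  structure provincial healthcare panels typically show. Setting the
  dispersion to zero forces Tw = 0 exactly; equal multipliers force
  T = 0.
* **Efficiency**: outputs are frontier(inputs) × exp(−u) with
  u ~ half-normal(σ_u = 0.15 by default), the standard one-sided
  inefficiency of stochastic frontier analysis. Two technologies:
  `linear_crs` (a ray technology — one shared dispersion vector keeps
  input bundles proportional, making the planted efficiency *exactly*
  the CCR score, the closed-form recovery oracle) and `cobb_douglas`
  (elasticity sum 0.95, mild decreasing returns, independent input
  mixes) for realism.
* **Determinants**: `generate_tobit_sample` draws censored-Gaussian
  responses from a known β and σ over a standard-normal design, with an
  optional intercept shift solved so the expected censoring fraction
  (average of normal upper-tail probabilities) hits a target.

All randomness flows through one explicitly seeded
`numpy.random.Generator`; identical seeds give byte-identical panels.

What the generator does **not** emulate: serial correlation of
inefficiency within a unit, measurement error, true magnitudes of the
Chinese provincial yearbook (scale realism is cosmetic), or efficiency
that depends causally on the covariates. Passing tests therefore show
that each estimator recovers the structure it assumes, not that the
assumptions hold in any particular real panel.

## Test-design choices worth knowing

* **DEA recovery under the curved technology.** With 31 units and a
  5-input/3-output technology, most units are vertices of the empirical
  hull and tie at efficiency 1 — the well-known small-sample
  dimensionality bias of DEA, not an implementation artefact. The
  Cobb-Douglas rank-recovery test therefore runs at 120 units with
  σ_u = 0.3 (spread above the estimator's resolution) and compares PTE
  to the planted efficiency, since under decreasing returns the planted
  frontier is the VRS one; Spearman ρ ≥ 0.8 holds across seeds there.
  The exact (closed-form) recovery check uses the ray technology, where
  no such bias exists.
* **Independent oracles.** The LP path is cross-checked against a
  brute-force basic-solution (vertex) enumeration implemented with
  `numpy.linalg` only, and against the 1-input/1-output ratio closed
  form — neither touches the HiGHS solver.
* **Problem sizes.** The default suite simulates study-shaped panels
  over short horizons (2–3 years) and validates the Tobit recovery over
  40 seeds at n = 2000 (100 seeds in the end-to-end battery); these
  sizes are where the checked properties are informative while keeping
  the suite quick.

## Benchmark tables

`src/fairdea/data/` ships three small CSVs transcribing published
provincial results (comprehensive efficiency 2014–2019; the 2019
TE/PTE/SE/RTS decomposition; the per-province Malmquist decomposition)
whose summary rows — means, frontier counts, decreasing-returns counts,
component products — are recomputable from their per-province bodies.
`verify_fixtures()` recomputes each such check. One known inconsistency
in the source tables: the 2015 efficiency column prints 14 values equal
to 1 but an "effective number" of 13 (the column is printed at 2 dp, so
a value just below 1 was likely rounded up); the frontier-count checks
therefore cover 2014 and 2019, where the printed counts are consistent,
and the mean checks cover all six years.
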