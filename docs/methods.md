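# Methods

This note documents the models implemented in `sagitta`, the choices made
where the underlying field methodology leaves the design open, and what the
synthetic-data generator does and does not emulate.

## Encounter kernels

The calm-water kernel treats predator and prey as points moving at constant
speeds `y` and `x` with isotropic, mutually independent headings; the
expected rate at which prey cross into the predator's perception sphere of
radius `R` at prey density `N` is `C = (πR²N/6)·[(x+y)³ − |x−y|³]/(xy)`.
The implementation evaluates the bracket through its exact expansion
`(3·hi² + lo²)/(3·hi)` with `hi = max(x,y)`, `lo = min(x,y)`: this is
algebraically identical, avoids catastrophic cancellation of the cubed
difference when one speed is much smaller than the other, and yields the
ambush limit `C = πR²Nx` at `lo = 0` without a branch. Both speeds zero is a
domain error (the kernel describes encounters by relative motion). All
inputs are SI (m, m/s, ind/m³); a single ×86 400 converts to the per-day
rates used in field tables.

Defaults describe a chaetognath ambushing copepods: `R = 3 mm` (attack
distance measured for a congeneric species by vibrating-probe experiments),
`x = 150 mm/s` (copepod escape-jump speed), `y = 0`.

The turbulent kernel substitutes `v → √(v² + w²)` for both speeds, `w`
being the rms small-scale turbulent velocity. For `y = 0` this reduces to
`C_RO = πR²N·(3x² + 4w²)/(3√(x² + w²))`, giving the enhancement ratio
`f(w) = C_RO/C_GS = (3x² + 4w²)/(3x√(x² + w²))` with `f(0) = 1`, strict
monotonicity, and asymptote `4w/(3x)`. The quadratic
`4q² − 3fq − 1 = 0` in `q = √(x²+w²)/x` inverts `f` in closed form
(`calibrate_surface_w`), with round-trip accuracy at the 1e-12 level.

**Why `w` is a parameter, not a wind formula.** Published wind-to-turbulence
scalings for the upper mixed layer give `w` of order `u* ≈ 0.0012·W`
(millimetres per second for winds of 2.6–3.9 m/s), far too small to produce
the 1.5–1.8× surface enhancements reported from field tables; those
enhancements imply `w ≈ 0.13–0.17 m/s`. Rather than guess an unstated
parameterization, the surface `w0` is a first-class configurable parameter,
calibrated when needed from an observed enhancement ratio, and the wind
speed is carried as provenance metadata only. This discrepancy is inherent
to the source analysis, not resolvable here.

**Depth decay.** Field profiles show the turbulent/calm disparity fading by
roughly 28 m at 2.6–2.8 m/s winds and 40 m at 3.9 m/s, but no functional
form is given. `TurbulenceSpec` therefore offers three shapes —
`exponential` (default, `w0·e^(−z/decay_depth)`), `linear_cutoff`, and
`constant` — with `decay_depth` free; choosing `decay_depth ≈ horizon/ln 10`
places the 10 %-of-surface level at the observed horizon (e.g. 12 m for a
28 m horizon). This is a modelling convenience, not an assertion about the
source computation.

## Feeding rates

`DT(T) = a·e^(−bT)` hours with defaults `a = 10.48`, `b = 0.086 °C⁻¹`,
strictly decreasing over the sanity window −2…40 °C. A published version of
this model prints the exponent as `0.86`; that value predicts ~1e−10 h
digestion at 26 °C, while `b = 0.086` reproduces all six published seasonal
digestion-time extremes to 2 decimals from their temperature extremes — it
is treated as an order-of-magnitude erratum, and the package default.

`FR = (NPC/DT)·24` is computed per station from that station's mean gut
count and 0–50 m integrated temperature; seasonal summaries are means of
per-station ratios (mean-of-ratios, matching how field tables are built),
never the ratio of seasonal means — the two differ because gut-content and
temperature extremes occur at different stations.

Layer means use trapezoidal quadrature over [first sample, 50 m] divided by
the span — standard for CTD profiles and exact for linear gradients; the
layer bottom is interpolated when it falls between samples, and profiles
shallower than 50 m are averaged over their available span with a logged
warning. `GutSurvey` stores per-individual counts (not just the mean) so
sampling variance is computable; prey found near the mouth are a data-entry
flag handled at table-reading time (possible cod-end feeding artifacts),
not re-adjudicated statistically.

## Electivity

`X = O/(1+O)` with `O` the gut/habitat odds ratio, computed in the
numerically stable form `X = g(1−a)/[g(1−a) + a(1−g)]`. Properties used as
tests: `X(g,a) + X(a,g) = 1`; strict monotonicity in each argument;
`X = 0.5` iff `g = a`. A taxon absent from the habitat aliquot has zero
availability odds and an undefined index (blank cell), as does a taxon
absent from guts — no continuity correction is applied.

Uncertainty: `g* ~ Beta(G+1, N_G−G+1)`, `a* ~ Beta(A+1, N_A−A+1)` (the
posterior under a uniform Bayes–Laplace prior, well-defined at zero counts),
10 000 draws, percentile 2.5/97.5 interval. This prior reproduces published
field intervals to ~0.01 at the relevant count magnitudes, which is as close
as an unstated-prior procedure can be pinned. Classification: `positive` if
the interval lies above 0.5, `negative` below, `none` otherwise. At field
sample sizes (N_G ≈ 10–25) power is low: strong selection (odds 4.5) is
usually not called at N_G = 9 but usually is at N_G = 200 — a caveat the
synthetic generator makes testable.

Printed composition tables give rounded percentages; `CompositionTable.
from_percentages` reconstructs integer counts from a known total and
accepts them only within ±0.05 percentage points, so analyses run on exact
counts.

## Permutation statistics

PERMANOVA uses the Gower-centred matrix `G = −½·J D² J`; for any symmetric
idempotent projection `P`, `SS = tr(PGP) = tr(GP)`. Sequential (Type I) sums
of squares come from differences of hat matrices of the nested designs
`1 ⊂ 1+A ⊂ 1+A+B ⊂ 1+A+B+A:B`; degrees of freedom from rank differences;
`pseudo-F = MS_term/MS_residual`. On balanced crossed designs with
univariate Euclidean distances this reproduces classical two-way ANOVA
exactly (the oracle used in tests). p-values use unrestricted permutation of
sample labels with the add-one convention `p = (1+#{F* ≥ F})/(B+1)`;
default `B = 9999`, seed-deterministic; unique permutations actually drawn
are reported. Permutation-of-residuals schemes and Type III SS (as used by
some commercial packages on unbalanced field designs) are out of scope, so
exact field ANOVA tables from unbalanced surveys are a qualitative, not
numeric, reference. Confounded designs (empty cells) raise an error naming
the empty cell.

BIOENV z-scores each environmental variable, searches all non-empty subsets
exhaustively (≤6 variables → 63 subsets), and maximizes the Spearman rank
correlation between subset Euclidean distances and response distances.
Variables collinear with the response by construction (prey density, when
the response derives from an encounter rate that is exactly linear in it)
are excluded by name; constant variables are dropped with a warning. The
global BEST permutation test (shuffle sample identities, re-run the search)
is available but off by default — it is B times the cost of the search.

The size regression is ordinary least squares of prey length on predator
length with a two-sided t-test on the slope.

## Synthetic data

The generator emulates: per-stratum truncated-normal temperatures (e.g.
winter neritic 18.7–22 °C), normal salinity, log-normal copepod and
chaetognath densities (strictly positive, right-skewed, parameterized by
arithmetic mean and CV; stratum means follow observed seasonal ordering,
summer > winter > fall on the shelf), seasonal winds (2.64/2.81/3.87 m/s),
CTD profiles built as linear gradient plus noise then shifted so the 0–50 m
trapezoidal mean equals the drawn station value to float precision,
Bernoulli gut counts (arrow worms rarely hold more than one prey; Poisson
mode for fuller guts), and multinomial diet pairs tilted in odds space
(`q ∝ s·a`), for which a single tilted taxon's realized gut/habitat odds
ratio equals its tilt exactly.

It does **not** emulate: spatial autocorrelation or fronts/plumes, net
avoidance or extrusion biases, turbidity effects on predation, taxon-
specific digestion visibility, or within-station prey patchiness. Passing
tests therefore demonstrate correctness of the estimators under the stated
sampling models, not robustness to those field complications.

Default problem sizes used by the test suite (chosen to make Monte-Carlo
error small relative to the tested tolerances while keeping the suite
fast): 500 replicates for the PERMANOVA null (B = 199 permutations each,
balanced 3×2×4 design), 100 replicates for BIOENV recovery (n = 30 stations,
1 signal + 5 decoy variables), 500 gut surveys of 200 predators for
feeding-rate recovery, and ~30 million segment checks (~3500 events) for the
individual-based encounter oracle, giving ~2 % Monte-Carlo error against a
5 % bound.

## Known limitations

- The wind → `w` link is deliberately unresolved (see above); calibrated
  `w0` values are consistency parameters, not independent predictions.
- Electivity intervals depend on an assumed (uniform) prior; published
  intervals are matched approximately, not bitwise.
- PERMANOVA implements sequential SS only; unbalanced-design Type III
  tables from other software will differ.
- The abstract-level aggregation of feeding rates in the source field study
  (a 0.44–0.74 range not derivable from its own tables) is not reproduced.
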