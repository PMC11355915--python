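# Methods

## Topological asymmetry of an image pair

An image is treated as a field `z(i, j)` on an N×M pixel lattice.  The
package uses the sublevel-set filtration — a pixel is included once the
threshold reaches its value, `z(i, j) ≤ l` — so the family of cubical
complexes is nested as `l` grows, dark structures (vessels, the optic disc
in fundus photographs) enter first, and the final complex is the full
rectangle.  Cells follow the vertex construction: each pixel is a vertex,
edges join 4-neighbours and carry the maximum of their endpoint values,
unit squares carry the maximum of their four corners.

Dimension-0 persistence is computed by a union-find sweep over edges in
filtration order with the elder rule (on a merge, the component with the
larger birth value dies; ties broken by vertex index for determinism).
Dimension-1 persistence is computed by boundary-matrix reduction over Z/2
of the square columns against the globally ordered edges; in a planar grid
every square kills exactly one loop, so the reduction pairs each square
with the edge that created the cycle it fills.  Both routes are checked in
the test suite against an independent brute-force oracle
(`oracle_betti`): flood-fill component counting plus the Euler
characteristic `b1 = b0 − (V − E + F)` on the included complex, evaluated
at every distinct pixel value.

Two conventions make the downstream lifetime sums well defined:

* **Essential class.**  The one component that never dies is assigned
  death equal to the maximum pixel value, giving it the finite lifetime
  `max(z) − min(z)`.  Any other policy (e.g. dropping it) changes APF₀ by
  a constant offset after its mean age; assigning the global maximum keeps
  the class comparable between two images on the same intensity scale.
* **Zero-lifetime pairs.**  Merges and fills that occur at the birth value
  (plateaus) contribute nothing to any lifetime sum and are dropped from
  the diagrams; a constant image therefore has exactly one dimension-0
  point and an empty dimension-1 diagram.

Diagrams are re-expressed as (mean age, lifetime) points and accumulated
into the APF step function.  The difference `D(m) = APF_R(m) − APF_L(m)`
between two APFs of the same dimension is piecewise constant, so its
supremum is attained on the union of the two breakpoint sets; no grid
approximation is involved.  The measure returns the *signed* value of `D`
at the location of the largest `|D|` (ties broken toward the smallest mean
age), which makes the measure antisymmetric in its arguments: swapping
left and right negates it.  The prose definition ("difference with the
maximum absolute value") and the formula (argmax of the raw difference)
are not identical; the absolute-argmax reading is used because it treats
left-dominant and right-dominant asymmetry symmetrically, which the signed
supremum-metric framing requires.

Both images pass through a common intensity transform first: `unit`
(min–max rescale to [0, 1], constant image to all-zero) or `z` (global
standardization, constant image to all-zero with a warning).  The same
transform is applied in both homology dimensions; `unit` is the default.
Which transform is "right" is a user choice — both are first-class and
every diagram and curve carries its transform tag, with mixing rejected.

## Synthetic data

The generator exists so that every stage of the pipeline can run, and be
tested, without access to clinical images or records.

**Images.**  A stylized vessel tree: from an off-centre "optic disc", a
fixed number of root branches grow complete binary trees of configurable
depth; segment length, width and darkness decay per generation, with
per-node random jitters; the tree is stamped dark onto a bright background
and Gaussian pixel noise is added.  A left/right pair shares one
structural draw and one noise field; the right image's branch angles,
lengths, widths and contrast are shifted by zero-mean perturbations of a
chosen scale (the injected asymmetry level), so level 0 produces
byte-identical fields and larger levels produce increasingly different
topology.  The model is deliberately not physiological — no fractal
statistics, no flow constraints — it only needs nontrivial component and
loop structure at multiple thresholds, which the tests verify.  Passing
the monotone-response and zero-law tests on these images therefore shows
that the measure responds to structural asymmetry as designed, not that it
has clinical validity on real fundus photographs (which bring alignment
error, illumination gradients and acquisition noise that this generator
does not emulate).

**Cohort.**  One latent lognormal asymmetry propensity `u` per subject
(log-sd 0.5) drives everything shared: each of the 20 bilateral traits
(nine ophthalmic, three Doppler systolic pressures, eight audiometric
thresholds, each with field-realistic means and spreads) draws its signed
left−right difference with standard deviation `effect·u·scale + noise`, so
signed residuals average to zero (fluctuating asymmetry) while their
magnitudes co-vary across body parts through `u`.  Setting the global
effect scale to 0 gives the null regime of independent asymmetries.  The
ROH segment count is Poisson with rate `λ₀·exp(βs − β²/2)` in the
standardized log-propensity `s`; β is solved in closed form (lognormal ×
Poisson moments) to hit a target Pearson correlation with `u` — default
0.229 — rather than tuned by simulation, and mean count λ₀ = 30 with
Gamma-distributed segment lengths (mean 3 Mb) reflects an isolated-island
population.  Survival times are exponential with log-linear hazards in
age (HR 1.10/year), sex (HR 0.67 for women) and comorbidity count (HR 1.22
per diagnosis) around a baseline of 0.012/year; independent exponential
censoring is solved numerically to yield ~40% events.  About 3% of
subjects carry a unilateral-hearing-loss flag and are excluded from the
audiometry group only.  Everything is deterministic under (config, seed),
and CSV round-trips are bit-exact through the package's writers
(shortest round-trip float representation on write, round-trip parsing on
read).

## Cohort asymmetry stages

Per trait: signed residual = left − right; extent = its absolute value;
normalization divides by the per-trait maximum over subjects, giving
unitless values in [0, 1] with exactly one subject at 1 barring ties.
(The alternative residual convention — deviation from the left/right
midpoint — differs by a factor 2 that the max-normalization cancels, so
the choice is observationally neutral downstream.)  Normalized values are
averaged within four body-part groups — retina (the normalized magnitudes
of the two topological measures), ophthalmic, pressure indices,
audiometry — and subjects at or above the empirical 90th percentile
(linear-interpolation quantile; ties at the threshold all flagged) of a
group are its top-decile cases.  The overlap stage computes the exact
16-cell Venn partition of the four flags and the ≥2-flag multi-asymmetry
indicator; subjects missing any group's flag (e.g. audiometry exclusions)
are dropped as incomplete, with the count logged.  Under independent group
asymmetries the multi-asymmetry fraction has the closed form
`1 − 0.9⁴ − 4·0.1·0.9³ ≈ 5.23%`, which the tests verify by simulation at
n = 10,000; a shared propensity raises it.

The estimator classes (`ReVAExtractor`, `TraitMaxNormalizer`,
`TopDecileFlagger`) expose these stages in scikit-learn fit/transform
form for composition with pipelines and model selection; the module-level
functions are the same logic.

## Statistics

Correlations are pairwise-complete Pearson (scipy), reported with n and
two-sided p per pair; no multiple-testing correction by default (an
optional Benjamini–Hochberg flag exists).  Group comparisons use Welch's
t-test (two groups), one-way ANOVA (more), or chi-square for categorical
variables.  Survival uses lifelines' Cox partial-likelihood fit with fixed
reference levels (men, the Vis sub-cohort, no multi-asymmetry) and
listwise deletion (logged); at least 10 events are required.  Comorbidity
enters the model as the numeric 0–5 count; the none/one/multiple grouping
is descriptive only.  The acceptance suite checks calibration: over 100
simulated cohorts of n = 1800 with ~40% events, the 95% CIs cover the
configured hazard ratios at the nominal rate and the mean age-effect
estimate is within 0.02 of truth.

## Problem sizes and numerical choices

Persistence at 64×64 takes ~45 ms per image pair (both dimensions), so
the simulation-heavy tests use 32×32–64×64 images and 20–50 replicates
per property; cohort-level tests use n = 50–10,000 rows, and the Cox
calibration uses 100 × n = 1800.  These sizes put every Monte-Carlo
tolerance (±0.05 on correlations, ±0.01 on the null overlap fraction,
coverage ≥ 0.89 of a nominal 0.95) at three or more standard errors.
Tie-breaks are fixed throughout (smallest mean age at supremum ties,
vertex index at merge ties, first occurrence in argmax), and one run
seed fans out to per-stage `SeedSequence` children, so whole-pipeline
re-runs are byte-identical.

## Known limitations

* The filtration direction is fixed to sublevel; bright-on-dark imagery
  should be inverted by the caller (the unit transform makes this a
  one-liner).
* The essential-class death convention couples APF₀'s largest step to the
  image's intensity range; comparing images with very different dynamic
  ranges under the `z` transform shifts that step's location.
* The vessel generator produces trees, so dimension-1 signal in synthetic
  pairs comes mostly from noise loops and branch crossings at coarse
  thresholds; real vasculature has richer loop structure.
* The survival stage models a proportional, time-constant hazard; no
  frailty or stratified extensions beyond the optional sex-stratified run.
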