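# Methods

This note documents the models and estimators implemented in `nichefill`,
the numerical choices behind them, what the synthetic data do and do not
emulate, and the known limitations. Parameters named here are the package
defaults; all are exposed in the API.

## Environmental space

The niche comparisons operate in a reduced climate space built from six
bioclimatic variables (annual mean temperature BIO1, warmest/coldest-quarter
means BIO10/BIO11, annual precipitation BIO12, driest-month precipitation
BIO14, and radiation RAD). Variables are screened so that every retained
pair has |Pearson r| < 0.85 (`screen_variables`; the lower-priority member
of an offending pair is dropped).

Because occurrence databases oversample well-recorded regions, availability
is characterized by background points drawn from a **sampling-effort
surface**: reference-taxon records (any well-sampled clade occupying the
same habitats) are binned on the raster grid, Gaussian-smoothed
(sd = 3 cells), floored at 1e-6 of the surface maximum on valid cells —
absence of records may be a recording artifact, so no available climate gets
zero probability — and normalized. 100,000 background points (10,000 in the
desk-scale runs; see *Problem sizes*) are drawn cell-multinomially and
placed uniformly within cells.

The PCA is weighted: rows are the pooled background points and occurrences
(each occurrence carrying the weight of one background point), variables are
centered and scaled by their weighted mean/SD (bioclim units are
incommensurate), and the loadings are eigenvectors of the weighted
covariance of the standardized data. Each loading column is sign-fixed so
its largest-magnitude entry is positive, making axis orientation
reproducible. The first two axes define the grid space; kernel contours of
availability (`density_contour`) use a Gaussian product kernel with
Silverman bandwidths on a 100×100 grid over the pooled score extent ± 5%.

## Occupancy grids and the overlap statistic

For one range, occurrence density `o` and availability density `e` are
Gaussian-kernel estimates evaluated at the centers of an R×R grid (R = 100).
The kernel is a separable product kernel, so the full grid evaluates as one
matrix product per axis — exact, not an approximation.

Three numerical choices matter here:

- **One bandwidth for everything.** `o` and `e` of both ranges share a
  single per-axis bandwidth (the mean of the two ranges' occurrence
  Silverman values, `n^(−1/6)·sd`). The corrected occupancy `z = o/e`
  is a ratio of two density estimates; if numerator and denominator smooth
  at different scales the ratio inherits availability structure that has
  nothing to do with the species, and two samples of the *same* niche can
  show D ≈ 0.75–0.84 instead of ≈ 0.93.
- **Availability support.** Cells with `e` below 1e-4 of its maximum count
  as unavailable; the ratio is never formed in the far kernel tails where
  both densities underflow.
- **Two estimands, two scales.** Schoener's D and its randomization test are
  computed on grids smoothed at 2× the Silverman bandwidth; the
  expansion/stability/unfilling masks use the 1× grids. Overlap is a
  whole-distribution statistic whose error is dominated by kernel variance;
  occupancy support is a boundary-location problem that heavier smoothing
  would blur.

`D = 1 − ½ Σ|p1 − p2|` with `p` the corrected occupancy normalized to sum 1
over the grid. The similarity test translates one range's occupancy surface
so its density centroid lands on a uniformly chosen cell of that range's
available space, recomputing D each time (100 randomizations;
`p = (#{D_null ≥ D_obs}+1)/101`). Toroidal wrap-around is disallowed — mass
translated off the grid is dropped and the surface renormalized, since
re-entering climate space from the opposite side is meaningless. Placements
are restricted to cells jointly holding the top 85% of the availability
mass: the kernel halo beyond the genuinely available climates otherwise
hosts placements with artificially low D and makes the test
anti-conservative. That 15% trim was calibrated on null simulations (niche
placed at random within its background; p-values checked for uniformity
over several experiment seeds) and then frozen. Both test directions
(native→non-native and the reverse) are run by swapping which surface is
randomized.

## Expansion, stability, unfilling

Within analog climate (cells available to both ranges), with each range's
corrected occupancy normalized to sum 1:

- expansion `E` = share of non-native occupancy in cells the native range
  does not occupy;
- stability `S = 1 − E`;
- unfilling `U` = share of native occupancy in cells the non-native range
  does not occupy.

"Occupied" needs care with Gaussian kernels, which never strictly vanish: a
plain `z > 0` rule declares every analog cell occupied and drives `E` and
`U` to zero regardless of the real niche change. The default occupancy rule
therefore (i) derives one **common density cutoff** — the level below which
the lowest-density cells of the two ranges' mean occupancy field jointly
hold 5% of its mass — and applies it to both ranges (a per-range cutoff
mismatches the two trim contours and biases both indices upward even for
identical niches); (ii) **dilates** the opposing range's occupancy mask by
one grid cell before exclusion, absorbing trim-contour sampling wiggle; and
(iii) counts each range's occupancy mass only on its own occupied cells
(density in cells a range does not occupy is trimmed kernel tail, not
niche). An exact-threshold mode (`occupancy_quantile=None`, `z > τ`) is kept
for analytically constructed grids and for users who prefer the full-extent
convention, and a binary (cell-count) weighting is available alongside the
default density weighting.

## Covariance-structure comparison (CPCA)

The two ranges' climatic covariance matrices are compared under Flury's
hierarchy: equality (one shared matrix), proportionality (Σ₂ = ρΣ₁),
common principal components (shared orthogonal eigenvector basis B, free
eigenvalues per group), and unrelated. All models are fitted by maximum
likelihood under a two-group Wishart model with group weights n₁, n₂ (the
occurrence counts): equality by the pooled covariance; proportionality by
alternating updates of Σ₁ and ρ (converges monotonically from ρ = 1, so its
likelihood never falls below equality's); the CPC basis by the
Flury–Gautschi pairwise-rotation algorithm, initialized from the pooled
matrix's eigenvectors, sweeping all column pairs until the criterion
improves by less than 1e-10 (cap 1,000 sweeps; non-convergence raises an
error carrying the criterion trace). Parameter counts (p variables, 2
groups): equality p(p+1)/2, proportionality +1, CPC p(p−1)/2 + 2p,
unrelated p(p+1)/2 × 2; χ² statistics are likelihood ratios against
unrelated with df equal to the parameter-count difference, and the
preferred model minimizes AIC = −2 logL + 2k (ties break toward fewer
parameters).

One statistical caveat is inherent to AIC here: when a boundary hypothesis
is true (say equality), AIC prefers the adjacent richer model whenever the
1-df likelihood-ratio χ² exceeds 2, which happens with asymptotic
probability ≈ 0.16 at any sample size. Selection rates for the equality and
proportionality generators therefore plateau in the mid-80s%, while the cpc
and unrelated generators are recovered near-always; pooled over the four
generators the recovery rate is ≈ 92% (n = 500, p = 6).

## Hypervolumes

Each range's standardized climate cloud carries an axis-aligned **box
kernel** per point; the hypervolume is the union of boxes, estimated by
importance sampling: candidates are drawn uniformly from randomly chosen
boxes and accepted with probability 1/(number of boxes containing them),
leaving the accepted points exactly uniform over the union, whose volume
follows from the acceptance rate. Box kernels make inclusion tests exact,
so the intersection of two hypervolumes is estimated by cross-inclusion of
each one's uniform points in the other's support (the two one-sided
estimates are averaged); union, unique fractions, overlap fraction
(union denominator by default, mean available) and size ratio follow.

The box half-width per dimension is `0.7 × (4/(m(d+2)))^(1/(d+4)) × sd`,
where `m` counts *distinct* points. The 0.7 factor was calibrated once
against a known-volume oracle (500 uniform points in the 3-D unit cube):
the raw Silverman factor as half-width inflates the union ~47%
(boundary-dilation dominated) while using it as full width deflates ~45%
(interior holes); 0.7 recovers the cube volume to ~1%. Counting distinct
points keeps the volume invariant under dataset duplication — duplicates
carry no information about support geometry, but would otherwise shrink the
Silverman bandwidth and the volume by ~10%. `samples_per_point` (default
100) is the accuracy/runtime knob; doubling it moves the volume < 1%.

Both ranges must be standardized with the *same* statistics (the native
range's mean/SD by convention) or their volumes are not comparable; the
`standardize` helper enforces this pattern. Variable importance for a
hypervolume is the normalized shrinkage `V_full / V_without_k` when
dimension k is dropped and the hypervolume rebuilt with the same seed.

In high dimensions (d = 6) at ecological sample sizes the union of boxes
systematically undercovers a filled region (points cannot tile a 6-D
volume), so absolute 6-D volumes are conservative; ratios and overlap
fractions between two clouds built under the same convention remain
meaningful, which is how they are used.

## Fundamental niche from tolerance limits

Temperature tolerances enter as constants: optima for egg incubation
(29.5 °C) and daily activity (25.6 °C); ranges for feeding (16.8–32.1 °C),
normal activity (10–37 °C) and basking (26.7–31.2 °C); lethal limits
−12.6 to 42.3 °C; and a 10-km buffer for distance to fresh water. Each
behaviour becomes a beta curve `k(x−p1)^α(p2−x)^γ` on the open lethal
interval, normalized to max 1 (mode at `(αp2+γp1)/(α+γ)`):

- optimum behaviours: mode pinned at the optimum, α+γ = 6 (one free shape
  degree of freedom; 6 gives a smoothly peaked curve);
- range behaviours: α, γ solved so the curve crosses 5% of its maximum
  exactly at the reported range endpoints. At a trial mode the two endpoint
  conditions are *linear* in (α, γ); the solver scans the mode for a
  self-consistency sign change and refines by bisection — robust where a
  bivariate Newton solve stalls.

The composite tolerance curve is the normalized equal-weight mean of the
five behaviour curves (product composition available; it errors on disjoint
supports). It is exactly 0 at and beyond the lethal limits, positive
everywhere inside, and attains 1 at 28.8 °C — inside the basking/incubation
zone. Distance to water is a decreasing logistic with midpoint 10 km and
scale 2.5 km, keeping suitability ≥ 0.88 at 5 km (turtles routinely roam
5–10 km overland).

Habitat suitability composes the responses per raster cell — product by
default (conservative, limiting-factor logic), mean optional — and is
rescaled to [0, 1] over valid cells; nodata propagates. The occupied
temperature range is the contiguous region around the mode of a Gaussian
KDE of occurrence temperatures where the density stays ≥ 5% of its maximum
(the KDE rescaled to max 1 for plotting against tolerance curves); the
unfilled-tolerance report gives the fractions of the tolerance support
(curve > 0.05) lying below and above the occupied interval.

The environmental-space region classification needs the fundamental niche
as a mask over the PCA plane, including climates not available anywhere at
present; each grid cell's center is mapped back to climate space through
the minimum-norm PCA inverse and the suitability responses evaluated there.

## Synthetic data

`make_landscape` builds six climate-like surfaces on a projected-km grid as
broad gradients plus Gaussian-filtered noise (autocorrelation length 15
cells): an annual-temperature surface spanning a requested range,
warm/cold-quarter surfaces tracking it at ±8 °C, precipitation along the
orthogonal gradient, radiation on the diagonal, random-disk water bodies
and their exact distance field. `simulate_virtual_species` samples
occurrence cells with probability proportional to suitability × bias
(occurrences conditionally independent given suitability; bias acts
multiplicatively, matching the assumption behind effort-weighted
backgrounds). The default bias surface is a Gaussian bump near one corner
(strength 0.5), and each landscape also yields *reference-taxon* records
whose density tracks the bias only — the analysis estimates its
sampling-effort surface from these, which is what lets the corrected
occupancy cancel the bias.

`make_invasion_scenario` designs a known niche change along the temperature
axis: the native niche is a beta response on (5, 23) °C; the invader (a)
loses the warm tail above the temperature below which 1 − U_target of the
native suitability mass lies, with a 3 °C cosine taper (a gradual range
edge; a cliff edge would be smeared by the kernel and bias the recovered U
downward), and (b) gains an expansion lobe on (29, 35) °C scaled to carry
E_target of its suitability mass — outside the native niche but inside the
climates available to both ranges, separated from the native niche by ~3
kernel bandwidths so the signal is resolvable at n = 1,000. The two
landscapes share one structural seed with thermal regimes (−5, 38) vs
(0, 43) °C: broad analog space, a genuinely non-analog warm margin, and —
critically — similar joint distributions of the secondary climate variables,
without which the same temperature niche occupies different parts of the
PCA plane in the two ranges and the designed 1-D truth does not apply. The
**achieved** fractions (recomputed by numerical integration over the analog
temperature interval) are stored with the scenario; recovery is always
scored against achieved values, not targets. Targets of exactly 1 are
rejected as infeasible (the construction scales the lobe by E/(1−E) against
the shared-niche mass).

What the generator does *not* emulate: real covariance among bioclim
variables beyond two latent gradients, coastlines and irregular study-area
boundaries, spatial aggregation of records beyond a smooth bias field,
taxonomic error, and dispersal limitation within a range. Passing recovery
tests therefore demonstrates estimator correctness under the model's own
assumptions, not robustness to every field complication.

## Pipeline, seeds, problem sizes

`run_pipeline(RunConfig(...))` chains every stage and writes a consolidated
JSON report (sorted keys), occupancy grids as CSV, the suitability raster
as an ASCII grid and optional PNG quick-looks. All randomness flows from
one master seed through fixed named substreams, so a rerun with the same
config is bit-identical; rasters travel as plain-text ASCII grids and
polygons as GeoJSON, keeping every artifact diffable.

Default desk-scale problem sizes — 200×200-km landscapes, 1,000 occurrences
per range, 10,000 background points, R = 100, 100 randomizations — complete
the full pipeline in well under a minute on one core and give recovery
errors comfortably inside ±0.10 for the designed indices; the validation
experiments (200 null datasets for test calibration, 4×50 replicates for
CPCA model recovery) add a few minutes. Larger backgrounds sharpen the
availability estimate but leave the comparisons unchanged.

## Known limitations

- The o/e correction is undefined where availability is (numerically) zero;
  conclusions about climates at the very margin of a range's availability
  depend on the availability floor.
- E/S/U depend on the occupancy convention; the common-cutoff default is
  calibrated for kernel estimates at n ≈ 10³ and the exact-threshold mode
  should be preferred for analytically specified grids.
- The similarity test conditions on the estimated occupancy surface; its
  null reflects placement, not re-sampling, variability.
- Absolute 6-D hypervolumes undercover (see above); compare, don't trust
  their absolute scale.
- Geographic distances treat raster grids as isotropic-km (exact for the
  synthetic projected grids; an approximation at a stated reference
  latitude for geographic grids). Spatial thinning uses great-circle
  distances and is greedy in input order — sort by id first for an
  order-free result.
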