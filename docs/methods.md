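# Methods

`seasonstruct` links remotely sensed forest structure and its within-season
stability to ground-measured overyielding in a young tree diversity
experiment. This note records the models, the synthetic study design, the
numerical choices, and what the tests do and do not demonstrate.

## The analysis chain

Per plot (100 m², 10 m × 10 m) and survey date, a LiDAR-like point cloud is
conditioned in a fixed order — height normalization, clipping to the plot
polygon shrunk by a −0.5 m buffer (81 m² of analysis area, matching the
edge-row exclusion of the field inventory), statistical outlier removal on
vegetation returns (k = 30 neighbours, mean-distance threshold at the 97.5%
type-7 quantile, applied only above 0.25 m), and 1 cm voxel thinning — and
summarised by three metrics:

* **HH_CV**, the coefficient of variation (sample SD over mean) of 0.1 m
  digital-canopy-model cell heights, with empty cells excluded (zero-filling
  would conflate canopy gaps with height variance; a flag restores the
  zero-filled variant);
* **FC**, fractional plant cover: the sum over vegetation returns
  (height > 0.25 m) of 1/return_number, divided by the pulse count (pulses
  are identified by first returns because pulse IDs are not carried);
* **d_D**, a fractal dimension: Hill diversity of order q = 0.999 of the
  per-voxel point shares is computed for 12 log-spaced voxel edges between
  0.1 and 2.25 m, and d_D is the standardized-major-axis slope of
  log D against log(1/S). At q = 0 the curve reduces to classic box
  counting (tested against a brute-force voxel count); q near 1 discounts
  density differences between plots. The Shannon limit replaces the power
  form only when |q − 1| < 1e−6.

Seasonal structural stability is the inverse CV, SS = mean/SD, of each
metric over the eight surveys of one growing season (DOY 100, 138, 163,
188, 215, 250, 261, 297). SS is scale-invariant, undefined on incomplete
series (an error, not a silent skip), and flagged infinite when the series
has zero variance. Plots enter the analysis only if their maximum canopy
height exceeds 1.5 m at every survey, their mean planting year predates
2019, and they were not replanted in the study year.

Ground-based productivity treats each stem as a conoid: V = H·π·D_rc²/12
below breast height, and the conoid frustum between the root collar and
1.3 m plus a conoid above it otherwise (verified against quadrature of the
solids of revolution to 1e−9 relative). Annual wood productivity divides
the volume increment between two inventories by the interval (365 d/yr) and
the 0.0081 ha effective plot area; dead trees contribute their lost volume
as a negative increment. The net biodiversity effect is
NBE = AWP_plot − Σᵢ pᵢ·AWPᵢ with monoculture means taken as the grand mean
over qualifying monocultures, and is partitioned into complementarity and
selection effects with the relative-yield algebra (population covariance,
so CE + SE equals NBE exactly).

Diversity uses Hill numbers at q = 0: richness after mortality,
phylogenetic diversity as the pruned-tree total branch length including the
stem to the root, and functional diversity as the ordered-pair sum of
Euclidean distances on z-scored traits (the dendrogram-total-branch-length
alternative sits behind a switch). Variability is the phylogenetic species
variability of Helmus — one minus the mean off-diagonal correlation of the
shared-branch-length covariance — applied to the phylogeny, to a UPGMA
dendrogram of trait distances, and to a unit-step taxonomic-distinctness
tree (congeners join at one step, confamilials at two, ordinal relatives at
three, the rest at four). UPGMA is used for both constructed trees because
PSV requires ultrametry. Monocultures carry no variability value.

The statistical layer natural-log transforms strictly positive metrics,
stabilities, volumes and diversity values (never NBE, which can be
negative), fits per-date OLS cross-sections, fits mixed models with the
predictor × DOY interaction and random intercepts for plots nested in
blocks (falling back, with a log message, to a plot-only intercept when the
nested fit is singular), and fits a structural equation model. The SEM is a
RAM-parameterised covariance-structure model estimated by maximum
likelihood on standardized variables: latent Diversity is measured by
richness, PD and FD; latent Variability by the three PSVs (anchored on the
phylogenetic one, the most reliable indicator); SS regresses on both
latents and NBE on SS and both latents. Standard errors come from the
numerical Hessian of the discrepancy function; latents are orientated after
fitting so each has a positive mean standardized loading, because a latent
factor is only identified up to sign. Significance is two-sided at 0.05
with no multiple-testing correction — each model is reported on its own.

## The synthetic experiment

The generator emulates a single-cohort common-garden experiment on flat
ground: twelve species (eight deciduous, four evergreen) on an ultrametric
phylogeny whose deepest split separates the leaf habits, with traits (wood
density, leaf mass per area, maximum height, relative growth rate, shade
tolerance) evolved by Brownian motion on the tree plus independent noise —
phylogenetically autocorrelated but not perfectly so. Plots carry
replicated monocultures plus random mixtures at richness 2, 4, 6 and 12 in
three blocks; trees sit on a 1 m grid, and the outer row (within 0.5 m of
the boundary) is excluded from all ground-based quantities.

Deciduous foliage display follows a double-sigmoid (smoothstep) curve of
DOY — exactly zero at or before flush − 3·sharpness, one at mid-season —
with species flush dates drawn once from DOY 110–135, senescence from
270–295, and sharpness from 5–8 days; evergreen display is constant. A
woody floor (8% of full foliage density) keeps leafless crowns visible to
the scanner, as bare branches are. Each plot additionally shifts every
species' phenology by a microsite offset (SD 6 days) — a realized,
plot-level quantity that the repeated surveys can measure but
composition-based metrics cannot.

Point clouds are simulated by vertical ray casting on a jittered pulse grid:
crown solids (cones for evergreens, ellipsoids for deciduous) intercept a
pulse segment of length L with probability 1 − exp(−λL), where λ is the
species foliage density (1.5–2.5 m⁻¹) scaled by the phenology curve; the
beam continues after a return with probability 0.6 up to the sensor's three
returns, and yields a ground return if it reaches the ground. A configurable
fraction (default 0.1%) of high outliers is injected 2–10 m above the
canopy to exercise the SOR filter, and a ground-offset variant exercises
height normalization. Mortality (default 5%/yr) zeroes year-2 measurements.

**The injected biodiversity effect.** Year-2 growth of each tree is
`base × (1 + strength · bᵢ / 0.1)` where bᵢ is the species' *temporal niche
benefit* in the realized surviving community: the mean, over neighbours
weighted by their shares, of the fraction of the focal species'
activity-weighted season during which the neighbour's canopy is dormant,
measured against the conspecific baseline and clamped at zero (competition
is part of the base rate; complementarity only adds). The benefit is zero in
monocultures by construction, largest for evergreens among deciduous
partners, and positive for deciduous species with spread flush dates — so
mixtures overyield exactly to the extent that their members' canopies are
active at different times, which is also what stabilises the community's
cover across the season. The 0.1 normaliser is the typical cross-habit
benefit, so `strength` is roughly the maximal fractional growth boost; the
default 0.5 produces mean overyielding of order 20–40% of expected
productivity, at the strong end of what young diversity experiments report.
With strength 0, mixture NBE is centred on zero (checked to within two
standard errors over ≥100 plots).

## What the synthetic data do and do not show

The generator reproduces the qualitative machinery the analysis targets —
phenology-driven seasonal structure, return-number statistics, edge
effects, outliers, mortality, and a diversity effect on growth routed
through temporal complementarity. It does not attempt radiometric realism,
wind, calibrated allometry, spatially structured mortality, or the oblique
scan geometry of a real survey (pulses are nadir; the metrics depend on
return and height structure, not scan angle). Passing tests therefore show
that the pipeline recovers relationships a forest with these mechanisms
would produce, not that the real forest has them.

Problem sizes are chosen for a single CPU: the parameter-recovery run uses
about 150 plots × 8 survey dates at 150 pulses/m² (the real sensor's
~2100 points/m² would change precision, not structure), and the
null-hypothesis replicates use a smaller design at lower density, with
clouds generated only for the mixture plots the SEM consumes.

## Numerical choices and degenerate inputs

* Sample (n−1) SD everywhere a CV or SS is formed, and in the SMA fit.
* Voxel grids (decimation and box counting) anchor at the cloud's minimum
  corner; decimation keeps the first point in input order per voxel. Both
  choices are documented because the operations are origin-sensitive.
* SOR uses the mean distance to the k nearest neighbours and a
  linear-interpolation (type-7) quantile threshold; clouds with too few
  vegetation points pass through with a warning.
* Ground estimation is per-cell minimum (1 m cells) with bilinear
  interpolation and nearest-cell filling — adequate for the flat outwash
  terrain emulated here, not for slopes beyond a few percent.
* SMA with zero response variance returns slope 0 with a degenerate flag;
  box counting requires a non-empty cloud; FC clamps to 1 with a warning if
  orphaned multi-returns push the weighting above the pulse count.
* The SEM objective certifies positive-definiteness by Cholesky, bounds
  variances below at 1e−6, raises an identification error on singular
  sample covariances (e.g. collinear indicators), and reports
  non-convergence with the optimizer state rather than silently.
* Box-counting scales should not exceed roughly half the object extent;
  for the 3 m reference solids used in dimension-recovery checks the
  sequence is truncated at 1.5 m.

## Known limitations

* PSV here follows the shared-branch-length correlation definition; PSE/PSR
  abundance-weighted variants are out of scope.
* The functional-Hill FD convention is the ordered-pair total distance; the
  literature also uses dendrogram-based FD, available behind a switch but
  not the default.
* The mixed model treats DOY as continuous and linear; the pronounced
  seasonal curvature in the metrics is absorbed by the interaction and the
  random structure, which is the model family the analysis specifies, not a
  claim of linear phenology.
* The SEM's SS → NBE path measures the unique association of measured
  stability with overyielding conditional on two latent factors built from
  noiseless composition summaries; with the injected mechanism its
  standardized value is small though positive, and it is the weakest link
  in the recovery chain at desk-scale problem sizes.
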