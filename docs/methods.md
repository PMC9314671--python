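# Methods

This note records the models, parameter choices and numerical decisions
behind `cryosdm`, and what the synthetic benchmarks do and do not
demonstrate.

## Spatial frame

All modelling happens on a North Pole Lambert azimuthal equal-area grid.
The projection is implemented in its spherical form (mean Earth radius
6371.0088 km): ρ = 2R·sin((90°−φ)/2), x = ρ·sin λ, y = −ρ·cos λ. On the
sphere this is exactly area-preserving, so habitat area is cell count ×
one constant cell area (`resolution_km²`). Geographic source layers are
cropped to ≥ 30 °N and resampled by nearest neighbour: each target cell
takes the value of the source cell containing its centre and is valid
only if that source cell is valid. Nearest-neighbour resampling avoids
inventing values along the coast and keeps the categorical substrate
layer meaningful; invalid cells never gain values. The target resolution
is configuration (default 50 km for the synthetic system); the cell area
printed by a run is always derived from it.

The study mask keeps cells that are shallow (depth between 0 and 100 m
inclusive, positive down) **or** whose centre lies within 10 km of the
shoreline, **and** whose substrate is erosional (rocky), **and** whose
centre latitude is ≥ 30 °N. Cell membership of a point uses half-open
cell intervals (left/top edge inclusive). Any cell invalid in any
selected covariate layer is excluded from modelling and background.

## Occurrences and background

Records with coordinates outside [−180, 180] × [−90, 90] are skipped with
a logged count. Records falling in the same grid cell collapse to a
single presence; records outside the study mask are dropped and counted.
No temporal filter is applied by default (a `min_year` option exists).
The background is the target-group sample: the union of every modelled
species' presence cells, the modelled species included. This makes the
background carry the same spatial survey bias as the presences. A
consequence worth knowing: removing a species from a run changes the
background and therefore, slightly, every other species' fit.

## Covariate screening

Candidate covariates are screened on the background cells by stepwise
variance inflation: VIF_j = 1/(1−R²_j) from regressing covariate j on all
other candidates (with intercept); while any VIF ≥ 10 the worst covariate
is dropped (ties broken by earliest column order). The background is used
because it represents the environmental space the model normalises over.

## MaxEnt core

Features are built from min–max-scaled covariates (training ranges taken
over the pooled presence+background sample): linear z, quadratic z²,
pairwise products, and forward/reverse hinges at 8 evenly spaced interior
knots per covariate. At prediction time inputs are clamped to the
training range by default, so future-scenario extrapolation saturates
rather than explodes.

Weights minimise −(1/m)Σ_presence λ·f + log Σ_background exp(λ·f) +
Σ_j β_j|λ_j| with β_j = β·max(s_j, 0.1)/√m, s_j the feature's standard
deviation over the presence sample. The floor of 0.1 (about a third of
the standard deviation of a uniform [0, 1] feature) matters: features
that are nearly constant across presences — typically a covariate that
merely brackets the range boundary — would otherwise be almost
penalty-free, and the optimiser would substitute them for the covariates
that actually structure the niche, distorting permutation-based variable
contributions.

The L1 problem is solved exactly by splitting λ into positive and
negative parts and running bound-constrained L-BFGS-B (up to three warm
restarts). Convergence is verified against the subgradient optimality
conditions; a residual above 10⁻⁶ is logged, above 10⁻³ it raises a
convergence error carrying the residual. Raw output exp(λ·f−log Z) sums
to one over the training background by construction. The default display
transform is the logistic τ·r·n/(1+τ·r·n) with τ = 0.5 and n the
background size; a complementary log-log transform using the training
entropy is available. Both are strictly increasing in raw, so rankings,
AUC and threshold ordering are transform-independent.

Hyperparameters can be tuned by seeded k-fold cross-validation over a
grid of feature-class sets ({linear+quadratic, +product, hinge-only,
all}) and penalty multipliers ({0.5, 1, 2, 4}), scored by mean held-out
AUC; ties go to the first candidate in grid order. Tuning is off by
default in the synthetic experiments (a fixed all-classes, β = 1 model);
benchmarks showed it changes results little there while multiplying cost.

Variable contributions are permutation importances: each covariate
column is shuffled jointly across the pooled presence+background rows
(three shuffles averaged), the drop in training AUC floored at zero, and
drops normalised to sum to 100.

## Evaluation

* **AUC**: rank-based presence-vs-background estimator with half credit
  for ties.
* **Boyce index**: 101 overlapping windows of width 10 % of the landscape
  prediction range; P/E per window (presence fraction over landscape
  fraction); windows with no landscape mass dropped; duplicated P/E
  values reduced to their first occurrence (the standard treatment — long
  runs of tied empty windows would otherwise swamp the statistic); index
  = Spearman correlation of P/E with window midpoint. The landscape is
  the whole masked study area.
* **Spatial-block cross-validation**: square 300-km blocks (configurable)
  assigned largest-first to the currently least-loaded fold, which
  balances presences per fold while never splitting a block. AUC and
  Boyce are means over held-out folds refit per fold. If the presences
  occupy too few blocks the run falls back to random folds with a
  warning.
* **Threshold**: the max-sensitivity+specificity cut-off (sensitivity
  counts presences ≥ t, specificity background < t, candidates are the
  unique predicted values, ties go to the smallest candidate using exact
  integer scoring). The operational threshold is the mean of per-fold
  max-SSS thresholds computed on held-out predictions of a seeded
  fivefold split, and the same per-species threshold is reused for every
  future scenario — a threshold is a property of the model, not of the
  scenario.

## Projection and areas

Binary maps are suitability ≥ threshold inside the mask (inclusive).
Stacks are cellwise unions within the cryophilic and cryotolerant
categories; cryophobic species are never stacked. Change maps classify
cells as stable (1→1), loss (1→0), gain (0→1) or absent. Areas are
Σ value × cell area over cells at or above each cut in {30, 40, 50, 60,
70, 80}°N, for both thresholded (primary) and probabilistic maps, with
percent change against the present day.

## The synthetic world

The generator produces a closed system in which truth is known, sized by
default at 60 × 360 cells of 1° between 25 and 85 °N (the size used
throughout the test suite and the acceptance script).

* **Seascape**: land/sea from thresholded kernel-smoothed noise (35 %
  land, 6° correlation length; correlation lengths are physical, so
  different grid resolutions sample the same process). Distance to shore
  uses an equirectangular metric; depth grows at 1.5 m/km beyond the
  shore-adjacent ring (so shoreline cells have depth 0) with
  multiplicative noise; substrate is 60 % erosional in contiguous
  patches.
* **Temperature**: the benthic minimum follows a sigmoid latitudinal
  profile — 14 °C at the southern edge, steepest decline (0.65 °C per
  degree) near 45 °N, plateauing at −2 °C across the high Arctic — plus
  smoothed noise (sd 1.5 °C). Real benthic minima saturate near the
  freezing point; the plateau also means temperature carries no
  information *within* the Arctic zone, which is exactly why ice can be
  identified as the driver of Arctic-endemic distributions. The maximum
  sits a 6 °C seasonal offset (plus non-negative noise) above the
  minimum.
* **Ice**: maximum thickness 0.5 m/°C × max(0, 0 − t_min), modulated by
  multiplicative variability (clip(1+0.9·noise, 0)). Ice support is
  pinned to the 0 °C benthic isotherm — the same isotherm that defines
  the Arctic environment — which makes the cryophilic confinement
  invariant exact by construction, while the variability creates
  cold-but-iceless cells whose existence forces models to learn ice
  rather than temperature. Minimum ice is a regionally varying fraction
  (0.45 ± 0.25, smoothed) of the maximum, keeping the two ice layers
  correlated but clearly below the VIF threshold.
* **Salinity**: independent field, 32 ± 2.5 PSU, at half the correlation
  length of the temperature noise (river-plume-scale structure).
* **Scenarios**: uniform warming offsets and multiplicative ice
  reductions per scenario label; the strongest (rcp85_2100) applies
  +3 °C and a 70 % ice reduction.
* **Virtual species**: true suitability is a product of logistic
  responses. Cryophilic: decreasing in minimum temperature with midpoint
  0 °C (any positive slope confines the >0.5 range to sub-zero water
  exactly) and strongly increasing in maximum ice (midpoint ≈ 1.2 m), so
  ice dominates — as it does for real Arctic endemic seaweeds, whose
  phenology tracks ice cover. Cryotolerant: broad thermal plateau with a
  warm limit on maximum temperature (≈ 18 °C) and a dominant salinity
  response. Cryophobic: increasing in minimum temperature with midpoint
  0 °C plus a salinity response. Salinity response directions alternate
  per species (fully marine vs brackish-tolerant, equal odds): without
  this heterogeneity the pooled target-group background itself becomes
  salinity-enriched, and the fitted density ratio provably inverts the
  salinity response of any species with a below-community-average
  affinity. Per-species jitter perturbs slopes (×0.85–1.2) and midpoints
  on scales matched to each covariate's field variation, with thermal
  midpoints confined to the side of 0 °C that preserves the archetype's
  definition.
* **Sampling**: presences are drawn without replacement with probability
  ∝ truth × effort, where effort decays southward-heavy with latitude
  (e-folding 40°), from the coastal habitat band (seaweeds are substrate-
  and light-limited, and surveys are coastal). The default community is
  2 cryophilic, 3 cryotolerant and 3 cryophobic species with 160–350
  presences each, mirroring the structure and sample sizes of curated
  macroalgal occurrence sets.

## What the benchmarks show — and what they do not

On this world the pipeline recovers, across independent master seeds:
the qualitative warming pattern (stacked cryophilic area declines
sharply; cryotolerant declines less in relative terms; the warm
archetype gains), per-species rank correlation ≥ 0.6 between fitted and
true suitability, and top-ranked ice contributions for the Arctic
endemics. These are checks of *internal correctness and identifiability
under known truth*. They do not validate transfer to real data: the
synthetic world has no real coastline geometry or ocean physics, its
warming is spatially uniform, its species' niches are exactly
multiplicative-logistic, and its survey bias is a smooth latitudinal
gradient. Global Spearman recovery is also flattered where a species'
truth is near zero over large parts of the mask — rank agreement among
essentially unsuitable cells is noise — so the per-species floor of 0.6
is a conservative summary of much higher agreement inside and near the
true range.

## Degenerate inputs and tie rules

Constant covariates raise errors at VIF and are dropped with a warning
at feature expansion. All-identical predictions make the max-SSS
threshold undefined (error). Boyce with fewer than three usable windows
is an error; a flat P/E profile returns 0. Argmax ties resolve to the
first/smallest candidate everywhere (VIF drops, tuning grid, threshold).
Every stochastic operation takes an explicit seed; the pipeline derives
per-species seeds from the master seed by hashing the species name, so
results are independent of species ordering and reruns are bit-identical.
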