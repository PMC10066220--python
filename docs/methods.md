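# Methods

## The analysis

The pipeline quantifies the foraging response of a central-place forager to
a change in prey availability, using three independent data streams around
one colony and a single statistical engine for all contrasts.

**Trips.** GPS fixes are linearly interpolated onto an exact 5-min lattice
(no extrapolation past the last fix), passed through an iterative 10 m/s
speed filter (a forward pass that tests each fix against the last retained
one, so speeds are recomputed after every removal and the first fix is never
dropped), stripped of fixes within 250 m of the colony, and split into trips
wherever the remaining fixes have a time gap larger than the interpolation
interval. Trips of ≤ 1 h are discarded. Distances are haversine on a sphere
of radius 6371 km; linear interpolation in lon/lat is adequate at the
< 40 km scales involved. Metrics per trip: duration (h), cumulative distance
(km), maximum straight-line range from the colony (km).

**Dives.** The 1 Hz depth series is first zero-offset corrected: the surface
baseline is a low (5%) quantile over non-overlapping blocks of window/30
samples (window 1800 s), smoothed by a centred rolling lower quartile across
blocks and interpolated back to sample resolution. This O(n) construction
tracks slow sensor drift with little lag and is exact for a constant offset,
provided each 30-min window contains some surface time. Dives are maximal
runs deeper than 3 m (the threshold is configurable; 3 m keeps porpoising
and wave noise out at 1 Hz). The bottom phase spans the first to the last
sample at ≥ 80% of the dive's maximum depth; a dive is *complete* when that
span lasts ≥ 5 s, operationalising "a dive with a bottom phase". Wiggles are
local depth minima within the bottom phase with prominence ≥ 1 m
(scipy's peak prominence on the negated trace); capture effort is the mean
wiggle count over complete dives. Boundary conventions: ≥ on the
completeness threshold, half-open bins everywhere.

**Acoustics.** Sample densities are summed into half-open 0.5 nmi × 5 m
cells over a 0–500 m collection range (a sample exactly on the far transect
end folds into the last bin so density is conserved to float precision).
Swarm depths are the depth midpoints of cells above the first quartile
(type-7, linear interpolation) of positive cell NASC. Horizontal
aggregation per 5-m stratum uses Ripley's K with the isotropic edge
correction:

    K_iso(r) = |W|/(n(n−1)) · Σ_{i≠j} w_ij · 1[d_ij ≤ r]

where w_ij is the reciprocal of the fraction of the circle of radius d_ij
centred on point i lying inside the rectangular window (evaluated on 360
arc points; circles fully inside give weight exactly 1, making the interior
case identical to the naive estimator). The aggregation index is the
unweighted mean over 10 radii (linearly spaced to a quarter of the shorter
window side) of K_iso(r) − πr²: positive = aggregated, ≈ 0 = random,
negative = dispersed. Detection cells are placed at their along-track
midpoints on the transect centreline in a corridor-shaped window (default
width 10 km); the near-collinear geometry is accepted, and a 1-D
along-transect variant (CSR expectation 2r, no edge correction) is available
behind a flag for narrower corridors. Strata with fewer than 5 detections
get an undefined index — the K estimator is uninformative there.

**Environment and breeding.** Gridded fields are subset to cells whose
centres lie within 75 km (haversine) of the colony. CHL, PAR and surface
wind average November–January of the breeding season; sea-ice fraction
averages June–September of the immediately previous winter. Monthly
climatologies report per-calendar-month mean ± sd across years (sd missing
for single-year months). Breeding success is chicks at crèche / nests at
incubation per sub-colony; zero-nest records are excluded and logged.

**PERMANOVA.** One-way, Euclidean distances on z-scored variables
(sample sd), unrestricted label permutations, p = (1 + count)/(1 + n_perm)
with n_perm = 999, so p is never 0 and has resolution 1/1000. Univariate
pseudo-F is algebraically the classic ANOVA F, which the test suite uses as
an exact oracle; a joint multivariate mode exists but per-variable runs are
the default (matching F_{1,N−2}-style reporting). Permuted within-group
sums of squares are computed by batched indicator-matrix products, one
matrix multiply per group. Degenerate within-variance yields an infinite F
flagged with the smallest resolvable p. Endpoints are reported unadjusted
for multiplicity.

## The synthetic generator

The generator emulates the study's two contrasting seasons with the
statistical structure the analysis assumes, not with hydrodynamic or
bioenergetic realism. Defaults (17 vs 10 birds, 5 trips/bird, 8 h vs 12 h
mean trip duration, krill depth mode 50 m vs 90 m, biomass scale 1.0 vs
0.45, parent intensity 0.10 vs 0.14 km⁻¹ with offspring sd 1.0 vs 2.5 km,
CHL 1.2 vs 0.6 mg m⁻³, wind 6 vs 8 m s⁻¹, winter sea ice 0.55 vs 0.30)
encode the qualitative season contrast — the poor season has scarcer,
deeper, more diffuse krill, longer trips, lower breeding success — with
sanity ranges held to the study system: straight-line range capped below
35 km, dive depths clipped at 133 m, wiggles per complete dive in [2, 17],
most dives under 2 min, a configured breeding-success ratio of ~1.4.

Design choices worth knowing:

* **Tracks** are correlated random walks with an outbound phase and a
  homing phase whose colony-ward pull ramps quadratically; the range cap is
  enforced in every phase with one step of slack. Realized trip durations
  land somewhat below the drawn gamma durations (birds sometimes stumble
  home early); season contrasts are unaffected. Fix times carry ±20 s
  jitter and 2% dropouts so interpolation has real work to do.
* **Dives** come in two shapes. Complete dives descend at a rate that grows
  with target depth (clipped 1.0–3.0 m/s), hold a bottom phase whose
  duration is drawn *independently* of the wiggle count (the count is then
  truncated to what fits at 4 samples per wiggle), and carry a per-trip
  random effect. Incomplete dives are fast shallow "bounce" dives (13–17 m
  apex at 2.4 m/s) with a mid-water wander: a slow V-dive would spend > 5 s
  inside 80% of its max depth and classify as complete, so incompleteness
  must come from shape, not brevity. Bounce duration is matched to complete
  dives so mean dive duration carries no season signal. A 3% fraction of
  complete dives targets the krill depth mode: enough to move the per-trip
  *maximum* bottom depth, far too little to move the mean.
* **Krill fields** are Thomas cluster processes along the transect: Poisson
  parents, Poisson(40) offspring with Gaussian horizontal and vertical
  scatter, lognormal per-sample density scaled by the biomass multiplier.
  The good season has fewer-but-denser detection cells (tight clusters),
  the poor season more, weaker ones — which is what drives both the NASC
  and the aggregation contrasts.
* **Environment** grids are i.i.d. Gaussian around scenario means on a 5 km
  grid (no spatial autocorrelation; the PERMANOVA treats cells as
  replicates). PAR is keyed to the calendar month only and is therefore
  identical across seasons — irradiance has no inter-annual contrast in
  this design, making the expected null exact instead of approximate.
* **Breeding**: chicks-per-nest rate mean is 0.98 · (biomass scale)^0.42,
  sd 0.09 across 12 sub-colonies, putting the configured good/poor ratio at
  1.40 (realized ratios scatter ~±0.06 across seeds).

What the generator does *not* emulate: spatial autocorrelation in
environmental fields, tide/weather-driven trip timing, accelerometer-based
prey capture, multi-year demography, or any mechanistic krill–behaviour
coupling (effect *directions* are reproduced, not effect sizes). Passing
tests therefore certify the pipeline's correctness and calibration on data
with this structure, not ecological effect-size fidelity on field data.

## Problem sizes and numerical choices

Default runs use 135 trips, ~10,500 dives (~5.8 M depth samples), 540
along-track bins × 100 strata per season, ~700 grid cells per season within
the 75 km radius, and 999 permutations per endpoint; the full pipeline
completes in a few seconds on one CPU, and the calibration scripts use 500
null replicates and 200 CSR patterns. Reproducibility: one generator stream
per season seeded from the scenario, PERMANOVA seeded per endpoint;
identical configuration gives byte-identical CSV outputs.

Known limitations: the stratum-level aggregation index has heavy right
tails when a stratum holds only a handful of detection cells, so the
between-season aggregation contrast is underpowered at realistic transect
lengths (its season *means* order correctly, but significance is
seed-dependent); the near-collinear window makes the 2-D K magnitude scale
with the configured corridor width (contrasts are width-invariant); and the
trip-binned vertical-effort profile inherits the deliberate
season-invariance of mean bottom depth, so depth shifts in effort appear in
the dive-level distribution (share of wiggles below 60 m), not in the
profile's mode.
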