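# Methods

## Coordinate and unit conventions

All geometry lives in a planar, equal-area coordinate system in kilometres;
no geodesy is performed.  Every downstream computation needs areas and
lengths only, so a planar convention is exact by construction and sidesteps
projection error.  Units are fixed throughout: depth m (positive down),
density kg m⁻² wet weight (WW), biomass t WW, areas km², vessel speeds
knots (1 kn = 1.852 km h⁻¹), filtration 10⁶ L day⁻¹, gas/nutrient fluxes
t day⁻¹.

## Synthetic seascape

The generator produces worlds with the statistical structure the estimators
assume, not replicas of any real bank:

* **Bathymetry** — a linear west→east ramp (defaults 100 → 2600 m) plus
  smoothed Gaussian relief (SD 150 m).  The ramp guarantees both a
  sponge-suitable band and abyssal cells beyond the 2000 m occurrence
  limit, so depth masking is always exercised.
* **Sponge density** — a sum of Gaussian patches (default 60, SD ≈ 6 km)
  with log-normal peak amplitudes (median ≈ 0.02 kg m⁻², the density scale
  reported for the Sackville Spur closure), tapered by a Gaussian depth
  preference centred at 1200 m, plus a small diffuse background
  (2 × 10⁻⁴ kg m⁻²); hard zero deeper than 2000 m.  This reproduces the
  patchy, depth-structured fields that make grid infilling and
  distribution modelling non-trivial, with peak cell densities of order
  0.1 kg m⁻², matching the reported 5 × 5 km cell maximum (0.13 kg m⁻²).
* **Covariates** — depth, slope, a temperature proxy, and a "productivity"
  field constructed to co-vary with the density field.  The real predictor
  stack (50 kriged layers) carries the signal that lets a random forest
  explain sponge biomass; one informative synthetic covariate plays that
  role here.  Covariates arrive on the analysis grid; no kriging is
  emulated.
* **Divisions** — four equal vertical strips named after the NAFO
  divisions (3L/3M/3N/3O): a cover of the extent with no overlap, which is
  all the division logic requires.
* **Closures** — discs centred on the densest cells (emulating closures
  drawn around known grounds), default radius ~20 km so a standard 18-nm
  trawl set fits inside.
* **Tows** — midpoints uniform over the extent (the real surveys are
  depth-stratified; uniform sampling suffices for estimator testing and
  keeps the catchability contract trivial to verify).  Catch = local
  density × swept area × 1.0 (100% catchability), with the gear fixed per
  division (Lofoten in 3M, Campelen elsewhere).  Tows are point samples;
  the survey tow length/speed is not modelled, only the published swept
  areas (39,000 / 67,000 m²).
* **VMS tracks** — each vessel alternates steaming legs (9 ± 1 kn,
  whole ping intervals long) and fishing legs (nominal 3 kn along the
  local isobath, default 18 nm).  Pings fall on a regular clock; ticks on
  a fishing-leg endpoint count as fishing, so a 6-h set with hourly pings
  emits 7 fishing pings (fenceposts).  Recorded speeds are jittered within
  their side of the 6-kn threshold, so the speed filter separates phases
  exactly — real VMS data contain slow steaming and fast fishing pings
  that this generator deliberately omits.

Passing tests on these worlds demonstrate estimator correctness
(arithmetic, conservation, recovery of known totals), not field accuracy:
real surveys have stratified designs, gear selectivity below 100%,
positional error and non-Gaussian patchiness.

## Grid-cell biomass surface

Tow-to-cell assignment uses half-open intervals [x₀, x₀ + 5) so edge
points belong to exactly one cell.  Cells are estimated separately from
tows inside and outside the closure union (a tow on the closure boundary
counts as inside, via polygon coverage), then merged by area weighting:
a bisected cell carries each stratum's estimate on its own fraction.  The
per-cell estimate scales each tow by its own gear factor
(cell area / swept area, unrounded — the printed 373/641 are rounded
display values) before averaging, which reduces to the mean-catch formula
when a cell is single-gear and handles mixed-gear cells gracefully.

Focal infilling is a single pass over a queen (8-neighbour) window using
*observed* values only: filled values never seed further fills, and fills
never cross a stratum boundary.  Whether the original procedure iterated
is unstated; a single pass is the conservative reading (it never
extrapolates beyond one cell from data) and is the documented default.
Zero-catch cells are observed zeros, never refilled.

Totals over a region weight each cell-stratum piece by
area(cell ∩ stratum ∩ region) / cell area.  Empty regions warn and return
0.

## Random-forest model

The response defaults to tow density (catch / swept area, kg m⁻²) rather
than raw catch because the two gears sweep different areas; a raw-catch
mode exists for comparability but is rejected for surface prediction
(it predicts kg per tow, not an areal density).  The forest uses the
published configuration — 1000 trees, 2 candidate variables per split —
with the minimum terminal-node size left at the implementation's
regression default (1) and echoed into the run report.  Validation is
10-fold CV repeated 10 times; R² is computed per held-out fold and
summarised as mean ± SD over the 100 folds, each fold's forest seeded
deterministically from the config seed.  Tests and the bundled examples
use smaller forests (≤ 100 trees) and fewer repeats purely as a
problem-size choice; the statistical behaviour they verify (signal vs
noise separation, recovery of a known field) is insensitive to forest
size at these data sizes.

Predictions are masked outside 50–2000 m, the reported bathymetric
envelope of the sponges.  Nonnegativity needs no clamping: a forest
averaging nonnegative responses predicts nonnegative values.

## Footprint reconstruction

The fishing filter is strictly `speed < 6 kn`; a ping at exactly 6.0 kn is
steaming.  Runs of ≥ 2 consecutive fishing pings become tracks.  With an
explicit `max_gap`, a run breaks when the inter-ping time strictly exceeds
it; by default the nominal cadence is inferred per vessel (smallest
positive inter-ping interval) and a run breaks once the gap reaches twice
that cadence — i.e. whenever at least one intervening ping (an excluded
steaming ping, or a transmission gap) is missing.  Tracks are not split at
division boundaries.

Swaths buffer the track polyline by half the 100-m wingspread with flat
end caps, so a straight track of length L sweeps exactly L × 0.1 km²
(rounded caps are available by flag).  The footprint is the swath union,
optionally clipped to a region — "trawled at least once", with no
cumulative-effort accounting, matching the assessment convention.

## Removal accounting and closure simulation

Per cell piece (cell ∩ stratum), removal = full-cell biomass ×
(trawled area / cell area) × removal rate (default 1.0, the worst case).
This makes removal linear in both the rate and the biomass, and bounded by
the standing stock, with equality exactly at complete coverage — the
conservation properties the tests assert.

Simulated closure trawling allocates the n = 30 sets to closures in
proportion to closure area (largest-remainder rounding), since the
original allocation is unstated.  Each set starts at a uniform random
point in its closure and walks 1-km steps along the local isobath
(heading perpendicular to the depth gradient, sense kept between steps,
Gaussian jitter SD 0.15 rad), for 18 nm — or 7 and 8 nm in the two
smallest closures.  Placement is rejection-sampled (up to 200 attempts)
so swaths never overlap, encoding the non-overlapping-fishing assumption;
a path that cannot reach its target length inside the closure is accepted
shortened, with a warning.  Per-set removal applies the standard overlay
to the set's swath.  The summary SD is the sample SD (ddof = 1).

Trawls-to-depletion is ⌈stock / mean removal per set⌉ — a ceiling, because
eliminating the entire stock requires covering the final partial set.
Removal percentages always take an explicit reference biomass: the
published percentages mix denominators (footprint total vs study-area
total), so the package refuses to guess one.

## Function upscaling

All conversions are exact unit arithmetic; the key constant is
1 t WW → 245.76 g O₂ day⁻¹ at the mean respiration rate.  Two conventions
deserve note:

* The 0.70 activity factor applies to pumping-derived quantities only
  (filtration and the nitrogen fluxes carried by the filtered volume),
  never to respiration — the only assignment consistent with both
  published headline figures deriving from one biomass total.
* The C:O ratio "0.9 : 1.0" is a mass ratio applied as
  C tonnage = O₂ tonnage / 0.9.  Molar readings do not reproduce the
  published carbon figures and are rejected.

Molar masses are standard 4-significant-figure values.  The published
NO₂⁻ tonnages back-imply ≈ 45.0 g mol⁻¹; the standard 46.01 is used, a
documented ~1.7% difference.  SDs of filtration, respiration and carbon
propagate the single rate SD linearly (exactly reproducing the published
±SDs); nitrogen SDs default to quadrature of the filtration and
concentration relative errors, with single-source modes available, because
the published nitrogen SDs match no standard propagation and the original
method is unrecoverable.

Summary tables are computed both ways: full precision with a direct Total
row (exact by linearity), or display-rounded per region with the Total as
the sum of rounded rows — the published table's convention, which can
differ from the direct total in the last digit (e.g. carbon 63.11 vs
63.12).

## Economic valuation

Inflation adjustment is compound, `v × (1 + r)ⁿ` — the only reading
consistent with all three published adjusted yearly values at the printed
2-decimal rates (reproduced to within 0.05%).  The plant operating cost is
held as a 3-year total (USD 5.4 M), the only reading consistent with the
published USD 187 M (= 182 + 5.4, rounded to the million).

Replacement cost charges one plant when the loss-to-flow ratio is within
(0.5, 1.5] — the "substantially equivalent" convention — and otherwise the
nearest integer number of plants (minimum one for any positive loss);
zero loss costs nothing.  Nearest-integer scaling keeps the valuation
continuous with the one-plant band and monotone in the loss.  No
discounting or price forecasting is applied, and only the filtration
service is monetized.

## Known limitations

* Sediment-plume mortality is not modelled (no basis to quantify it).
* No cumulative multi-pass depletion dynamics; the footprint is binary.
* The physiological proxy is a single species (*G. barretti*) applied to
  the whole assemblage; no temperature or seasonal dependence.
* The synthetic world omits stratified survey design, gear selectivity
  < 100%, VMS positional error and speed-class overlap; conclusions from
  passing tests are about estimator correctness, not survey realism.
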