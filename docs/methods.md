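# Methods

## The accounting model

The unit of analysis is one protected area (PA) with a recorded (vector) GIS
area `A` and a stack of co-registered rasters: categorical land cover
(classes 1–8 = forest, 20 = non-forest), AGB and BGB (Mg dry mass ha⁻¹), and
a binary forest-loss grid for a 12-year window. All layers share one planar
equal-area frame; reprojection and datum handling are out of scope.

Per PA:

| quantity | definition | notes |
|---|---|---|
| forest area `A_f` | forest-class pixel area inside the PA | centre-point zonal rule |
| forest fraction `f` | `min(A_f / A, 1)` | capped so `m = 1/f ≥ 1` |
| multiplier `m` | `1/f` (or 1 in uncorrected mode) | `≤ 2` under the 50 % filter |
| stock `C` | `A_f (AGB̄ + BGB̄) × 0.5` Mg C | carbon = 50 % of biomass |
| raw loss `p_raw` | loss area / `A` | see "loss denominator" below |
| corrected loss `p` | `min(m · p_raw, 1)` | a PA cannot lose > its forest |
| loss `L` | `C · p`; annual `L/12` | linear annualisation, no compounding |

The loss correction exists because the biomass and land-cover grids are ~30×
coarser than the loss grid: stocks and losses are both assumed concentrated
in the forested portion of a partially forested PA, so a whole-PA loss
fraction understates the fraction of *forest* lost by exactly the factor
`1/f`. Corrected losses therefore always dominate uncorrected ones, with
equality iff `f = 1` or `p_raw = 0`.

**Errors.** The budget is additive, not quadrature — a deliberate
conservative choice that keeps absolute errors linear in the stocks:
AGB-carbon error = (0.439 + 0.05)·AGB-C, BGB-carbon error = (0.21 + 0.05)·BGB-C,
stock error = their sum; loss errors inherit the stock's relative error. The
0.439/0.21 are the maxima of the biomass map's published relative-error
layers; 0.05 is the land-cover misclassification allowance. CO₂ figures use
the molar ratio 44/12.

**Inclusion rules**, applied in order with the first failing rule recorded:
GIS area ≥ 10 km² (inclusive — the smallest admissible PA is exactly
10 km²); ≥ 10 one-km²-equivalents of forest pixels; forest fraction ≥ 0.5.
"Proposed" PAs are included by default, with a flag to exclude them.

## Statistical layer

Gross emissions scale with starting forest area, so disproportionate
emitters are defined against an OLS fit of log₁₀(annual emissions) on
log₁₀(forest area in km², both base-10). Outliers are **internally
studentised** residuals `e_i / (s √(1−h_i))` strictly beyond ±2; external
(leave-one-out) studentisation is available as an option. Zero-emission PAs
cannot enter a log regression and are excluded and counted rather than
patched in with an offset, which would bend the slope. The flags are
invariant to annual vs whole-window emissions (the ×12 only shifts the
intercept).

Quartiles use linear (type-7) interpolation; box-plot whiskers are the
furthest points within 1.5 IQR of the quartiles. Country aggregates report
total stock, total/annual loss, and proportional loss of protected carbon
(country loss ÷ country stock). Concentration sorts PAs by descending
emissions (stable under ties) and returns the shortest prefix reaching the
target share.

## Geometric core

Zonal statistics use a centre-point membership rule: a pixel is in a zone
iff its centre lies inside the polygon. A centre exactly on the outline is
resolved half-open — in on bottom/left edges, out on top/right — so zonal
sums are additive across polygons tiling a region. This rule was chosen over
area-weighted clipping because it is exactly checkable against a per-pixel
brute-force loop, and additivity makes cohort totals independent of how PAs
are grouped. Nearest-neighbour resampling never alters values; aggregation
of the binary loss grid to per-pixel loss fractions conserves mass exactly
when the dimensions divide (zero-padding otherwise, flagged in metadata).
No-data pixels never contribute to a statistic; an empty zone reports an
undefined mean, never 0.

**Working resolution.** All zonal extraction happens at 250 m: an integer
divisor of the 1 km grid (each coarse cell tiles into 4×4 working cells, so
resampling is lossless) and an integer multiple of the ~31 m loss grid (so
area-averaging needs no padding). This balances polygon-edge quantisation
against memory/time, the same compromise operational analyses make with a
300 m grid; it is configurable wherever it appears.

**Loss denominator.** The raw loss proportion divides loss area by the
*recorded GIS area* rather than by the zonal pixel-count area. The two
differ only by edge quantisation, but this reading makes the corrected
proportion equal loss area / forest area exactly — the quantity the
correction is meant to produce — and removes one discretisation term from
the error budget.

## Synthetic landscapes and what passing tests show

The generator emulates the statistical structure the analysis assumes, not
real geography. Defaults (the study conditions for tests and acceptance):
240 × 240 km scene, 1 km coarse pixels subdivided 32× (~31 m loss pixels),
100 PAs of 10–600 km² (log-uniform), forest fractions 55–100 %, AGB ~
N(250, 75²) Mg ha⁻¹ truncated at 10, BGB = 0.28 · AGB (a fixed root:shoot
ratio standing in for a separate BGB map), background forest on 20 % of
non-PA cells, 12-year loss proportions Beta-distributed with mean 2 %
(≈ 0.17 % yr⁻¹, the observed regime for tropical PAs) and concentration 100,
and five injected outlier PAs whose Beta mean is multiplied by 20. Scaling
the *mean* (rather than multiplying a random draw by 20) makes the injection
strength the multiplier itself; injection targets PAs meeting the inclusion
rules, since the scene's purpose is to plant detectable outliers in the
analysed cohort.

PA polygons are axis-aligned rectangles snapped to the fine grid, placed
non-overlapping with a one-coarse-cell margin. Snapping makes every
geometric quantity exact in integer fine-cell units: recorded GIS areas,
per-cell overlaps, forest areas, and loss areas are computed from the
construction itself (forest is assigned coarse-cell-wise, interior cells
first, accumulating exact overlap until the target fraction; loss cells are
drawn without replacement from the PA's forest fine cells). The truth table
is therefore analytic and never touches the pipeline under test.

What the scenes do **not** emulate: spatial autocorrelation of biomass,
irregular PA shapes, cloud/no-data gaps, geographic coordinates, raster–
vector misregistration beyond edge quantisation. Passing recovery tests
shows the pipeline's geometry and arithmetic are correct under the stated
sampling rules; it does not validate the global datasets or the 50 %-biomass
and fixed root:shoot assumptions against field data.

**Recovery tolerance (a-priori).** Sampling a w × l rectangle by the centre
rule on a grid of pixel h quantises each edge within h/2, bounding the zone
area error by h(w+l); relative to the forest area (≥ wl/2 under the
fraction filter) that is ≤ 2h(w+l)/(wl). Stocks are held within that bound
and carbon losses within twice it (they compound stock and loss-area
quantisation). The bounds depend only on PA geometry and were fixed from
this derivation, not fitted to observed errors; acceptance requires ≥ 95 %
of PAs within them, plus ≥ 90 % sensitivity to the injected outliers with
≤ 4 % false flags.

## Numerical conventions and degenerate inputs

- Boundary ties in zonal membership: resolved by a +ε nudge (10⁻⁹ pixel)
  toward the upper right, realising the half-open rule for any polygon.
- A perfect regression fit studentises to exactly zero (SSE below a
  scale-relative 10⁻¹² threshold is treated as zero); leverage-1 points are
  undefined and returned as NaN.
- Strict inequalities at the ±2σ threshold; a residual of exactly 2 is not
  flagged.
- Forest fractions > 1 (raster overshoot of the vector area) cap at 1 with
  the multiplier floored at 1; corrected loss proportions cap at 1.
- Infeasible PA packing raises an explicit error naming the constraint, as
  do non-binary loss grids, misaligned working pixels, non-co-registered
  layers, and invalid geometries.

## Problem sizes

Tests run on 60–80 km scenes with 8–12 PAs (subdivision 8); the recovery
acceptance test and the acceptance script use the full default scene
(100 PAs, 7680² fine cells), which generates and analyses in a few seconds
on one CPU. These sizes were chosen as the smallest cohorts where the
regression and concentration behaviour is stable across seeds.

## Known limitations

Soil carbon is excluded (loss timing too uncertain), so emission totals are
underestimates by design. Gross losses only — no regrowth netting, no
committed-vs-instant flux timing. The centre-point rule makes per-PA values
for very small PAs (near the 10 km² threshold) sensitive to the working
resolution; the inclusion filters exist precisely to keep that error
bounded. Internal studentisation partly masks outliers when they are a
large fraction of a small cohort (they inflate the residual SD); at the
default 5 % contamination this effect is negligible.
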