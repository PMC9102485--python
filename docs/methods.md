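# Methods

## The measurement model

An overhead, fronto-parallel stereo pair observes a tray at working distance
`z` (mm). The world frame sits at the left camera's optical center (x right,
y down, z toward the scene); pixels are 0-based `(column, row)`. On a
rectified rig a scene point at depth `z` appears in both rows equally and
its columns differ by the disparity

    d = f_px · b / z      [px],   f_px = f_mm / pixel_size_mm,

so depth is recovered as `z = b·f_px/d` and the lateral coordinates follow by
similar triangles, `x = (c − c_x)·z/f_px`, `y = (r − c_y)·z/f_px`. Disparity
is signed `d = x_left − x_right ≥ 0`; non-positive disparities are invalid.

Differentiating the triangulation gives the design formula

    Δz = z² · Δd / (f · b)

for the smallest resolvable depth change when disparity is known to `Δd`
(mm on the sensor). With subpixel matching, `Δd` is conventionally one
fifth of the physical pixel; for the reference design (f = 3.38 mm, 1.4 µm
pixels, b = 152.4 mm, z = 1524 mm) this yields 1.26 mm, and the tests check
that the formula agrees with a finite difference of the triangulation to
first order.

## Matching

The matcher is semi-global matching with a census cost. The census
transform encodes, per pixel, which neighbors in an odd window (default
5×5) are darker than the center; matching cost is the Hamming distance
between left and right codes. Census depends only on local intensity
*order*, so it tolerates exposure and illumination differences between the
two eyes — relevant for hardware that does not expose both cameras at the
same instant. A mutual-information cost would serve the same role; census
is the standard radiometrically robust choice and is what this package
implements.

Aggregation sums 1-D minimum-cost paths from 8 (or 4) directions:

    L_r(p,d) = C(p,d) + min(L_r(p−r,d), L_r(p−r,d±1)+P1, min_k L_r(p−r,k)+P2)
               − min_k L_r(p−r,k)

The trailing subtraction is the standard normalization bounding path-cost
growth; it shifts all disparities of a pixel by the same constant (exactly
`min_k DP(p−r,k)` of the unnormalized program, which the tests verify) and
never changes the winner. `aggregate_paths(..., normalize=False)` exposes
the raw recursion, which equals exhaustive enumeration over disparity
sequences — the oracle the test suite checks against on small volumes.

Defaults: census window 5; 8 paths; P1 = 10, P2 = 120 (scaled to the 0–24
range of a 5×5 census cost); ties break to the smallest disparity; subpixel
refinement fits a parabola through the aggregated costs at the winner and
its neighbors (skipped at range ends, offset clamped to ±0.5 px). The
search range is derived from the rig and a depth band around the tray,
default [tray − 300 mm, tray + 50 mm], unless overridden. None of these
values is dictated by the measurement model; all are exposed in `SGMParams`.

Left-right consistency: a right-referenced disparity map is computed from
the re-indexed cost volume (`C_R(r,c,d) = C_L(r,c+d,d)`), and a left pixel
survives iff the right map at its match agrees within `cross_check_tol`
(default 1 px). This removes occlusions and gross mismatches, but not
"foreground fattening": near a depth step the matching window drags the
foreground disparity a couple of pixels over the occluded background, and
those pixels are self-consistent. The tests therefore check that occluded
bands fail the check at several times the rate of visible pixels, not that
they vanish entirely.

## Refinement

Holes (failed consistency, low texture) are filled by normalized Gaussian
convolution: an invalid pixel becomes the Gaussian-weighted mean of the
valid pixels in its kernel support, iterated (default ≤ 10 passes, σ = 2 px,
radius 4 px) until nothing reachable remains. Measured pixels are never
altered — where a plain convolution reading would smooth them too, the
`smooth_all` switch provides that behavior, but preserving measured data is
the default because filling is meant to interpolate, not to re-estimate.
Filled values are convex combinations of valid neighbors, so the output
range cannot exceed the input range. A 5×5 median filter then removes
speckle; filling precedes smoothing.

## Volume integration

The tray is the height reference. Its plane is fit to tray-mask points by
total least squares; the robust default runs a small consensus search
(random minimal triples, inlier threshold 2 mm ≈ 2× the design depth
resolution at 1524 mm, 50 iterations, seeded) and re-fits on the winning
inlier set. Food-pixel heights are point-to-plane distances clamped at zero
— the flat-bottom assumption; concave-bottomed objects will be
overestimated. Volume is `Σ A_voxel · h_vbar`.

Two footprint conventions:

* **fixed** — `A_voxel = (lateral resolution)²` with a configured
  resolution (default 0.55 mm/px), the deployed-device convention that
  assumes one resolution at all depths;
* **metric** (default) — `A_voxel = (z/f_px)²`, the physical
  back-projection of one pixel. The pipeline evaluates it at the mean depth
  of the food-surface points rather than the tray depth: a raised surface
  covers more pixels than its tray-depth footprint suggests, and for a flat
  top the mean-depth choice makes pixel count × footprint reproduce the
  physical area exactly (tray-depth evaluation carries a (z_tray/z_top)²
  bias, ≈ +4% for a 30 mm object at 1524 mm).

## The simulator

The simulator emulates what the capture hardware provides, not how it looks:
parametric shapes of known volume on a fronto-parallel tray plane, a random
dot texture (Poisson-count Gaussian dots, seeded), and a rectified pair in
which the right image is, by construction, the left texture sampled at the
ground-truth corresponding coordinate. Surface depths are found by marching
each pixel ray through the solid `tray ≥ z ≥ tray − h(x,y)` (0.5 mm steps,
14 bisection refinements), which handles vertical side walls exactly.
Occlusions are flagged by left-right ground-truth disparity disagreement.
Optional additive Gaussian intensity noise is drawn independently per eye
(emulating non-simultaneous exposure), and an off-by-default specular-spot
option injects saturated blobs, the failure mode bright table reflections
cause.

The default simulation rig keeps the reference baseline (152.4 mm) and
tray distance (1524 mm) but uses f_px = 1600 (f = 8 mm, 5 µm pixels) so the
tray sits at exactly 160 px disparity and two-thirds of a 480-px frame
overlaps; the reference sensor's f_px ≈ 2414 would leave almost no stereo
overlap at desk-scale frame sizes. Scenes place objects near x = +76 mm,
the center of the stereo overlap. Default study conditions: 480×360 frames,
dot density 50 per 1000 px², dot σ = 1 px, background 60/255, noise σ ∈
{0, 2}.

What the simulator does **not** model: photometric realism (shading,
shadows, specular food surfaces), lens blur and vignetting, IR radiometry,
calibration error, or real segmentation noise (masks are exact). Passing
the end-to-end tests therefore demonstrates that the *reconstruction and
integration chain* is correct and meets its error budget under controlled
texture and noise — not that a physical device achieves the same accuracy
on real food.

## Validation tables

Two packaged CSVs transcribe the per-trial predicted volumes of a five-food
plastic-replica study (banana, chocolate brownie, chickpeas, French fries,
popcorn; ground truth by water displacement): one for a structured-light
stereo rig (12 trials per food, 8 for the brownie), one for a
time-of-flight comparison camera (12 per food). Summaries use the
population SD (divisor n), which reproduces the published ±5.33 mL for the
stereo chickpeas row (divisor n−1 would give 5.57); per-food percent error
is computed from the mean volume, whose printed ± equals SD/GT×100,
confirming the convention. Aggregation reproduces the published 5.60%
(stereo) and 16.62% (time-of-flight) across-food MAEs. A handful of printed
summary cells in the time-of-flight table are internally inconsistent with
their own per-trial cells at print precision (popcorn mean by 0.01, the
French-fries mean by 0.10, banana mean by 0.04, chickpeas error SD by
0.07); in each case the error columns are consistent with the cells, the
cells are treated as authoritative, and the affected assertions carry
correspondingly widened tolerances. The source also states a 5.40% MAE for
the stereo device in prose while its own table footer and conclusion give
5.60%, which is what the cells yield; 5.60 is used.

## Problem sizes and determinism

End-to-end studies run at 480×360 with a ~47-level disparity search —
about 15–30 s per scene on one core, so the full acceptance script (six
pipeline runs plus two texture runs) completes in a few minutes. All
randomness — dot placement, noise draws, heightfield seeds, consensus plane
fitting — flows from explicit integer seeds; identical configuration and
seed give byte-identical outputs.

## Known limitations

* Foreground fattening at depth steps (see Matching) biases slab-like
  objects slightly; with hole filling it contributes most of the residual
  −4…−7% volume error on sharp-edged shapes.
* The flat-bottom assumption overestimates concave-bottomed objects.
* Rectification assumes a pure relative rotation (plane-induced homography
  pair) and even radial distortion; tangential distortion, rolling shutter
  and self-calibration are out of scope — rigs are consumed pre-calibrated.
* The fixed-footprint mode inherits the single-depth resolution assumption;
  it is provided for comparability, the metric mode for correctness.
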