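# Methods

This note records the model, the coordinate conventions, the numerical
choices and the known limitations of `eyespot`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from elsewhere.

## Eye model and frames

The eye is a triaxial ellipsoid with semi-axes (r_x, r_y, r_z) in a
single length unit (image pixels in a session; the synthetic generator
samples micrometres and converts at a stated pixel size). The retina is
the part of the surface below a circular **rim**. Two equivalent rim
conventions are used, converted at exactly one place
(`EyeModel.phi0_deg`):

* `rim_opening_deg` — the user-facing angle between the optical axis and
  the rim (default 53°, typical of an early-postnatal mouse eye);
* `phi0` — the rim colatitude measured from the deepest point,
  `phi0 = 180° − rim_opening_deg` (127° by default).

All angular bookkeeping happens on the **normalized unit sphere**:
coordinates divided componentwise by the semi-axes and rescaled to unit
length. The deepest point of the cup is (0, 0, −1); the opening faces
+z; the rim circle is at z = −cos φ0. The nasal pole of the NT axis is
placed at +x on the rim — which world direction is nasal is carried
entirely by the view transforms, so this is a pure internal convention.
Whether wedge coordinates should be computed on the ellipsoid itself or
on the normalized sphere is a genuinely open design point; the normalized
sphere was chosen because the wedge construction assumes a sphere, and
the ellipsoids of interest are nearly spherical (±5%).

## View transforms and back-projection

A camera is a rigid map b = R a + t with R = R_x R_y R_z (z-rotation
applied first). Camera x/y are the image axes and the viewing direction
is −z, so the viewer sits at large positive camera z. Image pixel
coordinates have y pointing down; the y sign is flipped at the single
conversion point where marks enter the geometry (`back_project`, and its
mirror image in the renderer), keeping the eye frame right-handed.

Under orthographic projection a mark (x, y) constrains the injection to
the segment between T⁻¹(x, y, t_z + r_max) and T⁻¹(x, y, t_z − r_max),
which is guaranteed to span the ellipsoid. Two marks give two segments;
the injection estimate is the midpoint of their mutual perpendicular,
with the closest-approach distance reported as `ray_gap` (an alignment
diagnostic: zero for perfectly consistent marks). Views subtending less
than 5° are rejected as near-parallel — below that the second view adds
no usable depth. The triangulated point is snapped to the ellipsoid
surface by radial rescaling on the normalized sphere; injections live on
the retina, and snapping makes the output independent of the residual
depth error. If the snapped point lands above the rim it is flagged
(`above_rim`), and the NT/DV fractions are evaluated at the rim point
with the same azimuth, since wedge coordinates are undefined above the
rim.

## Wedge coordinates

For an axis with poles P± = (±sin φ0, 0, −cos φ0) (NT as stored; DV
after rotating the point by −90° about the optical axis), the plane
through both poles tilted ψ ∈ [−90°, 90°] from vertical cuts the unit
sphere in a circle of radius ρ = √(sin²φ0 + cos²φ0 cos²ψ) centred at
(0, y0, z0) with y0 = −sin ψ cos ψ cos φ0, z0 = −sin²ψ cos φ0. With the
angular parameter α measured so that α0 = arcsin(sin φ0 / ρ) at the
first pole, the arc through the deep side of the eye spans 2π − 2α0
(always less than a full turn), and the forward map is

    x = ρ sin α,   y = y0 − ρ sin ψ cos α,   z = z0 + ρ cos ψ cos α,
    α = α0 + f (2π − 2α0).

The inverse recovers ψ = atan2(y, −cos φ0 − z), then α = atan2(x, v)
with v = −(y − y0) sin ψ + (z − z0) cos ψ, wrapping α by +2π when
negative, and f = (α − α0)/(2π − 2α0). Standard two-argument atan2 with
range (−π, π] is used throughout. f = 0 and f = 1 are the two poles for
every ψ; (ψ = 0, f = 0.5) is the deepest point. The only points where
ψ is undefined are the two poles themselves; they are reported with
ψ = 0, f ∈ {0, 1} and a degeneracy flag. These formulas were fixed
against an independent construction (intersect the tilted pole plane
with the sphere and walk the arc directly); the forward/inverse pair
round-trips to better than 1e-8 over the whole parameter box, which the
test suite checks on 10⁴ random inputs.

For right eyes the DV fraction is mirrored, f_DV → 1 − f_DV; the NT
fraction is unchanged.

## Line–ellipsoid intersection

Projecting a pixel onto the surface scores points p on its
back-projected segment by the residual v = |x²/r_x² + y²/r_y² + z²/r_z² − 1|.
Two modes agree to within the sampling resolution (verified on 500
random rays at 2000 samples):

* **sampled** (default, 2000 points): the *first local minimum* of the
  sampled v sequence is taken. A segment crossing the ellipsoid has
  near-zero v at both crossings; the first local minimum selects the
  viewer-side crossing, whereas a plain global argmin would let
  floating-point noise pick either side.
* **exact**: the quadratic in the segment parameter is solved and the
  root nearest the viewer taken, falling back to the continuous
  minimum-v point when the ray misses.

Rays whose best residual exceeds v = 0.05 are dropped (with a count
reported): such pixels lie off the eye. The tolerance accepts pixels
within ~2.5% of a radius outside the silhouette, which is the intended
reading of "nearest surface point" for boundary pixels.

## Area estimation

The injection's extent is segmented by colour: the image is converted to
CIELAB (D65 white point — the original colour profile of any given
camera is unknowable, and D65 is the standard assumption), the lightness
channel is discarded so that shading across the curved eye does not
split the mask, and pixels within a chroma distance (default threshold
5) of the seed pixel are kept. Only the connected component containing
the seed survives, so disjoint debris of similar colour cannot inflate
the area.

Masked pixels are projected to the surface (above), normalized to the
unit sphere, and flattened by a **Lambert azimuthal equal-area
projection** centred on their spherical centroid, scaled by the
geometric-mean radius (r_x r_y r_z)^{1/3}. Equal-area projection makes
planar area equal spherical area exactly for regions; the planar
**alpha-shape** area (Delaunay triangles kept when their circumradius is
at most α, with α = 10× the median nearest-neighbour spacing, convex
hull as fallback for degenerate shapes) then measures the patch,
following concave outlines without hand-tuning. The fraction divides by
the retinal surface area — the rim-curtailed ellipsoid, since injection
sizes are biologically referenced to the retina; the full ellipsoid is
available as an option. No closed form exists for a curtailed triaxial
ellipsoid's area, so it is computed by 256-point tensor Gauss–Legendre
quadrature (relative error below 1e-8 against an independent adaptive
integrator; exact closed forms for spheres are matched to 1e-6).

Accuracy: a rendered 10°-half-angle cap on a spherical eye is recovered
within ~2% of the closed-form fraction (1 − cos 10°)/(1 − cos 127°); the
dominant error is pixel quantization at the mask boundary, which shrinks
with image resolution. Projected geodesic polygons up to 30° angular
radius keep their Girard-excess area to ~0.03% through the projection;
alpha-shape carving of extremely elongated boundary slivers can cost up
to ~1% more.

## Synthetic data generator

The generator reproduces the study conditions under which the method is
validated:

| quantity | law | default |
|---|---|---|
| semi-axes | Normal(1400, 70) µm, truncated > 0 | per eye |
| rim opening | Normal(53°, 3°), clamped to (10°, 85°) | per eye |
| camera x/y tilts | Normal(0°, 9°) truncated at ±20° | per view |
| camera z-spin | Uniform[0°, 360°) | per view |
| side camera | independent tilt draw ∘ 90° about eye x ∘ top pose | — |
| injection centre | area-uniform on the sub-rim cap | per scene |
| injection points | 100, isotropic 6° tangent-plane Normal, exponential map | per scene |
| above-rim points | discarded | — |
| pixel size | 10 µm/px, 360×360 px rasters | config |

Two deliberate interpretations: (1) the centre is sampled
**area-uniformly below the rim** rather than uniformly in spherical
angles — angle-uniform sampling is pole-heavy and can place the centre
above the rim where no ground-truth fractions exist; the angle-uniform
scheme remains available as `legacy_angles=True` (redrawn until the
centre is at or below the rim). (2) the 6° scatter is an isotropic
normal in the tangent plane pushed through the exponential map, because
a "normal distribution in spherical coordinates" is ill-defined near the
poles.

**Visibility.** The eye is rendered as an opaque *cup*: there is no
surface above the rim. A surface point is visible in a view when it is
the viewer-side intersection of its own pixel ray (front face) or when
that ray enters through the opening (front intersection above the rim)
and the point is the interior back wall — this is how the optic disc at
the bottom of the cup appears in a top view. Scenes where no injection
point is visible in one of the views are skipped (and counted) by the
validation loop; with the default laws roughly a quarter of scenes are
skipped.

Rendering (orthographic ray-casting of the cup, rim circle, two cardinal
wire-frame meridians, an "M" glyph at the nasal rim point, and one
claret dot per visible injection point) is deterministic given the seed;
only the geometry is contractual, the palette is configuration.
Automatic marking places each view's mark at the projected centroid of
the *visible* injection points, standing in for a human observer;
partial occlusion therefore biases marks slightly, which is part of the
protocol being validated, and rendered-dye-pixel centroids track these
geometric marks to within ~1.5 px (rasterization only).

## Validation protocol and what it shows

`validate_scenes(n, seed)` generates scenes until `n` have the injection
visible in both views, auto-marks, localizes with the *true* view
transforms and eye, and reports Pearson r and RMSE between estimated and
true NT/DV fractions. At n = 150 the automated pipeline reaches
r ≈ 0.999 on both axes with RMSE below 0.01 — this isolates the
geometric machinery (back-projection, triangulation, snapping, wedge
inversion) plus centroid/occlusion effects. It deliberately does **not**
exercise the two dominant error sources with real images: manual
wire-frame alignment and human mark placement. Synthetic images are
clean — no debris, depth-of-field blur, or deformation of the eye — so
passing validation bounds the algorithmic error, not the end-to-end
experimental error.

Problem sizes used throughout (150 scenes, 10⁴ round-trip samples, 500
rays, 360-px rasters) were chosen as the smallest that make the
statistics stable; all complete in seconds.

## Sessions and export

Sessions are versioned JSON (schema 1): eye, two views, optional marks
and results, image paths with SHA-256 checksums (images are referenced,
never embedded; a checksum mismatch warns, a schema violation names the
offending field). Composite images merge-split along the longer
dimension, which must be even; square composites need an explicit axis,
and the top view is the first pane unless overridden. The polar export
writes colatitude/azimuth/NT/DV/area to CSV (full float precision, so
re-reading reproduces the result) and a polar figure with the rim circle
at φ0 and the injection dot drawn to the equal-area angular radius of
its area fraction.

## Limitations

* One injection per eye: with several same-colour labels the two views
  cannot be put in correspondence (the stereo correspondence problem).
* Orthographic cameras only; perspective foreshortening at short working
  distances is not modelled.
* The wire-frame alignment is an input, not fitted automatically.
* Area estimation requires the whole injection visible in the chosen
  view and assumes the dye chroma is separable from tissue at a single
  threshold.
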