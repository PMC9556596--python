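# Methods

This note documents the models, conventions and numerical choices behind
`bordercell`, and what the synthetic test bed does and does not
establish about real microscopy data.

## Coordinate and unit conventions

Points are (x, y) pixel pairs, 0-based, x rightward, y downward; arrays
are indexed `[y, x]`.  Angles follow the same frame, so +90° points down
the image.  Velocities are stored in µm/min (conversion
px/frame × pixel size × 60 / frame interval), divergence in min⁻¹,
lengths in µm, areas in µm².  Calibration (pixel size, frame interval)
always travels with the pixel data; configuration values are
authoritative over TIFF tags, which are treated as advisory.

## Segmentation model

The decomposition assumes a single compact cluster that is brighter than
the background and whose peripheral cable is brighter than the bulk
cytoplasm.

1. **Group mask** — Otsu threshold, hole filling, largest connected
   component.  This replaces an interactively trained pixel classifier;
   it is appropriate whenever foreground and background are separable by
   a single global threshold, which holds for the synthetic fixtures and
   for well-exposed, background-subtracted reporter images.
2. **Protrusion / body split** — the body is the morphological opening
   of the group mask with a disk (default radius 2 µm); connected
   components of mask∖body with area ≥ 5 µm² become labelled
   protrusions, smaller residues are merged back.  The opening radius
   sets the narrowest neck that still counts as a protrusion; 2 µm
   matches the width of border-cell fingers at typical magnification.
   The curvature-tree edge filtration used in interactive tools is not
   reimplemented: the opening honours the same observable contract
   (protrusions vs main body) with one interpretable parameter.
3. **Cable tracing** — the body boundary polyline (marching-squares
   contour, rounded and snapped onto mask pixels, forced clockwise) is
   cut at the clicked cell-boundary landmarks (snap tolerance 3 px) into
   per-cell arcs.  Each rim vertex is scored by the mean of the frame
   over the vertex and the two pixels along the inward normal — a 3-px
   band reaching *into* the cable, because the segmented boundary sits
   at its outer edge.  Vertices at or above
   `cable_intensity_threshold × group-mean intensity` are cable, the
   rest broken; a circular 7-vertex majority vote removes speckle
   flicker shorter than ~3 px without moving longer run boundaries.
   The default threshold is **1.15 × group mean**: a bundled cable is
   consistently brighter than the whole-group mean (which averages dim
   cytoplasm with the bright periphery) while bare cortex at a broken
   section falls below it.  The intensity criterion for "cable" was
   never specified numerically in the protocol this reimplements, so
   this default is a design choice, exposed in the configuration.
4. **Contacts** — the brightest path between the two clicked endpoints:
   minimal accumulated cost 1/(1+I) restricted to the body, with
   geometric step weights so that on a flat field the path degenerates
   to the straight line; the path is dilated to a ribbon (default
   half-width 2 px).

## Morphometrics and classification

* Protrusion-area fraction f = A_prot/(A_body+A_prot); cable
  discontinuity d = Σ broken length / Σ all segment lengths; areas via
  pixel-size².
* Classification follows the printed inequality directions exactly:
  tight iff f < 0.10 and d ≤ 0.08; loose iff f > 0.25 and d ≥ 0.25;
  balanced iff 0.10 ≤ f ≤ 0.25 and 0.08 < d < 0.25.  The plane regions
  these bands leave uncovered (e.g. a compact group with a shattered
  cable) return `unclassified` rather than being forced into a nearest
  category.  Protrusion-count descriptors ("1–2 large protrusions") are
  reported but deliberately not used by the classifier; the quantitative
  definition rests on the two axes above.
* Migration speed uses the first and third time points: Euclidean
  distance of the group centre over 2 frame intervals, per minute.  A
  stride-1 sliding variant is provided for time-course plots.  The group
  centre is the intensity-weighted centroid of the background-subtracted
  frame inside the group mask dilated by 2 µm: intensity weighting keeps
  the estimate subpixel-accurate under slow drift (a binary-mask
  centroid quantizes at ~0.5 px), and the dilated-mask restriction stops
  far-field camera noise from diluting the centre.
* Relative region intensity divides each class mean by the same frame's
  whole-group mean.  The normalising denominator is a config-level
  choice (group mean was chosen so values stay comparable across
  bleach-corrected frames); summed intensities feed the
  cable/(cable+protrusion) periphery ratio.
* Photobleaching is modelled as a single exponential on frame means:
  least squares on log-means, each frame divided by its fitted relative
  decay.  A flat or brightening series is returned unchanged and
  flagged, never "corrected" upward.
* Front/middle/rear cell positions: centroids projected on the motion
  axis and split into terciles (front = highest third); with fewer than
  three cells the extremes are used.  No assignment rule was specified
  in the source protocol; terciles are the symmetric default.

## PIV actin-flow analysis

"Cross-correlation coefficient" is interpreted as the zero-normalized
(Pearson) correlation of patches — the only definition bounded in
[−1, 1] for which a 0.5 cutoff is meaningful.  Window areas in µm² are
converted to the nearest odd pixel side (side = round-to-odd(√area /
pixel size)); at 0.2 µm/px the defaults give a 5-px source inside a 7-px
search window.  The estimator grid uses one source-window side as stride
(the original grid spacing is not documented; this keeps estimates
non-overlapping), evaluates every integer shift of the source inside the
search window, and keeps the argmax coefficient if it exceeds c₀ = 0.5.
Ties are broken by smallest displacement magnitude, then lexicographic
(dy, dx), making the estimator fully deterministic.  Integer-pixel
argmax is the default so a literal brute-force oracle can match it
exactly; 3-point parabolic subpixel refinement is available behind a
flag.

Dense fields are normalized Gaussian-weighted averages of the kept
estimates (kernel truncated at the stated 6 µm size, circular support);
pixels farther than the kernel radius from every estimate are invalid,
and zero kept estimates produce an all-invalid field rather than an
error.  Temporal smoothing is a renormalized Gaussian over the frames
within half the 20 s kernel, excluding invalid samples.  Divergence uses
central differences and is defined only where a pixel and its four axis
neighbours are valid; for linear fields the scheme is exact, which the
tests exploit.  Retrograde/anterograde labels are the sign of
cos(flow, motion); exact zeros stay unclassified so the labelling is
antisymmetric under motion reversal.  Rose histograms are computed in a
frame where the protrusion axis maps to 90° (anterograde) and its
opposite to 270°.

The "strong flow" cutoff for occurrence statistics defaults to half the
95th-percentile in-mask speed of the movie and is recorded in the output
metadata — the source protocol names no number.  The divergence–myosin
association uses Spearman rank correlation between per-frame mean
negative divergence and mean second-channel intensity over the cable
mask; constant series are flagged undefined instead of returning 0.

## Synthetic data model

The generator emulates the acquisition geometry of the imaging protocol
(0.2 µm pixels, 10 s frame interval by default) with fully known truth:

* **Geometry.** n cell lobes (default 6) on a ring around the centre,
  union-of-disks body of radius 12 µm; capsule-shaped protrusions
  anchored at the rim; landmark points at the inter-lobe junction angles
  (mimicking the clockwise clicking protocol); straight contact lines
  from each junction to the centre; broken cable sections carved from
  per-cell rim arcs so the total gap length matches the requested
  fraction to within about a pixel step (gaps are placed away from
  protrusion bases, at most ~30 % of one arc per gap).
* **Appearance.** Per-region base intensities (body 150, cable 280,
  protrusion 220, contact 200, broken section = body level, background
  0 DN) multiplied by a frozen per-pixel log-normal speckle texture
  (σ = 0.18) that gives the cross-correlation tracker structure, as the
  endogenous granularity of an F-actin reporter does.  The intensity
  ladder was chosen so that one global Otsu threshold separates
  background from foreground while the cable cut (1.15 × group mean)
  separates cable from bare cortex with ≥ 2.5 σ speckle margin on both
  sides.  The cable band is painted by nearest-rim-vertex state and
  clipped to the body, so the rendered silhouette equals the geometric
  truth mask and intact/broken boundaries fall on perpendicular
  bisectors.
* **Dynamics.** Frame t+1 is frame t advected by the prescribed flow
  (backward bilinear warping; out-of-domain samples fall back to the
  base intensity) plus whole-group drift, scaled by exp(−Δt/τ) when
  bleaching is on, plus per-frame Gaussian noise clipped at zero.  Flow
  models: uniform translation, retrograde (anti-parallel to each
  protrusion axis), centripetal on the cable band, and the radial sink
  v(r) = −k·r whose divergence −2k anchors the analytic end-to-end
  tests.  All randomness flows through one `numpy` generator seeded from
  the spec; equal specs render bit-identical movies.
* **Fixtures.** The canonical suite holds tight (5 %/5 %), loose
  (30 %/30 %) and balanced (15 %/15 %) groups — protrusion lengths are
  solved by bisection against the rasterized truth so the area fraction
  lands on target — plus a pure-translation pair (3 px/frame), a sink
  movie (k = 0.5 min⁻¹) and a τ = 300 s bleaching stack.  Category
  fixtures drift at 0.5 µm/min with noise σ = 2 DN, three frames each —
  enough for the first-to-third-frame speed rule at desk-scale cost.

What passing on this test bed shows — and what it does not.  The
synthetic movies prove the *computations*: exact displacement recovery,
analytic divergence, partition invariants, threshold boundaries,
parameter recovery through the full segmentation chain.  They do not
contain out-of-focus light, a point-spread function, z-blur, uneven
illumination, cell-shape change, or texture decorrelation, so success
here does not guarantee segmentation accuracy on arbitrary real movies;
on real data the opening radius, cable threshold and background region
are the parameters to revisit first.

## Problem sizes

Tests and the acceptance script run on 160–320 px frames, 2–12 frame
movies, chosen as the smallest sizes at which every geometric tolerance
(≈ 2 px of rim out of a ≈ 380 px perimeter) is still meaningful.  The
classifier sweeps use 0.5 % steps over 1–40 %.

## Known limitations

* Cell identities exist only through the landmark ordering; there is no
  tracking beyond landmark re-use across frames.
* The cable tracer assumes one closed outer rim; clusters that split
  into multiple components are not handled.
* Bleach correction is uniform per frame (monoexponential on means); it
  cannot correct spatially varying bleaching.
* PIV is single-pass with non-deforming windows; strongly sheared flows
  are better served by multi-pass schemes.
* The semi-automatic landmark file replaces interactive clicking; no GUI
  is provided.
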