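# Methods

This note records the models, conventions, parameter choices and known
limitations of `sliceloc`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

The atlas frame is fixed: x left→right, y dorsal→ventral, z
anterior→posterior.  A slicing plane is parameterized by its AP position
`d_um` at an in-plane anchor (x_c, y_c) and two tilt angles, giving the
height function

    z(x, y) = d + tan(α)·(x − x_c) + tan(β)·(y − y_c).

Design choices where the convention was open:

* AP origin: plate 1 ↦ 0 μm, so plate labels convert to micrometers by
  ×100 and label errors read directly as μm.
* Angle signs: positive α tips the right hemisphere posterior; positive β
  tips the ventral side posterior.
* `d` is read as a z-coordinate at the anchor (not a distance along the
  tilted normal); the anchor defaults to the volume's x–y center.
* Fractional plate numbers are legal everywhere (regression labels are
  continuous); AP-group routing rounds half-up.

## Atlas handling

Label rasters are categorical, so every slice/warp of IDs uses
nearest-neighbor sampling; linear interpolation is reserved for grayscale
images and is rejected for integer rasters at the API level.  Out-of-volume
pixels map to background 0 (sections near the volume boundary are
routine).  The structure taxonomy is a single-rooted tree with
`level(child) = level(parent) + 1` and a hereditary fiber-tract flag;
aggregation to level L replaces each ID by its ancestor at L (0 when the
ID is shallower than L).  NIfTI-1 I/O goes through nibabel; NRRD through a
minimal built-in raw/gzip codec (the two paths are cross-checked in
tests).  Multiplane extraction fills disjoint per-component boxes from
per-component planes and leaves gaps as background.

The simplified atlas rendering encodes exactly the contrast a fluorescent
section shows — fiber tracts (gray, default RGB 128/128/128) against
generic tissue (green, 0/160/0) on black — so that mutual information
between a section and a rendering is meaningful.  Colors are configurable;
at most 3 distinct colors ever appear.

## Localization

The plane solver is closed-form weighted least squares of the quadrant
labels over the quadrant centers.  The geometric relation between Q labels
and (α, β, d) is exactly linear, so a learned mapping would only add
opacity; the `SectionPredictor` interface still admits one.  With two
valid quadrants (one cerebrum) only (β, d) are identifiable and α is fixed
at 0; one quadrant fixes d alone.  Posterior (group C) sections get
per-cerebrum (β, d) fits with α = 0, and a d-only brainstem fit whose β is
inherited from the cerebrum average.

Component detection for posterior sections thresholds the image, removes
small components (default floor: 1 % of the foreground) and classifies by
centroid geometry: the brainstem is the most ventral component near the
midline (within 25 % of the foreground width); remaining components sort
left/right.  A single component spanning the midline is reported as "no
detachment".  Quadrant numbering is Q1/Q2 dorsal left/right, Q3/Q4 ventral
left/right, Q5 brainstem, and quadrant centers are geometric box centers
(deterministic, simulator-friendly).

### Brute-force plane search

The deterministic stand-in for learned predictors scores candidate planes
by the Studholme normalized mutual information (NMI = (H_A + H_B)/H_AB,
24 bins) between the section (masked, resized to 160²) and the simplified
rendering of the atlas slice at the candidate plane, processed through the
identical canvas-and-resize path.  The search is coarse-to-fine: d in
500 μm steps over the volume AP extent and angles in 2.5° steps over
±10°, then 100 μm / 1° fine sweeps around a shortlist of coarse
candidates.  Because the NMI landscape has near-tied basins both along AP
and in the angles, the shortlist is the union of (a) the best coarse
entries that differ pairwise by more than one coarse step in d or an
angle and (b) the best angle pair at each of the strongest coarse d
values (8 of each before deduplication).  Ties break deterministically
toward smaller d, then α, then β.

A final sub-grid stage runs two rounds of per-axis parabolic peak
interpolation in which each axis profile is averaged over the neighboring
grid values of the nuisance coordinates; this marginalization suppresses
the score noise injected by staining bias and residual deformation, which
otherwise flips the argmax to an adjacent grid point.  The search is a
pure function of its inputs.

The group-A baseline segmenter transfers bulb-layer classes from the
atlas slice at the predicted plane, assigning each foreground pixel the
class of the nearest labeled template pixel.

## Registration

The automatic stage re-implements the *contract* of an MI-driven
deformable registration, not a diffeomorphic method: a centered similarity
transform (translation, rotation, isotropic log-scale) found by Powell
search on mutual information at 1/4 resolution, followed by demons-style
dense refinement over a 3-level pyramid (factors 4/2/1, iterations
30/40/60, update smoothing σ = 2 px, field smoothing σ = 1 px, step
0.5 px).  Two structural points matter:

* The dense field is the residual on top of the similarity-resampled
  source, composed analytically afterwards — regularizing a field that
  contains the global pose ramp corrupts it at the image borders.
* The pair is multimodal (3-level rendering vs many-level histology), so
  each iteration projects the section into the atlas contrast space by
  replacing each target-intensity bin with the mean warped-source
  intensity it overlaps, and the demons force is computed on that
  monomodal pair.

If the dense stage fails to beat the similarity stage by MI (tolerance
0.02 bits), the similarity field is returned with `converged: False` in
the history — never silently.

Landmark refinement triangulates the section-side landmarks (Delaunay);
each triangle's warp is the exact affine through its three vertex pairs,
with the destination→source solve driving resampling and out-of-hull
pixels mapped by identity.  Zero-area sliver triangles (grid-aligned
contour points are often exactly collinear) carry no pixels and map by
identity rather than through an ill-posed solve.  The 20 automatic contour
landmarks are equally spaced by arc length from a canonical start
(topmost-then-leftmost, clockwise); the two contours are paired by
arc-length index after choosing the cyclic shift minimizing total pair
distance — pairing from the raw canonical start alone proved brittle when
the start lands on different contour features of the two masks.  Contours
are taken on an any-tissue mask (small intensity floor, largest component,
holes filled) rather than the Otsu mask, which notches out dark fiber
structures.

## Synthetic world

The phantom is a deterministic arrangement of ellipsoidal solids spanning
the full 132-plate AP range at 50 μm voxels (160×128×264), mirror
symmetric about the mid-sagittal plane under a left↔right label swap map:
an anterior olfactory bulb with concentric layers (glomerular, outer
plexiform, granule, a tract core and an accessory bulb) for plates 1–22; a
mid cerebrum with per-hemisphere cortex, subcortical plate, deep nuclei
and a fiber ring for plates 23–83; a posterior zone (84–103) where a
mid-sagittal gap splits the cerebrum and a detached ventral brainstem
appears; and a hindbrain zone (104+) where a dorsal cerebellum rejoins the
brainstem.  Its hierarchy has 4 levels and ≥ 28 leaves.

Plane identifiability is a stated design requirement of the phantom, so
several features carry a continuous AP signal: the outline radius
"breathes" along z (two incommensurate sine periods plus a monotone taper
that breaks AP aliasing), the fiber-ring radius and nuclear radius
modulate with z, a ventral flat cut oscillates in depth, and a dorsal
midline fiber column oscillates in width.  The dorsoventrally localized
markers (ventral cut, dorsal column) exist specifically because β tilt
produces only a *differential* AP shift between dorsal and ventral
content; centered features average it out.

Sections are rendered with per-region base intensities (hash-derived, in
[0.30, 0.90]; fiber tracts fixed dark at 0.12, matching their appearance
in fluorescent tissue), a smooth multiplicative bias field bounded to
±20 % (uneven staining) and additive Gaussian noise.  Artifact levels
follow the qualitative taxonomy: level 1 = uneven staining with only a
slight residual warp (max 1 px ≈ 50 μm — by its definition this level has
no morphological changes); level 2 adds global shrinkage (scale 0.95) and
doubled noise; level 3 adds tears (background blobs, ≤ 5 % of foreground)
and, for posterior planes, optional loss of one cerebrum and an
independent brainstem plane offset (±300 μm default).  Tears and cerebrum
loss affect the image only — the label ground truth remains "slice at the
true plane, warped by the true field", and that identity is bit-exact by
construction.

What a green test does *not* establish: the phantom's region boundaries
are smooth ellipsoid shells with strong, designed AP gradients; real
anatomy has far weaker and less uniform AP signal, so brute-force search
accuracy here does not predict accuracy on real tissue (the real pipeline
uses trained regressors for that reason).  Rendering is single-channel
and noise is stationary; scanner optics, folds and debris are not
simulated.

Simulated raters draw plate labels as truth + i.i.d. Gaussian noise
clipped to [1, 132]; the reported per-level rater SDs (87/96/137 μm) can
seed the noise scale.

## Evaluation choices

Sample SD (n − 1) for the mean ± 2 SD rater-agreement accuracy; with
SD = 0 only an exact match counts.  Dice of two empty masks is defined as
1 (region tables omit regions absent from both sides anyway).
Majority-vote consensus uses strict majority, so even-count ties are off.

## Known limitations

* The brute-force search assumes the section image shares the atlas
  canvas convention (centered, known pixel size); arbitrary crops need
  pre-alignment.
* β remains the hardest coordinate (smallest lever arm, weakest
  differential signal) — consistent with it being harder for human raters
  too.
* The demons stage assumes the section is a single connected tissue; the
  multiplane posterior case is registered per component by the caller.
* No GPU path, no training loops, no interactive landmark picking;
  landmarks arrive as arrays/CSV.
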