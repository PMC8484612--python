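# Methods

`crmbiofilm` analyzes tag-free confocal reflection microscopy (CRM) z-stacks
of surface-associated microbial communities, and ships a physics-based
simulator of such stacks so every estimator can be scored against a known
ground truth. This note describes the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic data does and does
not establish about real microscopy.

## Optics model

CRM detects backscattered incident light. At a planar solid–liquid interface
the background is set by the normal-incidence Fresnel power reflectance

    R = ((n1 − n2) / (n1 + n2))²,

so a glass–water interface (n ≈ 1.5255 vs 1.333) reflects ~4.5 × 10⁻³ of the
incident light — orders of magnitude above the reflection from a bacterial
cell — while an index-matching material (IMM, n ≈ 1.33) against water
reflects ~10⁻⁶, effectively nothing. All optics routines work in µm;
wavelengths enter in nm and are converted once at the boundary.

The axial resolution (optical-slice thickness) is modeled as the quadrature
sum of a diffraction term and a finite-pinhole term:

    FWHM_z = sqrt( (0.88·λ / (n − sqrt(n² − NA²)))² + (√2·n·PH/NA)² ),

with PH the backprojected pinhole diameter (pinhole in Airy units × 1.22
λ/NA). This is the standard confocal handbook form; a diffraction-only
variant is available behind a flag (`diffraction_only=True`). Published
z-resolutions for specific instruments vary with the exact PSF model and
vendor conventions, so instrument-quoted values should be treated as
cross-checks of magnitude, not identities this formula must reproduce.

Two IMM-specific rules complete the module. First, an oil-immersion
objective imaging through an IMM layer loses the rays steeper than the
layer's critical angle to total internal reflection, clipping the aperture:
`effective_na = min(NA, n_layer)` whenever the layer has finite thickness.
The clipping is taken as thickness-independent because partial, thickness
graded clipping has no closed form at this level of description. Second, the
minimum useful layer thickness equals one axial FWHM, so that an optical
slice at the IMM–liquid interface excludes the glass–IMM interface beneath.

## Synthetic scenes

Cells are spherocylinders (capsules): the simplest convex solid with a
well-defined long axis, adequate for rod-shaped and filamentous bacteria.
Defaults: length uniform on 3–10 µm (the filamentous-cell range the analysis
targets), diameter 0.8 µm (a typical *Pseudomonas* width; a package default,
not a measured value), reflectivity 1.

Two orientation models cover the two architectures a porous, mesh-like
microcolony could have:

* **layered** ("laminated 2D-mesh"): pitch (angle between the long axis and
  the horizontal plane) is half-normal with scale `pitch_sigma`, truncated
  to [0°, 90°] by redrawing; yaw uniform; centroid z snapped to the nearest
  multiple of `layer_spacing` (default 1 µm) plus uniform jitter of at most
  10 % of the spacing. The half-normal family was chosen because it is the
  simplest single-parameter family on [0°, 90°) with mode at horizontal;
  its scale maps analytically to the two summary statistics of interest
  (mean = σ·√(2/π); P(pitch < θ) = 2Φ(θ/σ) − 1), which is what makes the
  recovery experiments self-calibrating.
* **isotropic** ("3D-mesh" null): axes uniform on the upper hemisphere, so
  P(pitch < θ) = sin θ and exactly half of all cells lie below 30°.

Placement is rejection sampling. Under `overlap_policy="reject"` a candidate
is accepted only if its core segment keeps at least `min_gap_um` of
surface-to-surface clearance from every accepted capsule (segment–segment
distances, vectorized); a cell that cannot be placed within
`max_placement_attempts` consecutive tries raises a placement error naming
the attempt count. The gap parameter is part of the scene definition: the
segmentation contract assumes resolvable (non-touching) cells, and touching
filaments are deliberately reported merged, not split. `overlap_policy=
"allow"` skips the clearance test for dense-mesh stress scenes.

Scenes can alternatively be calibrated to a target *occupancy* rather than a
cell count: cells are added one at a time (rasterized incrementally) until
the slice selected by a percentile of the occupied z-range reaches the
target labeled-area fraction. Because each cell adds ≲ 0.2 percentage points
to one slice, the calibrated occupancy overshoots the target by less than
the stated tolerance (0.5 points).

### Rasterization and coordinates

z = 0 at the solid–liquid interface, increasing into the liquid; the grid
also extends `z_below_um` (default 2 µm) below the interface, as a real
acquisition would. Arrays are (z, y, x); voxel centers at (i + 0.5) · pitch;
indices 0-based; extents half-open. Default voxels are 0.2 µm isotropic — a
compromise between discretization error in the second moments (< 0.5° pitch
error for 3-µm cells) and memory/time. A voxel belongs to a cell iff its
center lies within one radius of the cell's axis segment; with
non-overlapping placement each voxel has at most one owner, and later cells
overwrite earlier ones when overlap is allowed.

## Image formation

The rendered intensity is

    I = clip( B + PSF ⊗ [ S·ρ·1_cell + A·exp(−4 ln2 · z²/FWHM_z²) ] + noise ,
              0, I_sat )

with B the constant detector baseline (default 86.4 a.u.), S the cell
reflection scale (default 1280 a.u.), ρ the per-cell reflectivity, and the
interface term an x,y-uniform axial Gaussian at z = 0 of amplitude
A = R · G (Fresnel reflectance times a gain, default G = 2 × 10⁶ a.u.). The
PSF is an anisotropic Gaussian (lateral FWHM 0.25 µm, axial 0.5 µm,
mirroring a 561-nm / NA 1.4 oil configuration). Shot noise is Poisson at
`poisson_gain` photons per a.u. (0 disables); read noise is additive
Gaussian; saturation clips at `I_sat` (default 4095, a 12-bit detector).

The defaults form a coherent operating point: a bare glass–water interface
renders a saturated interface plane, an index-matched interface is flat at
baseline to within ~1 a.u., and cells sit roughly an order of magnitude
above background — the qualitative regime the pipeline is designed for.
There is no absolute intensity calibration in reflection imaging, so all
gains are free parameters in arbitrary units.

The interface term uses a Gaussian as a documented approximation of the
axial PSF shape; its amplitude is exactly linear in the Fresnel reflectance,
which is what makes the glass/IMM peak-ratio test an identity. Rendering is
bit-reproducible: noise-free renders are deterministic, and noisy renders
are a pure function of the imaging seed.

## Segmentation

Deliberately simple and fully deterministic: global Otsu threshold →
morphological opening (ball radius 1 voxel) → 3D connected components
(26-connectivity) → discard components below 0.5 µm³ → relabel 1..K by each
component's lexicographically smallest (z, y, x) voxel. Two guards matter in
practice:

* **No-signal guard.** Otsu always returns *a* split, even on pure noise.
  The threshold is honored only if it exceeds the retained voxels' median by
  three robust standard deviations (1.4826 × MAD); otherwise the stack is
  declared cell-free. The same guard backs the background estimator.
* **Near-interface exclusion.** Slices below `exclude_slices_below_um` are
  dropped from the threshold statistics and the mask (the volume keeps its
  shape). The 1-µm default mirrors the convention of measuring from +1 µm
  upward because a bare-glass interface plane saturates. For index-matched
  stacks nothing saturates and the exclusion should be set to 0 — the
  recovery experiments do exactly that, otherwise bottom-layer cells
  thinner than the opening element after cropping are spuriously erased.

Touching filaments merge into one component by construction; no watershed
splitting is attempted because any splitting criterion would be an
undocumented invention, and merges are visible in the measurement table as
oversized, low-elongation components.

## Morphometrics

The long axis of a labeled component is the principal eigenvector of the
covariance of its physical voxel-center coordinates (the 3D analogue of
image-moment orientation); eigenvalues are reported in descending order.
The axis sign is normalized to z ≥ 0 (ties toward +x, then +y) since a
cell's axis is a line, not a direction. Pitch = arcsin(|axis_z|) ∈ [0°, 90°].
Components with fewer than 4 voxels or a rank-deficient covariance carry no
3D orientation and are excluded; components with elongation √(λ₁/λ₂) < 1.2
are kept in the table (they count toward volume and occupancy) but flagged
isotropic and excluded from angle statistics — spheres have no meaningful
pitch. The cutoff is a package default; any value safely between 1 (sphere)
and ~4 (the shortest default cell) gives identical results on the default
geometry. A length heuristic 4·√λ₁ is reported; for capsules it
overestimates tip-to-tip length by ~10 %, and it is a convenience column,
not a calibrated estimator.

Field statistics:

* **Occupancy profile**: per slice, labeled voxels inside a 2D region of
  interest divided by ROI voxels. The default ROI is the bounding rectangle
  of the colony's x,y projection dilated by one cell diameter — a
  reproducible stand-in for a hand-drawn microcolony outline; any user mask
  or rectangle can be supplied instead. Colony "bottom / mid-height / top"
  are the 10th / 50th / 90th percentiles of the occupied slice indices.
* **Density heatmap**: per slice, per 2.4 µm × 2.4 µm tile (default), the
  labeled fraction; partial edge tiles are normalized by their own voxel
  count, so the tile-weighted mean identically equals the slice occupancy.
* **Axial profile**: mean intensity per slice, optionally excluding a 2D
  region (e.g. a bright reference mark); the interface shows up as the
  argmax for a mismatched interface and as no detectable peak (max < 2 ×
  median of slice means) for a matched one, in which case the declared
  z-origin is used and flagged.
* **SBR**: on the slice at `z_offset` (default +1 µm) above the interface,
  the mean of n (default 20) seeded 3×3-voxel patches fully inside cell
  regions over the mean of n patches fully outside. Patch geometry and
  seeded sampling make the estimator deterministic and auditable; an
  insufficient candidate pool on either side is a hard error naming the
  deficient class, not a silent fallback.

## Orchestration and reproducibility

A YAML `ExperimentConfig` drives `simulate` → `analyze` → `report`. One
global seed is fanned out through `numpy.random.SeedSequence.spawn` into
named substreams (scene, noise, SBR sampling), all below 2³¹, recorded in
the run manifest together with a config hash and every artifact path.
Identical config + seed reproduces the truth CSV byte-for-byte and the
measurement table to full precision. Stacks are written as OME-TIFF with
voxel sizes in the OME metadata; the interface-anchored z-geometry rides in
a JSON sidecar that the reader requires — reflection stacks without a
declared z-origin cannot be analyzed in interface-anchored coordinates.

## Problem sizes in the shipped experiments

The recovery experiments use fields of 40–100 µm square, 10–12 µm of liquid
above the interface, at 0.2 µm voxels: large enough that 300–800 cells place
without crowding artifacts and boundary effects are negligible, small enough
that a full simulate–segment–measure cycle takes tens of seconds. Pitch
recovery runs at 300 cells (σ = 19.8°, sub-30° mass 0.87) and 500 cells
(σ = 16.8°, analytic mean 13.40°); occupancy recovery calibrates scenes to
13.4 % mid-height and 10.0 % top-slice true occupancy; the isotropic null
pools ≥ 1000 cells over four seeds.

## What the synthetic data does and does not show

The simulator emulates the *geometry and first-order radiometry* of CRM:
interface reflection scaling with Fresnel reflectance, Gaussian PSF blur,
baseline, shot/read noise, saturation, and capsule-shaped cells in layered
or isotropic arrangements. Passing recovery tests therefore demonstrates
that the measurement chain — thresholding, component labeling,
moment-based orientation, occupancy bookkeeping — is unbiased and correctly
calibrated *under this image-formation model*. They do not establish
robustness to phenomena the model omits: coherent speckle, depth-dependent
aberrations and signal loss, sub-resolution cell walls versus lumen
contrast, motile or dividing cells, extracellular matrix reflections, or
genuinely touching filament networks (where merges are reported, not
resolved). Real-data use should treat segmentation parameters — threshold
method, minimum volume, opening radius, near-interface exclusion — as
instrument-specific settings to validate against a manually annotated
field.

## Known limitations

* Orientation is unsigned (pitch only); in-plane nematic order and yaw
  statistics are out of scope.
* No tracking across timepoints; a time series is analyzed as independent
  stacks.
* The effective-NA rule is a step function of layer presence; thicknesses
  between 0 and one working distance are all treated as fully clipping.
* Half-normal is an assumption about the layered pitch distribution, not an
  inference from data; only its two summary statistics are used as
  operating points.
* The occupancy estimator inherits a small (≲ 1 percentage point at ~13 %
  occupancy) negative bias from thresholding blurred 0.8-µm-wide objects;
  it is well within the shipped tolerances but would matter for much
  thinner cells or coarser voxels.
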