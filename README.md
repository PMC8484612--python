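# crmbiofilm

Tag-free analysis of surface-associated microbial communities imaged by
**confocal reflection microscopy (CRM)**. CRM detects backscattered incident
light, so it needs no fluorescent tagging — which makes it the tool of
choice for organisms that cannot be transformed and for anaerobic
(e.g. denitrifying) conditions where fluorescent proteins fail to mature.
The catch is the solid–liquid interface itself: the refractive-index (RI)
step between glass (n ≈ 1.53) and medium (n ≈ 1.33) reflects

    R = ((n1 − n2) / (n1 + n2))²  ≈ 4.5 × 10⁻³

of the incident light at normal incidence, dwarfing the reflection from
cells. Overlaying the glass with an **index-matching material (IMM**, n ≈
1.33) suppresses this background by three orders of magnitude and makes
cells at the surface visible.

The package is aimed at microbiologists and image analysts who want to
quantify biofilm microcolony architecture from reflection z-stacks:

* **Optics rules** for index-matched imaging: Airy unit, confocal axial
  FWHM (diffraction ⊕ pinhole in quadrature), Fresnel reflectance,
  effective NA of an oil objective through an IMM layer
  (`min(NA, n_layer)` — total internal reflection clips the aperture), and
  the minimum layer thickness (one axial FWHM).
* **A synthetic-stack simulator**: spherocylindrical cells in "laminated
  2D-mesh" (quasi-horizontal, half-normal pitch) or "3D-mesh" (isotropic)
  arrangements, rendered with interface reflection ∝ Fresnel reflectance,
  anisotropic Gaussian PSF blur, detector baseline, shot + read noise, and
  saturation — with per-cell ground truth for scoring every estimator.
* **Segmentation**: interface localization from the axial intensity peak,
  robust background estimation, Otsu thresholding with a no-signal guard,
  3D connected components, size filtering.
* **Morphometrics**: per-cell principal axis from voxel second moments,
  **pitching angle** arcsin(|axis_z|) ∈ [0°, 90°] (the angle between a
  cell's long axis and the interface plane), area-occupancy profiles and
  2.4 µm tiled density heatmaps, axial intensity profiles, and seeded
  cell/background signal-to-background ratios (SBR).
* **A `crm` CLI** that chains YAML config → simulate → analyze → report.

The headline use case: deciding whether a porous mesh-like microcolony is a
stack of quasi-horizontal cell layers (pitch concentrated near 0°) or an
isotropic 3D network (P(pitch < θ) = sin θ, so only half of all cells lie
below 30°).

## Worked example

Optics for a 561-nm, NA 1.4 oil objective (n = 1.515) with a 1.2-AU pinhole
behind a 20-µm MY-133-EA layer (n = 1.33) in water:

```sh
$ crm --quiet optics --wavelength-nm 561 --na 1.4 --immersion-ri 1.515 \
      --pinhole-au 1.2 --imm-ri 1.33 --imm-thickness-um 20
{
 "airy_unit_um": 0.4888714285714286,
 "axial_fwhm_um": 1.041254061204371,
 "effective_na": 1.33,
 "min_imm_thickness_um": 1.041254061204371,
 "fresnel_reflectance": 1.2691126603998845e-06
}
```

The Airy disk is 0.49 µm, the optical slice ~1.0 µm thick (so the IMM layer
must be at least that thick), the objective is clipped to an effective NA
of 1.33 by the layer, and the residual IMM–water reflectance is ~10⁻⁶ —
six orders below glass–water, i.e. background-free.

Simulate a laminated microcolony and recover its architecture end-to-end:

```python
import crmbiofilm as cb

scene = cb.SceneSpec(extent_um=(40, 40, 10), cell_count=60,
                     orientation_model="layered", pitch_sigma_deg=19.8,
                     min_gap_um=0.8, seed=42)
imaging = cb.ImagingSpec(seed=7)
imm = cb.Interface(1.33, 1.333)          # MY-133-EA against water

stack, truth = cb.simulate_stack(scene, imaging, imm)
labels = cb.segment_cells(stack, cb.SegmentationParams(exclude_slices_below_um=0))
table = cb.measure_cells(labels)
summary = cb.angle_summary(table[~table.flag_isotropic].pitch_deg, [30, 45])
true = cb.angle_summary([c.pitch_deg for c in truth.cells], [30, 45])

print(f"segmented cells      : {labels.n_labels} / {len(truth.cells)}")
print(f"mean pitch           : {summary['mean_deg']:.1f} deg (truth {true['mean_deg']:.1f})")
print(f"fraction below 30 deg: {summary['frac_below'][30.0]:.2f} (truth {true['frac_below'][30.0]:.2f})")
prof = cb.occupancy_profile(labels)
mid = cb.colony_slice_indices(prof.occupancy.to_numpy())["mid"]
print(f"mid-height occupancy : {100*prof.occupancy[mid]:.1f} %")
```

which prints:

```
segmented cells      : 60 / 60
mean pitch           : 17.0 deg (truth 17.0)
fraction below 30 deg: 0.83 (truth 0.83)
mid-height occupancy : 2.2 %
```

Every cell was recovered; the measured mean pitch and sub-30° fraction
match the generator's ground truth to the displayed precision, and the
colony's mid-height slice has 2.2 % of its area occupied by cells — the
loose, porous regime where single-cell recognition is reliable.

The same chain from the shell:

```sh
crm simulate -c config.yaml      # stack.ome.tif + truth.* + manifest.json
crm analyze  -c config.yaml run/stack.ome.tif --truth run/truth
crm report   run/                # figures + report.md
```

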