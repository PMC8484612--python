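"""Per-cell morphometrics and field statistics for reflection z-stacks.

The central quantity is the *pitching angle*: the angle between a cell's long
axis and the horizontal (interface) plane, arcsin(|axis_z|) in [0, 90]
degrees.  The long axis is the principal eigenvector of the covariance of a
labeled component's physical voxel-center coordinates — the 3D analogue of
region-moment orientation.  Around it sit the field statistics used to
characterize a microcolony: per-slice area occupation within a region of
interest, tiled density heatmaps, the axial mean-intensity profile used to
localize the interface reflection, and the cell/background
signal-to-background ratio (SBR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segment import LabelVolume, _region_mask
from .simulate import ZStack

__all__ = [
    "CellMeasurement",
    "SbrResult",
    "principal_axis",
    "pitch_angle",
    "measure_cells",
    "angle_summary",
    "colony_roi",
    "colony_slice_indices",
    "occupancy_profile",
    "density_heatmap",
    "axial_intensity_profile",
    "signal_background_ratio",
    "sbr_fold_improvement",
    "ELONGATION_CUTOFF",
]

#: cells below this sqrt(eigenvalue-ratio) are flagged isotropic and left out
#: of angle statistics (a sphere has no meaningful long axis)
ELONGATION_CUTOFF = 1.2

_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class CellMeasurement:
    """One measured cell: position, second moments, orientation."""

    label: int
    centroid_um: tuple[float, float, float]  # (x, y, z), z from interface
    volume_um3: float
    principal_axis_xyz: tuple[float, float, float]
    eigenvalues_um2: tuple[float, float, float]  # descending
    elongation: float
    pitch_deg: float
    length_estimate_um: float
    flag_isotropic: bool


@dataclass(frozen=True)
class SbrResult:
    """Signal-to-background ratio from sampled cell / background patches."""

    cell_mean: float
    background_mean: float
    ratio: float
    n_regions: int
    z_offset_um: float


def principal_axis(
    voxel_indices: np.ndarray, voxel_size_um: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis and covariance eigenvalues of one labeled component.

    ``voxel_indices`` is an (N, 3) array of (z, y, x) indices;
    ``voxel_size_um`` is (dz, dy, dx).  Returns ``(axis, eigenvalues)`` with
    the axis as a unit (x, y, z) vector sign-normalized to z >= 0 (ties
    broken toward x > 0, then y > 0) and eigenvalues sorted descending, in
    um^2.  Raises ``ValueError`` for degenerate components (< 4 voxels or
    rank-deficient covariance): such components carry no 3D orientation.
    """
    idx = np.asarray(voxel_indices, dtype=np.float64)
    if idx.ndim != 2 or idx.shape[1] != 3:
        raise ValueError("voxel_indices must be (N, 3) in (z, y, x) order")
    if idx.shape[0] < 4:
        raise ValueError("degenerate component: fewer than 4 voxels")
    dz, dy, dx = voxel_size_um
    coords = np.column_stack([idx[:, 2] * dx, idx[:, 1] * dy, idx[:, 0] * dz])
    cov = np.cov(coords, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    axis = evecs[:, order[0]]
    if evals[2] <= _DEGENERATE_RTOL * max(evals[0], 1e-300):
        raise ValueError("degenerate component: coplanar voxel set")
    # sign convention: z >= 0, then x > 0, then y > 0
    if axis[2] < 0 or (axis[2] == 0 and (axis[0] < 0 or (axis[0] == 0 and axis[1] < 0))):
        axis = -axis
    return axis, evals


def pitch_angle(axis) -> float:
    """Pitch of a long axis: arcsin(|axis_z|) in degrees, range [0, 90].

    Invariant under axis sign flip; a zero vector is rejected.
    """
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm < 1e-12:
        raise ValueError("axis must be a nonzero vector")
    return math.degrees(math.asin(min(1.0, abs(a[2]) / norm)))


def measure_cells(labels: LabelVolume) -> pd.DataFrame:
    """Measure every labeled component; one row per non-degenerate label.

    Columns: label, x_um, y_um, z_um (centroid, z from the interface),
    volume_um3, axis_x/y/z, eig1/2/3_um2, elongation (sqrt(eig1/eig2)),
    pitch_deg, length_est_um (4*sqrt(eig1)), flag_isotropic.  Cells with
    elongation below :data:`ELONGATION_CUTOFF` are flagged isotropic: they
    count toward volume and occupancy but not angle statistics.
    """
    grid = labels.grid
    dz, dxy = grid.voxel_z_um, grid.voxel_xy_um
    vol_vox = grid.voxel_volume_um3
    z0_um = -grid.z_below_um
    rows = []
    objects = ndimage.find_objects(labels.labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        local = np.argwhere(labels.labels[slc] == lab)
        offset = np.array([s.start for s in slc])
        idx = local + offset
        try:
            axis, evals = principal_axis(idx, (dz, dxy, dxy))
        except ValueError:
            continue  # degenerate: no orientation row
        cz = (idx[:, 0].mean() + 0.5) * dz + z0_um
        cy = (idx[:, 1].mean() + 0.5) * dxy
        cx = (idx[:, 2].mean() + 0.5) * dxy
        elong = math.sqrt(evals[0] / evals[1]) if evals[1] > 0 else math.inf
        rows.append(
            {
                "label": lab,
                "x_um": cx,
                "y_um": cy,
                "z_um": cz,
                "volume_um3": idx.shape[0] * vol_vox,
                "axis_x": axis[0],
                "axis_y": axis[1],
                "axis_z": axis[2],
                "eig1_um2": evals[0],
                "eig2_um2": evals[1],
                "eig3_um2": evals[2],
                "elongation": elong,
                "pitch_deg": pitch_angle(axis),
                "length_est_um": 4.0 * math.sqrt(evals[0]),
                "flag_isotropic": elong < ELONGATION_CUTOFF,
            }
        )
    columns = [
        "label", "x_um", "y_um", "z_um", "volume_um3",
        "axis_x", "axis_y", "axis_z", "eig1_um2", "eig2_um2", "eig3_um2",
        "elongation", "pitch_deg", "length_est_um", "flag_isotropic",
    ]
    df = pd.DataFrame(rows, columns=columns)
    # empty frames must keep usable dtypes for downstream boolean selection
    return df.astype({"label": np.int64, "flag_isotropic": bool}, errors="ignore")


def angle_summary(pitches, thresholds=(30.0, 45.0)) -> dict:
    """Mean pitch and, per threshold, the fraction strictly below it.

    An empty input yields ``n = 0`` with the mean and fractions reported as
    missing (None) rather than NaN arithmetic.
    """
    p = np.asarray(list(pitches), dtype=float)
    if p.size and (p.min() < 0 or p.max() > 90):
        raise ValueError("pitches must lie in [0, 90] degrees")
    if p.size == 0:
        return {"n": 0, "mean_deg": None,
                "frac_below": {float(t): None for t in thresholds}}
    return {
        "n": int(p.size),
        "mean_deg": float(p.mean()),
        "frac_below": {float(t): float((p < t).mean()) for t in thresholds},
    }


def colony_roi(labels: LabelVolume, dilate_um: float = 0.8) -> np.ndarray:
    """Default microcolony region of interest.

    The axis-aligned bounding rectangle of the labeled voxels projected to
    x,y, dilated by ``dilate_um`` (one cell diameter by default) — a
    reproducible stand-in for a hand-drawn colony outline.  Returns a boolean
    (y, x) mask; empty if nothing is labeled.
    """
    proj = (labels.labels > 0).any(axis=0)
    mask = np.zeros_like(proj)
    if not proj.any():
        return mask
    ys, xs = np.nonzero(proj)
    pad = int(round(dilate_um / labels.grid.voxel_xy_um))
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, proj.shape[0])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, proj.shape[1])
    mask[y0:y1, x0:x1] = True
    return mask


def colony_slice_indices(occupancy_per_slice: np.ndarray) -> dict[str, int]:
    """Bottom / mid-height / top slice indices of a colony.

    Operationalized as the 10th-percentile, median, and 90th-percentile of
    the occupied z-slice indices (occupancy > 0).
    """
    occupied = np.flatnonzero(np.asarray(occupancy_per_slice) > 0)
    if occupied.size == 0:
        raise ValueError("colony is empty: no occupied slices")
    pct = lambda q: int(np.percentile(occupied, q, method="nearest"))
    return {"bottom": pct(10), "mid": pct(50), "top": pct(90)}


def occupancy_profile(labels: LabelVolume, roi=None) -> pd.DataFrame:
    """Per-slice fraction of the ROI covered by labeled cell regions.

    ``roi`` is a boolean (y, x) mask or an index rectangle (y0, y1, x0, x1);
    None uses :func:`colony_roi`.  Returns a DataFrame with columns ``z_um``
    (strictly increasing) and ``occupancy``.
    """
    if roi is None:
        mask = colony_roi(labels)
    else:
        mask = _region_mask(roi, labels.labels.shape[1:])
    n_roi = int(mask.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    occ = (labels.labels[:, mask] > 0).mean(axis=1)
    return pd.DataFrame({"z_um": labels.grid.z_centers_um, "occupancy": occ})


def density_heatmap(labels: LabelVolume, tile_um: float = 2.4) -> np.ndarray:
    """Tiled local cell density: per slice, per tile, the labeled fraction.

    Tiles are ``tile_um`` squares in x,y (2.4 um default); partial edge tiles
    are normalized by their own voxel count, so every tile value is a true
    fraction in [0, 1].  Returns an array of shape (nz, n_tiles_y, n_tiles_x).
    """
    dxy = labels.grid.voxel_xy_um
    if tile_um < dxy:
        raise ValueError("tile_um must be at least one voxel")
    t = max(int(round(tile_um / dxy)), 1)
    fg = (labels.labels > 0)
    nz, ny, nx = fg.shape
    nty, ntx = math.ceil(ny / t), math.ceil(nx / t)
    out = np.empty((nz, nty, ntx), dtype=np.float64)
    for j in range(nty):
        for i in range(ntx):
            block = fg[:, j * t : (j + 1) * t, i * t : (i + 1) * t]
            out[:, j, i] = block.mean(axis=(1, 2))
    return out


def axial_intensity_profile(stack: ZStack, exclusion=None) -> pd.DataFrame:
    """Mean intensity per z-slice, optionally excluding an x,y region.

    This is the profile in which a refractive-index-mismatched interface
    shows up as a sharp axial peak; the exclusion region removes a bright
    reference mark from the average.  Returns columns ``z_um`` and
    ``mean_intensity``.
    """
    if exclusion is None:
        mask = np.ones(stack.data.shape[1:], dtype=bool)
    else:
        mask = ~_region_mask(exclusion, stack.data.shape[1:])
    if not mask.any():
        raise ValueError("exclusion region covers the whole field")
    prof = stack.data[:, mask].mean(axis=1)
    return pd.DataFrame({"z_um": stack.z_centers_um, "mean_intensity": prof})


def _patch_centers(eligible: np.ndarray, patch: int) -> np.ndarray:
    """Centers whose patch x patch window lies entirely inside ``eligible``."""
    full = ndimage.minimum_filter(eligible.astype(np.uint8), size=patch, mode="constant") > 0
    return np.argwhere(full)


def signal_background_ratio(
    stack: ZStack,
    labels: LabelVolume,
    z_offset_um: float = 1.0,
    n_regions: int = 20,
    seed: int = 0,
    patch: int = 3,
) -> SbrResult:
    """SBR on the slice ``z_offset_um`` above the interface.

    Samples ``n_regions`` patch x patch windows fully inside cell regions and
    ``n_regions`` fully outside them (without replacement, seeded), and
    returns mean(cell patches) / mean(background patches).  The +1 um default
    offset skips the interface plane, which can be saturated on bare glass.
    """
    if n_regions <= 0:
        raise ValueError("n_regions must be > 0")
    zi = stack.z_index(z_offset_um)
    if abs(stack.z_centers_um[zi] - z_offset_um) > stack.grid.voxel_z_um:
        raise ValueError(f"z offset {z_offset_um} um falls outside the stack")
    plane = np.asarray(stack.data[zi], dtype=np.float64)
    cell_mask = labels.labels[zi] > 0
    cell_centers = _patch_centers(cell_mask, patch)
    bg_centers = _patch_centers(~cell_mask, patch)
    if cell_centers.shape[0] < n_regions:
        raise ValueError(
            f"insufficient cell regions on slice: {cell_centers.shape[0]} < {n_regions}"
        )
    if bg_centers.shape[0] < n_regions:
        raise ValueError(
            f"insufficient background regions on slice: {bg_centers.shape[0]} < {n_regions}"
        )
    rng = np.random.default_rng(seed)
    half = patch // 2
    def patch_means(centers: np.ndarray) -> float:
        pick = centers[rng.choice(centers.shape[0], size=n_regions, replace=False)]
        vals = [
            plane[y - half : y + half + 1, x - half : x + half + 1].mean()
            for y, x in pick
        ]
        return float(np.mean(vals))

    cell_mean = patch_means(cell_centers)
    bg_mean = patch_means(bg_centers)
    return SbrResult(
        cell_mean=cell_mean,
        background_mean=bg_mean,
        ratio=cell_mean / bg_mean,
        n_regions=n_regions,
        z_offset_um=z_offset_um,
    )


def sbr_fold_improvement(sbr_with, sbr_without) -> float:
    """Fold improvement between two SBRs (accepts SbrResult or plain ratios)."""
    w = sbr_with.ratio if isinstance(sbr_with, SbrResult) else float(sbr_with)
    wo = sbr_without.ratio if isinstance(sbr_without, SbrResult) else float(sbr_without)
    if wo <= 0:
        raise ValueError("reference SBR must be > 0")
    return w / wo
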