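"""Single-cell recognition in reflection z-stacks.

The pipeline is deliberately simple and fully deterministic: locate the
solid-liquid interface from the axial intensity peak, optionally drop the
saturated near-interface slices from the statistics, apply a global threshold
(Otsu by default), clean up with a morphological opening, label 3D connected
components, and discard components below a physical volume cutoff.  Touching
filaments are reported merged, not split: no watershed is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .simulate import Grid, ZStack

__all__ = [
    "SegmentationParams",
    "LabelVolume",
    "InterfaceLocation",
    "locate_interface",
    "estimate_background",
    "segment_cells",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the thresholding + component-labeling pipeline.

    ``exclude_slices_below_um`` drops slices with z below this height above
    the interface from the threshold statistics and from the cell mask (the
    volume keeps its shape); the 1 um default mirrors the convention of
    analyzing from +1 um upward because the interface plane itself can be
    saturated.
    """

    threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float = 0.0
    min_volume_um3: float = 0.5
    opening_radius: int = 1
    connectivity: int = 26
    exclude_slices_below_um: float = 1.0

    def __post_init__(self) -> None:
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.min_volume_um3 < 0:
            raise ValueError("min_volume_um3 must be >= 0")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")


@dataclass
class LabelVolume:
    """Integer-labeled segmentation on the same grid as its source stack.

    Labels are consecutive 1..K (0 = background), ordered deterministically
    by each component's lexicographically smallest (z, y, x) voxel.
    """

    labels: np.ndarray  # int32 (z, y, x)
    grid: Grid
    n_labels: int
    threshold: float
    params: SegmentationParams

    @property
    def z_origin(self) -> int:
        return self.grid.z_origin


@dataclass(frozen=True)
class InterfaceLocation:
    """Result of interface localization: slice index + whether a peak stood out."""

    z_index: int
    peak_found: bool
    peak_mean: float
    median_mean: float


def _region_mask(region, shape_yx: tuple[int, int]) -> np.ndarray:
    """Normalize a 2D region spec to a boolean (y, x) mask.

    Accepts a boolean mask, or an index rectangle (y0, y1, x0, x1) half-open.
    """
    ny, nx = shape_yx
    if region is None:
        return np.ones((ny, nx), dtype=bool)
    region_arr = np.asarray(region)
    if region_arr.dtype == bool:
        if region_arr.shape != (ny, nx):
            raise ValueError(f"region mask shape {region_arr.shape} != field {(ny, nx)}")
        return region_arr
    y0, y1, x0, x1 = (int(v) for v in region_arr.ravel())
    if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError(f"region rectangle {(y0, y1, x0, x1)} outside field {(ny, nx)}")
    mask = np.zeros((ny, nx), dtype=bool)
    mask[y0:y1, x0:x1] = True
    return mask


def locate_interface(stack: ZStack, mark_region=None) -> InterfaceLocation:
    """Find the interface slice as the z of maximum mean intensity.

    The z-position of the interface is defined as the slice where the average
    intensity inside ``mark_region`` (a bright reference mark; the whole
    field if None) is maximal.  If the peak does not stand out — maximum
    slice mean below twice the median slice mean, as happens for
    index-matched data with a flat axial profile — the stack's declared
    z-origin is returned with ``peak_found=False``.
    """
    mask = _region_mask(mark_region, stack.data.shape[1:])
    if not mask.any():
        raise ValueError("mark_region is empty")
    means = stack.data[:, mask].mean(axis=1)
    zi = int(np.argmax(means))
    peak, med = float(means[zi]), float(np.median(means))
    if peak < 2.0 * med:
        return InterfaceLocation(stack.z_origin, False, peak, med)
    return InterfaceLocation(zi, True, peak, med)


def estimate_background(
    stack: ZStack, z_offset_um: float = 1.0, threshold: float | None = None
) -> float:
    """Mean non-cell intensity on the slice ``z_offset_um`` above the interface.

    Non-cell voxels are those at or below the segmentation ``threshold``.
    When no threshold is given, a whole-stack Otsu threshold is used, but
    only if it stands clear of the background mode (median + 3 robust
    standard deviations of the slice): on a cell-free slice Otsu merely
    splits the noise distribution, so the plain slice mean is the unbiased
    answer there.  The +1 um default offset skips the interface plane, which
    can be saturated on bare glass.
    """
    zi = stack.z_index(z_offset_um)
    z_at = stack.z_centers_um[zi]
    if abs(z_at - z_offset_um) > stack.grid.voxel_z_um:
        raise ValueError(f"z offset {z_offset_um} um falls outside the stack")
    plane = np.asarray(stack.data[zi], dtype=np.float64)
    if threshold is None:
        if np.ptp(stack.data) < 1e-9:
            return float(plane.mean())
        threshold = float(threshold_otsu(np.asarray(stack.data, dtype=np.float64)))
        med = float(np.median(plane))
        robust_sd = 1.4826 * float(np.median(np.abs(plane - med)))
        if threshold <= med + 3.0 * robust_sd:
            return float(plane.mean())
    below = plane[plane <= threshold]
    if below.size == 0:
        return float(plane.mean())
    return float(below.mean())


def _relabel_by_position(labels: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    """Relabel components 1..K ordered by their smallest (z, y, x) voxel."""
    if n == 0:
        return labels, 0
    lin = np.flatnonzero(labels.ravel())
    vals = labels.ravel()[lin]
    first = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first, vals, lin)
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return remap[labels], n


def segment_cells(stack: ZStack, params: SegmentationParams | None = None) -> LabelVolume:
    """Threshold, open, label, and size-filter a reflection z-stack.

    An all-background result (K = 0) is valid, not an error.
    """
    if params is None:
        params = SegmentationParams()
    data = stack.data
    z_um = stack.z_centers_um
    retained = z_um >= params.exclude_slices_below_um

    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)
    else:
        voxels = data[retained] if retained.any() else data
        blank = np.ptp(voxels) < 1e-9
        if not blank:
            thr = float(threshold_otsu(np.asarray(voxels, dtype=np.float64)))
            # Otsu always returns *a* split; require it to stand clear of the
            # background mode, else the stack is cell-free (noise only)
            med = float(np.median(voxels))
            robust_sd = 1.4826 * float(np.median(np.abs(voxels - med)))
            blank = thr <= med + 3.0 * robust_sd
        if blank:
            return LabelVolume(
                labels=np.zeros_like(data, dtype=np.int32),
                grid=stack.grid, n_labels=0, threshold=float(voxels.max()), params=params,
            )

    binary = data > thr
    binary[~retained, :, :] = False

    if params.opening_radius > 0:
        binary = ndimage.binary_opening(binary, structure=ball(params.opening_radius))

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[params.connectivity])
    labels, n = ndimage.label(binary, structure=structure)

    if n and params.min_volume_um3 > 0:
        min_voxels = params.min_volume_um3 / stack.grid.voxel_volume_um3
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        keep = counts >= min_voxels
        keep[0] = False
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
        labels = remap[labels]
        n = int(keep.sum())

    labels = labels.astype(np.int32, copy=False)
    labels, n = _relabel_by_position(labels, n)
    return LabelVolume(labels=labels, grid=stack.grid, n_labels=n, threshold=thr, params=params)
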