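"""Synthetic CRM z-stacks of biofilm microcolonies.

Generates scenes of spherocylindrical (capsule-shaped) cells above a
solid-liquid interface, rasterizes them onto a voxel grid, and renders a
confocal-reflection-like z-stack: interface reflection scaled by the Fresnel
reflectance of the refractive-index step, reflection from cell bodies,
anisotropic Gaussian PSF blur, constant detector baseline, shot and read
noise, and detector saturation.  The rasterized label volume and the per-cell
geometry are kept as ground truth so downstream segmentation and
morphometrics can be scored against a known answer.

Two orientation models are provided, mirroring the two architectures a
mesh-like microcolony could have:

``layered``
    quasi-horizontal cells: the pitching angle (angle between the cell long
    axis and the horizontal plane) is half-normal with scale ``pitch_sigma``,
    yaw uniform, and centroid z snapped near multiples of ``layer_spacing``
    ("laminated 2D-mesh").

``isotropic``
    axes uniform on the upper unit hemisphere, so the pitch CDF is
    P(pitch < theta) = sin(theta) ("3D-mesh" null model).

Coordinates: z = 0 at the solid-liquid interface, increasing into the liquid;
arrays are ordered (z, y, x); voxel centers sit at (i + 0.5) * pitch; all
indices 0-based, extents half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .optics import Interface, fresnel_reflectance

__all__ = [
    "CellSpec",
    "Grid",
    "SceneSpec",
    "ImagingSpec",
    "ZStack",
    "GroundTruth",
    "PlacementError",
    "GridMismatchError",
    "sample_scene",
    "sample_scene_to_occupancy",
    "rasterize_cells",
    "render_stack",
    "simulate_stack",
]

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class PlacementError(RuntimeError):
    """Cell placement failed: the domain is too crowded for the reject policy."""


class GridMismatchError(ValueError):
    """Ground truth and requested stack grid do not coincide."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSpec:
    """One spherocylindrical cell.

    ``length_um`` is tip-to-tip including the hemispherical caps; ``axis`` is
    a unit vector with non-negative z-component (axis sign is physically
    meaningless for a cell, so the upper-hemisphere representative is
    stored).  ``reflectivity`` scales the cell's reflection amplitude.
    """

    centroid_um: tuple[float, float, float]  # (x, y, z)
    length_um: float
    diameter_um: float
    axis: tuple[float, float, float]  # unit (x, y, z), z >= 0
    reflectivity: float = 1.0

    def __post_init__(self) -> None:
        if not (self.length_um >= self.diameter_um > 0):
            raise ValueError("need length_um >= diameter_um > 0")
        norm = math.sqrt(sum(a * a for a in self.axis))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError("axis must be a unit vector")
        if self.axis[2] < -1e-12:
            raise ValueError("axis z-component must be >= 0")
        if self.centroid_um[2] < 0:
            raise ValueError("centroid z must be >= 0 (cells sit above the interface)")
        if self.reflectivity < 0:
            raise ValueError("reflectivity must be >= 0")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def half_axis_um(self) -> np.ndarray:
        """Vector from centroid to one end of the cylindrical core segment."""
        half = (self.length_um - self.diameter_um) / 2.0
        return half * np.asarray(self.axis, dtype=float)

    @property
    def segment_um(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.centroid_um, dtype=float)
        h = self.half_axis_um
        return c - h, c + h

    @property
    def pitch_deg(self) -> float:
        return math.degrees(math.asin(min(1.0, abs(self.axis[2]))))


@dataclass(frozen=True)
class Grid:
    """Voxel grid spanning x,y in [0, extent) and z in [-z_below, z_extent).

    ``z_below_um`` is the depth imaged below the interface (the glass/IMM
    side), so the interface plane z = 0 lies inside the stack.
    """

    extent_um: tuple[float, float, float]  # (x, y, z above interface)
    voxel_xy_um: float = 0.2
    voxel_z_um: float = 0.2
    z_below_um: float = 2.0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent_um):
            raise ValueError("extents must be > 0")
        if self.voxel_xy_um <= 0 or self.voxel_z_um <= 0:
            raise ValueError("voxel sizes must be > 0")
        if self.z_below_um < 0:
            raise ValueError("z_below_um must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        nx = int(round(self.extent_um[0] / self.voxel_xy_um))
        ny = int(round(self.extent_um[1] / self.voxel_xy_um))
        nz = int(round((self.extent_um[2] + self.z_below_um) / self.voxel_z_um))
        return nz, ny, nx

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_xy_um**2 * self.voxel_z_um

    @property
    def z_centers_um(self) -> np.ndarray:
        nz = self.shape[0]
        return (np.arange(nz) + 0.5) * self.voxel_z_um - self.z_below_um

    @property
    def z_origin(self) -> int:
        """Index of the z-plane closest to the interface (z = 0)."""
        return int(np.argmin(np.abs(self.z_centers_um)))

    def xy_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        nz, ny, nx = self.shape
        y = (np.arange(ny) + 0.5) * self.voxel_xy_um
        x = (np.arange(nx) + 0.5) * self.voxel_xy_um
        return y, x


@dataclass(frozen=True)
class SceneSpec:
    """Population and grid parameters for one synthetic microcolony."""

    extent_um: tuple[float, float, float] = (60.0, 60.0, 12.0)
    voxel_xy_um: float = 0.2
    voxel_z_um: float = 0.2
    z_below_um: float = 2.0
    cell_count: int = 100
    orientation_model: Literal["layered", "isotropic"] = "layered"
    pitch_sigma_deg: float = 19.8
    layer_spacing_um: float = 1.0
    length_range_um: tuple[float, float] = (3.0, 10.0)
    diameter_um: float = 0.8
    overlap_policy: Literal["reject", "allow"] = "reject"
    min_gap_um: float = 0.0
    max_placement_attempts: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range_um
        if not (0 < lo <= hi):
            raise ValueError("length_range_um must satisfy 0 < min <= max")
        if lo < self.diameter_um:
            raise ValueError("minimum length must be >= diameter")
        if self.orientation_model == "layered" and self.pitch_sigma_deg <= 0:
            raise ValueError("pitch_sigma_deg must be > 0 for the layered model")
        if self.orientation_model == "layered" and self.layer_spacing_um <= 0:
            raise ValueError("layer_spacing_um must be > 0 for the layered model")
        self.grid  # validate grid parameters

    @property
    def grid(self) -> Grid:
        return Grid(
            extent_um=self.extent_um,
            voxel_xy_um=self.voxel_xy_um,
            voxel_z_um=self.voxel_z_um,
            z_below_um=self.z_below_um,
        )


@dataclass(frozen=True)
class ImagingSpec:
    """Rendering parameters for the CRM image-formation model.

    Intensities are detector arbitrary units (a.u.).  The defaults emulate a
    561 nm / NA 1.4 oil-immersion configuration on a 12-bit detector: axial
    FWHM 0.5 um, constant baseline 86.4 a.u., and a reflectance gain chosen
    so a bare glass-water interface (Fresnel reflectance ~4.5e-3) saturates
    the detector even after PSF blur, while an index-matched interface stays
    at baseline.
    ``poisson_gain`` is photons per a.u. (0 disables shot noise);
    ``read_noise_sd`` is additive Gaussian noise in a.u. (0 disables).
    """

    psf_lateral_fwhm_um: float = 0.25
    psf_axial_fwhm_um: float = 0.5
    interface_reflectance: float = 0.0
    reflectance_to_intensity_gain: float = 2.0e6
    cell_intensity_scale: float = 1280.0
    baseline: float = 86.4
    poisson_gain: float = 1.0
    read_noise_sd: float = 2.0
    saturation_level: float = 4095.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_lateral_fwhm_um <= 0 or self.psf_axial_fwhm_um <= 0:
            raise ValueError("PSF FWHMs must be > 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if self.saturation_level <= self.baseline:
            raise ValueError("saturation_level must exceed baseline")
        if self.poisson_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class ZStack:
    """A 3D reflection-intensity volume with physical voxel geometry.

    ``data`` is (z, y, x) in a.u.; ``grid`` carries voxel sizes and the
    interface-anchored z coordinate (``z_origin`` is the index of the plane
    closest to z = 0).
    """

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("ZStack data must be 3D (z, y, x)")
        if tuple(self.data.shape) != self.grid.shape:
            raise GridMismatchError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def z_origin(self) -> int:
        return self.grid.z_origin

    @property
    def z_centers_um(self) -> np.ndarray:
        return self.grid.z_centers_um

    def z_index(self, z_um: float) -> int:
        """Index of the slice whose center is closest to physical z (um)."""
        idx = int(np.argmin(np.abs(self.z_centers_um - z_um)))
        return idx


@dataclass
class GroundTruth:
    """Simulator oracle: per-cell geometry plus the rasterized label volume."""

    cells: list[CellSpec]
    labels: np.ndarray  # int32 (z, y, x), 0 = background
    grid: Grid
    occupancy: np.ndarray  # per-slice labeled fraction over the full field

    def occupancy_at(self, z_index: int) -> float:
        return float(self.occupancy[z_index])


# ---------------------------------------------------------------------------
# capsule geometry
# ---------------------------------------------------------------------------


def _segment_segment_distance(
    p0: np.ndarray, p1: np.ndarray, q0: np.ndarray, q1: np.ndarray
) -> np.ndarray:
    """Minimum distances between segment (p0,p1) and N segments (q0[i],q1[i])."""
    eps = 1e-12
    d1 = p1 - p0  # (3,)
    d2 = q1 - q0  # (N, 3)
    r = p0[None, :] - q0  # (N, 3)
    a = float(d1 @ d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = r @ d1
    b = d2 @ d1
    denom = a * e - b * b
    s = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0), 0, 1), 0.0)
    t = np.where(e > eps, (b * s + f) / np.where(e > eps, e, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    if a > eps:
        s = np.clip((b * t - c) / a, 0.0, 1.0)
    else:
        s = np.zeros_like(t)
    closest_p = p0[None, :] + s[:, None] * d1[None, :]
    closest_q = q0 + t[:, None] * d2
    return np.linalg.norm(closest_p - closest_q, axis=1)


class _PlacedGeometry:
    """Growing cache of accepted capsule segments for fast clearance tests."""

    def __init__(self) -> None:
        self._q0: list[np.ndarray] = []
        self._q1: list[np.ndarray] = []
        self._radii: list[float] = []
        self._arrays: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self._radii)

    def add(self, cell: CellSpec) -> None:
        p0, p1 = cell.segment_um
        self._q0.append(p0)
        self._q1.append(p1)
        self._radii.append(cell.radius_um)
        self._arrays = None

    def clear_of(self, cell: CellSpec, min_gap: float) -> bool:
        if not self._radii:
            return True
        if self._arrays is None:
            self._arrays = (
                np.array(self._q0),
                np.array(self._q1),
                np.array(self._radii),
            )
        q0, q1, radii = self._arrays
        p0, p1 = cell.segment_um
        d = _segment_segment_distance(p0, p1, q0, q1)
        return bool(np.all(d >= cell.radius_um + radii + min_gap))


# ---------------------------------------------------------------------------
# scene sampling
# ---------------------------------------------------------------------------


def _draw_axis(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.orientation_model == "isotropic":
        v = rng.normal(size=3)
        while np.linalg.norm(v) < 1e-9:  # pragma: no cover - measure-zero
            v = rng.normal(size=3)
        v = v / np.linalg.norm(v)
        v[2] = abs(v[2])
        return v
    # layered: half-normal pitch truncated to [0, 90], uniform yaw
    pitch = abs(rng.normal(0.0, spec.pitch_sigma_deg))
    while pitch > 90.0:
        pitch = abs(rng.normal(0.0, spec.pitch_sigma_deg))
    yaw = rng.uniform(0.0, 2.0 * math.pi)
    p = math.radians(pitch)
    return np.array([math.cos(p) * math.cos(yaw), math.cos(p) * math.sin(yaw), math.sin(p)])


def _draw_cell(spec: SceneSpec, rng: np.random.Generator) -> CellSpec:
    axis = _draw_axis(spec, rng)
    length = rng.uniform(*spec.length_range_um)
    r = spec.diameter_um / 2.0
    half = (length - spec.diameter_um) / 2.0 * np.abs(axis)
    lo = half + r
    hi = np.array(spec.extent_um) - half - r
    if np.any(hi <= lo):
        raise PlacementError(
            f"a cell of length {length:.2f} um cannot fit inside extents {spec.extent_um}"
        )
    centroid = rng.uniform(lo, hi)
    if spec.orientation_model == "layered":
        # snap z to the layer lattice, with jitter <= 10 % of the spacing
        snapped = round(centroid[2] / spec.layer_spacing_um) * spec.layer_spacing_um
        snapped += rng.uniform(-0.1, 0.1) * spec.layer_spacing_um
        centroid[2] = min(max(snapped, lo[2]), hi[2])
    return CellSpec(
        centroid_um=tuple(float(v) for v in centroid),
        length_um=float(length),
        diameter_um=spec.diameter_um,
        axis=tuple(float(v) for v in axis),
    )


def sample_scene(spec: SceneSpec, rng: np.random.Generator | None = None) -> list[CellSpec]:
    """Sample ``spec.cell_count`` cells; deterministic given ``spec.seed``.

    Under ``overlap_policy='reject'`` no two capsules come closer (surface to
    surface) than ``min_gap_um``; placement raises :class:`PlacementError`
    after ``max_placement_attempts`` consecutive rejections for one cell.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cells: list[CellSpec] = []
    placed = _PlacedGeometry()
    while len(cells) < spec.cell_count:
        cells.append(_place_one(spec, rng, placed))
    return cells


def _place_one(
    spec: SceneSpec, rng: np.random.Generator, placed: _PlacedGeometry
) -> CellSpec:
    for _ in range(spec.max_placement_attempts):
        cell = _draw_cell(spec, rng)
        if spec.overlap_policy == "allow" or placed.clear_of(cell, spec.min_gap_um):
            placed.add(cell)
            return cell
    raise PlacementError(
        f"failed to place a non-overlapping cell after "
        f"{spec.max_placement_attempts} attempts ({len(placed)} placed)"
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _paint_cell(
    labels: np.ndarray, cell: CellSpec, grid: Grid, value: int
) -> tuple[int, np.ndarray]:
    """Label all voxels whose center lies inside the capsule (in place).

    Returns ``(z_start, painted_per_slice)`` for the sub-range touched, so
    callers can maintain per-slice occupancy incrementally (exact when cells
    do not overlap)."""
    nz, ny, nx = labels.shape
    p0, p1 = cell.segment_um
    r = cell.radius_um
    lo = np.minimum(p0, p1) - r
    hi = np.maximum(p0, p1) + r
    # physical (x, y, z) -> index ranges; z axis is offset by z_below
    ix0 = max(int(math.floor(lo[0] / grid.voxel_xy_um - 0.5)), 0)
    ix1 = min(int(math.ceil(hi[0] / grid.voxel_xy_um + 0.5)), nx)
    iy0 = max(int(math.floor(lo[1] / grid.voxel_xy_um - 0.5)), 0)
    iy1 = min(int(math.ceil(hi[1] / grid.voxel_xy_um + 0.5)), ny)
    iz0 = max(int(math.floor((lo[2] + grid.z_below_um) / grid.voxel_z_um - 0.5)), 0)
    iz1 = min(int(math.ceil((hi[2] + grid.z_below_um) / grid.voxel_z_um + 0.5)), nz)
    if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
        return 0, np.zeros(0, dtype=np.int64)
    x = (np.arange(ix0, ix1) + 0.5) * grid.voxel_xy_um
    y = (np.arange(iy0, iy1) + 0.5) * grid.voxel_xy_um
    z = (np.arange(iz0, iz1) + 0.5) * grid.voxel_z_um - grid.z_below_um
    # squared distance from voxel centers to the core segment
    d = p1 - p0
    dd = float(d @ d)
    px = x[None, None, :] - p0[0]
    py = y[None, :, None] - p0[1]
    pz = z[:, None, None] - p0[2]
    if dd < 1e-12:
        t = 0.0
        qx, qy, qz = px, py, pz
    else:
        t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / dd, 0.0, 1.0)
        qx = px - t * d[0]
        qy = py - t * d[1]
        qz = pz - t * d[2]
    inside = qx * qx + qy * qy + qz * qz <= r * r
    sub = labels[iz0:iz1, iy0:iy1, ix0:ix1]
    sub[inside] = value
    return iz0, inside.sum(axis=(1, 2))


def rasterize_cells(cells: Sequence[CellSpec], grid: Grid) -> GroundTruth:
    """Rasterize capsules onto the grid: later cells overwrite earlier ones.

    A voxel is labeled with a cell's 1-based index iff its center lies within
    ``diameter/2`` of the cell's axis segment.  Per-slice true occupancy is
    the labeled-voxel fraction over the full field.
    """
    labels = np.zeros(grid.shape, dtype=np.int32)
    for i, cell in enumerate(cells, start=1):
        _paint_cell(labels, cell, grid, i)
    occ = (labels > 0).mean(axis=(1, 2))
    return GroundTruth(cells=list(cells), labels=labels, grid=grid, occupancy=occ)


def sample_scene_to_occupancy(
    spec: SceneSpec,
    target_fraction: float,
    *,
    slice_percentile: float = 50.0,
    tolerance: float = 0.005,
    rng: np.random.Generator | None = None,
    max_cells: int = 5000,
) -> tuple[list[CellSpec], GroundTruth]:
    """Add cells until the colony's percentile-selected slice hits a target
    true occupancy.

    The monitored slice is chosen by ``slice_percentile`` of the occupied
    z-slice indices (10/50/90 operationalize bottom / mid-height / top of the
    colony).  Cells are added one at a time (rasterized incrementally) and
    sampling stops at the first crossing of the target, so the calibrated
    occupancy overshoots it by at most one cell's cross-section;
    ``tolerance`` bounds the acceptable overshoot.  A
    :class:`PlacementError` is raised if the target is not reachable within
    ``max_cells`` or the overshoot exceeds the tolerance.
    """
    if not (0 < target_fraction < 1):
        raise ValueError("target_fraction must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.overlap_policy != "reject":
        raise ValueError("occupancy calibration requires overlap_policy='reject'")
    grid = spec.grid
    labels = np.zeros(grid.shape, dtype=np.int32)
    cells: list[CellSpec] = []
    nz = grid.shape[0]
    per_slice = float(grid.shape[1] * grid.shape[2])
    counts = np.zeros(nz, dtype=np.int64)
    placed = _PlacedGeometry()
    while len(cells) < max_cells:
        cell = _place_one(spec, rng, placed)
        cells.append(cell)
        z0, painted = _paint_cell(labels, cell, grid, len(cells))
        counts[z0 : z0 + painted.size] += painted  # exact: reject policy, no overlap
        occ = counts / per_slice
        occupied = np.flatnonzero(counts > 0)
        if occupied.size == 0:
            continue
        zi = int(np.percentile(occupied, slice_percentile, method="nearest"))
        if occ[zi] >= target_fraction:
            if occ[zi] - target_fraction > tolerance:
                raise PlacementError(
                    f"occupancy overshot the target by {occ[zi] - target_fraction:.4f} "
                    f"(> tolerance {tolerance}); use smaller cells or a larger field"
                )
            truth = GroundTruth(cells=cells, labels=labels, grid=grid, occupancy=occ)
            return cells, truth
    raise PlacementError(
        f"occupancy target {target_fraction:.3f} not reached with {max_cells} cells"
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_stack(
    truth: GroundTruth,
    imaging: ImagingSpec,
    interface: Interface | None = None,
    *,
    grid: Grid | None = None,
) -> ZStack:
    """Render a CRM-like z-stack from a rasterized scene.

    Image formation: baseline + cell reflection (``cell_intensity_scale x
    reflectivity`` inside cells) + interface reflection (an axial Gaussian of
    FWHM ``psf_axial_fwhm`` centered at z = 0, uniform in x,y, with amplitude
    Fresnel reflectance x ``reflectance_to_intensity_gain``), convolved with
    an anisotropic Gaussian PSF, then shot noise, read noise, and clipping to
    [0, saturation].  Deterministic given ``imaging.seed``.

    If ``interface`` is given its Fresnel reflectance overrides
    ``imaging.interface_reflectance``.
    """
    if grid is not None and grid != truth.grid:
        raise GridMismatchError("requested stack grid differs from ground-truth grid")
    grid = truth.grid

    reflectance = imaging.interface_reflectance
    if interface is not None:
        reflectance = fresnel_reflectance(interface)

    signal = np.zeros(grid.shape, dtype=np.float64)
    if truth.cells:
        refl = np.array([0.0] + [c.reflectivity for c in truth.cells])
        signal = imaging.cell_intensity_scale * refl[truth.labels]

    amp = reflectance * imaging.reflectance_to_intensity_gain
    if amp > 0:
        z = grid.z_centers_um
        axial = amp * np.exp(-4.0 * math.log(2.0) * (z / imaging.psf_axial_fwhm_um) ** 2)
        signal += axial[:, None, None]

    sigma_z = imaging.psf_axial_fwhm_um * GAUSS_FWHM_TO_SIGMA / grid.voxel_z_um
    sigma_xy = imaging.psf_lateral_fwhm_um * GAUSS_FWHM_TO_SIGMA / grid.voxel_xy_um
    blurred = ndimage.gaussian_filter(signal, sigma=(sigma_z, sigma_xy, sigma_xy), mode="nearest")

    img = blurred + imaging.baseline
    if imaging.poisson_gain > 0 or imaging.read_noise_sd > 0:
        rng = np.random.default_rng(imaging.seed)
        if imaging.poisson_gain > 0:
            img = rng.poisson(np.clip(img, 0, None) * imaging.poisson_gain) / imaging.poisson_gain
        if imaging.read_noise_sd > 0:
            img = img + rng.normal(0.0, imaging.read_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, imaging.saturation_level)
    return ZStack(data=img.astype(np.float32), grid=grid)


def simulate_stack(
    scene: SceneSpec, imaging: ImagingSpec, interface: Interface | None = None
) -> tuple[ZStack, GroundTruth]:
    """Convenience: sample a scene, rasterize it, and render the stack."""
    cells = sample_scene(scene)
    truth = rasterize_cells(cells, scene.grid)
    stack = render_stack(truth, imaging, interface)
    return stack, truth
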