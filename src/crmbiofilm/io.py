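"""Reading and writing stacks, ground truth, and tables.

Stacks go to OME-TIFF with physical voxel sizes in the OME metadata; the
grid's interface-anchored z geometry additionally rides in a small JSON
sidecar (``<stem>.meta.json``) so round-trips do not depend on OME XML
parsing.  Ground truth is a plain CSV of per-cell geometry plus a TIFF label
volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import CellSpec, GroundTruth, Grid, ZStack, rasterize_cells

__all__ = [
    "TruthParseError",
    "write_stack",
    "read_stack",
    "write_truth",
    "read_truth",
    "write_measurements",
    "MEASUREMENT_COLUMNS",
    "TRUTH_COLUMNS",
]


class TruthParseError(ValueError):
    """A ground-truth or metadata file is malformed."""


TRUTH_COLUMNS = [
    "id",
    "x_um",
    "y_um",
    "z_um",
    "length_um",
    "diameter_um",
    "axis_x",
    "axis_y",
    "axis_z",
]

MEASUREMENT_COLUMNS = [
    "label",
    "x_um",
    "y_um",
    "z_um",
    "volume_um3",
    "axis_x",
    "axis_y",
    "axis_z",
    "elongation",
    "pitch_deg",
    "flag_isotropic",
]


def _grid_meta(grid: Grid) -> dict:
    return {
        "extent_um": list(grid.extent_um),
        "voxel_xy_um": grid.voxel_xy_um,
        "voxel_z_um": grid.voxel_z_um,
        "z_below_um": grid.z_below_um,
        "z_origin_index": grid.z_origin,
    }


def _grid_from_meta(meta: dict) -> Grid:
    try:
        return Grid(
            extent_um=tuple(meta["extent_um"]),
            voxel_xy_um=meta["voxel_xy_um"],
            voxel_z_um=meta["voxel_z_um"],
            z_below_um=meta["z_below_um"],
        )
    except KeyError as exc:
        raise TruthParseError(f"metadata missing key {exc.args[0]!r}") from exc


def write_stack(stack: ZStack, path: str | Path) -> Path:
    """Write a ZStack as OME-TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    meta = _grid_meta(stack.grid)
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": stack.grid.voxel_xy_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.grid.voxel_xy_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.grid.voxel_z_um,
            "PhysicalSizeZUnit": "µm",
        },
    )
    sidecar = Path(str(path) + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> ZStack:
    """Read a stack written by :func:`write_stack`.

    The JSON sidecar is preferred; if absent, grid geometry is recovered
    from the TIFF description tag.  A stack without either raises
    :class:`TruthParseError` (voxel geometry is required downstream).
    """
    path = Path(path)
    data = tifffile.imread(path)
    meta = None
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description or ""
        for candidate in (desc,):
            try:
                parsed = json.loads(candidate)
            except (json.JSONDecodeError, TypeError):
                continue
            if isinstance(parsed, dict) and "voxel_z_um" in parsed:
                meta = parsed
    if meta is None:
        raise TruthParseError(
            f"no voxel-size metadata found for {path} (need the .meta.json sidecar)"
        )
    return ZStack(data=np.asarray(data, dtype=np.float32), grid=_grid_from_meta(meta))


def write_truth(truth: GroundTruth, prefix: str | Path) -> dict[str, Path]:
    """Write ground truth: ``<prefix>.cells.csv``, ``<prefix>.labels.tif``,
    ``<prefix>.meta.json``.  Returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, c in enumerate(truth.cells, start=1):
        rows.append(
            {
                "id": i,
                "x_um": c.centroid_um[0],
                "y_um": c.centroid_um[1],
                "z_um": c.centroid_um[2],
                "length_um": c.length_um,
                "diameter_um": c.diameter_um,
                "axis_x": c.axis[0],
                "axis_y": c.axis[1],
                "axis_z": c.axis[2],
                "reflectivity": c.reflectivity,
            }
        )
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS + ["reflectivity"])
    csv_path = Path(str(prefix) + ".cells.csv")
    df.to_csv(csv_path, index=False, float_format="%.12g")
    labels_path = Path(str(prefix) + ".labels.tif")
    tifffile.imwrite(labels_path, truth.labels.astype(np.int32))
    meta_path = Path(str(prefix) + ".meta.json")
    meta_path.write_text(json.dumps(_grid_meta(truth.grid), indent=1))
    return {"cells": csv_path, "labels": labels_path, "meta": meta_path}


def read_truth(prefix: str | Path) -> GroundTruth:
    """Read ground truth written by :func:`write_truth` (round-trip exact).

    A missing required column raises :class:`TruthParseError` naming it.  If
    the label-volume TIFF is absent the cells are re-rasterized on the grid.
    """
    prefix = Path(prefix)
    csv_path = Path(str(prefix) + ".cells.csv")
    meta_path = Path(str(prefix) + ".meta.json")
    labels_path = Path(str(prefix) + ".labels.tif")
    if not csv_path.exists():
        raise TruthParseError(f"missing ground-truth table {csv_path}")
    if not meta_path.exists():
        raise TruthParseError(f"missing ground-truth metadata {meta_path}")
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.ParserError as exc:
        raise TruthParseError(f"malformed CSV {csv_path}: {exc}") from exc
    for col in TRUTH_COLUMNS:
        if col not in df.columns:
            raise TruthParseError(f"missing column {col!r} in {csv_path}")
    grid = _grid_from_meta(json.loads(meta_path.read_text()))
    cells = []
    for row in df.itertuples(index=False):
        axis = np.array([row.axis_x, row.axis_y, row.axis_z], dtype=float)
        axis = axis / np.linalg.norm(axis)  # guard against CSV rounding
        cells.append(
            CellSpec(
                centroid_um=(row.x_um, row.y_um, row.z_um),
                length_um=row.length_um,
                diameter_um=row.diameter_um,
                axis=tuple(axis),
                reflectivity=getattr(row, "reflectivity", 1.0),
            )
        )
    if labels_path.exists():
        labels = np.asarray(tifffile.imread(labels_path), dtype=np.int32)
        labels = labels.reshape(grid.shape)
        occ = (labels > 0).mean(axis=(1, 2))
        return GroundTruth(cells=cells, labels=labels, grid=grid, occupancy=occ)
    return rasterize_cells(cells, grid)


def write_measurements(df: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-cell measurement table with its fixed public columns."""
    path = Path(path)
    df.loc[:, MEASUREMENT_COLUMNS].to_csv(path, index=False, float_format="%.9g")
    return path
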