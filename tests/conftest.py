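"""Shared synthetic fixtures: small scenes rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

import crmbiofilm as cb

IMM = cb.Interface(1.33, 1.333)
GLASS = cb.Interface(1.5255, 1.333)
NOISE_FREE = cb.ImagingSpec(poisson_gain=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def imm_interface():
    return IMM


@pytest.fixture(scope="session")
def glass_interface():
    return GLASS


@pytest.fixture(scope="session")
def layered_scene():
    """Small laminated scene with comfortably separated cells."""
    return cb.SceneSpec(
        extent_um=(30.0, 30.0, 10.0),
        cell_count=12,
        orientation_model="layered",
        pitch_sigma_deg=19.8,
        min_gap_um=1.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def layered_truth(layered_scene):
    cells = cb.sample_scene(layered_scene)
    return cb.rasterize_cells(cells, layered_scene.grid)


@pytest.fixture(scope="session")
def imm_stack_noise_free(layered_truth):
    return cb.render_stack(layered_truth, NOISE_FREE, IMM)


@pytest.fixture(scope="session")
def imm_stack_noisy(layered_truth):
    return cb.render_stack(layered_truth, cb.ImagingSpec(seed=5), IMM)


@pytest.fixture(scope="session")
def glass_stack_noise_free(layered_truth):
    return cb.render_stack(layered_truth, NOISE_FREE, GLASS)


@pytest.fixture(scope="session")
def labels_noise_free(imm_stack_noise_free):
    params = cb.SegmentationParams(exclude_slices_below_um=0.0)
    return cb.segment_cells(imm_stack_noise_free, params)


@pytest.fixture(scope="session")
def blank_truth(layered_scene):
    return cb.rasterize_cells([], layered_scene.grid)


def make_capsule(pitch_deg, yaw_deg=0.0, length=6.0, diameter=0.8,
                 centroid=(15.0, 15.0, 6.0)):
    """A single spherocylinder at a prescribed pitch (degrees)."""
    p = np.radians(pitch_deg)
    y = np.radians(yaw_deg)
    axis = (np.cos(p) * np.cos(y), np.cos(p) * np.sin(y), np.sin(p))
    return cb.CellSpec(centroid_um=centroid, length_um=length,
                       diameter_um=diameter, axis=tuple(axis))
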