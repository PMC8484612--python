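"""Experiment orchestration: YAML config -> simulate -> analyze -> report.

One :class:`ExperimentConfig` describes a full run; a single global seed is
fanned out into named substreams (scene, noise, sbr) so stages are
reproducible without seed collisions, and every run writes a manifest of the
artifacts it produced and the seeds it actually used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as crmio
from .morphometrics import (
    angle_summary,
    axial_intensity_profile,
    colony_roi,
    colony_slice_indices,
    density_heatmap,
    measure_cells,
    occupancy_profile,
    signal_background_ratio,
)
from .optics import Interface
from .segment import SegmentationParams, _region_mask, locate_interface, segment_cells
from .simulate import ImagingSpec, SceneSpec, rasterize_cells, render_stack, sample_scene

__all__ = [
    "AnalysisParams",
    "ExperimentConfig",
    "ConfigError",
    "RunManifest",
    "derive_seeds",
    "cmd_simulate",
    "cmd_analyze",
    "cmd_report",
]

logger = logging.getLogger("crmbiofilm")


class ConfigError(ValueError):
    """An experiment configuration is malformed; the message names the key."""


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the analysis stage (ROI, tiling, angle thresholds, SBR)."""

    tile_um: float = 2.4
    pitch_thresholds_deg: tuple[float, ...] = (30.0, 45.0)
    z_offset_um: float = 1.0
    n_regions: int = 20
    roi: tuple[int, int, int, int] | None = None  # (y0, y1, x0, x1) voxels
    roi_dilate_um: float = 0.8


@dataclass
class ExperimentConfig:
    """Everything needed for one reproducible simulate + analyze run."""

    scene: SceneSpec = field(default_factory=SceneSpec)
    imaging: ImagingSpec = field(default_factory=ImagingSpec)
    interface: Interface = field(default_factory=lambda: Interface(1.333, 1.333))
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    output_dir: str = "crm_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        sections = {
            "scene": SceneSpec,
            "imaging": ImagingSpec,
            "interface": Interface,
            "segmentation": SegmentationParams,
            "analysis": AnalysisParams,
        }
        kwargs: dict = {}
        for key, value in raw.items():
            if key in ("output_dir", "seed"):
                kwargs[key] = value
            elif key in sections:
                if not isinstance(value, dict):
                    raise ConfigError(f"section '{key}' must be a mapping")
                kwargs[key] = _build_section(sections[key], key, value)
            else:
                raise ConfigError(f"unknown config key '{key}'")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists for YAML/JSON

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_section(cls, section: str, value: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    for k in value:
        if k not in fields:
            raise ConfigError(f"unknown key '{section}.{k}'")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


@dataclass
class RunManifest:
    """What a run produced: config hash, artifacts, seeds, stage status."""

    config_hash: str
    tool_version: str
    seeds: dict[str, int]
    artifacts: dict[str, str] = field(default_factory=dict)
    stages: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Fan one global seed into named, collision-free substreams (< 2^31)."""
    children = np.random.SeedSequence(global_seed).spawn(3)
    names = ("scene", "noise", "sbr")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _version() -> str:
    from . import __version__

    return __version__


def cmd_simulate(config: ExperimentConfig, output_dir: str | Path | None = None) -> RunManifest:
    """Simulate a stack + ground truth per config and write all artifacts."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    scene = dataclasses.replace(config.scene, seed=seeds["scene"])
    imaging = dataclasses.replace(config.imaging, seed=seeds["noise"])

    logger.info("sampling scene (%d cells, %s model)", scene.cell_count, scene.orientation_model)
    cells = sample_scene(scene)
    truth = rasterize_cells(cells, scene.grid)
    logger.info("rendering stack %s", truth.grid.shape)
    stack = render_stack(truth, imaging, config.interface)

    manifest = RunManifest(
        config_hash=config.config_hash(), tool_version=_version(), seeds=seeds
    )
    stack_path = outdir / "stack.ome.tif"
    crmio.write_stack(stack, stack_path)
    truth_paths = crmio.write_truth(truth, outdir / "truth")
    config.to_yaml(outdir / "config.yaml")
    manifest.artifacts = {
        "stack": str(stack_path),
        "config": str(outdir / "config.yaml"),
        **{f"truth_{k}": str(v) for k, v in truth_paths.items()},
    }
    manifest.stages["simulate"] = "ok"
    manifest.save(outdir / "manifest.json")
    return manifest


def cmd_analyze(
    stack_path: str | Path,
    config: ExperimentConfig,
    output_dir: str | Path | None = None,
    truth_prefix: str | Path | None = None,
) -> dict:
    """Segment and measure a stack; write tables and a summary JSON.

    If a ground-truth prefix is supplied, the summary gains a ``recovery``
    section with absolute estimate-vs-truth errors per headline metric.
    """
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    stack = crmio.read_stack(stack_path)

    interface_loc = locate_interface(stack)
    labels = segment_cells(stack, config.segmentation)
    logger.info("segmented %d components", labels.n_labels)
    table = measure_cells(labels)
    elongated = table[~table.flag_isotropic]
    summary_angles = angle_summary(
        elongated.pitch_deg, config.analysis.pitch_thresholds_deg
    )

    roi_mask = None
    if config.analysis.roi is not None:
        roi_mask = _region_mask(config.analysis.roi, labels.labels.shape[1:])
    elif labels.n_labels:
        roi_mask = colony_roi(labels, config.analysis.roi_dilate_um)
    occ = None
    occ_points = {}
    if labels.n_labels:
        occ = occupancy_profile(labels, roi_mask)
        idx = colony_slice_indices(occ.occupancy.to_numpy())
        occ_points = {
            k: {"z_um": float(occ.z_um[i]), "occupancy": float(occ.occupancy[i])}
            for k, i in idx.items()
        }

    sbr = None
    try:
        if labels.n_labels:
            res = signal_background_ratio(
                stack,
                labels,
                config.analysis.z_offset_um,
                config.analysis.n_regions,
                seed=seeds["sbr"],
            )
            sbr = dataclasses.asdict(res)
    except ValueError as exc:
        logger.warning("SBR not computed: %s", exc)

    summary = {
        "label_count": labels.n_labels,
        "n_cells_measured": int(len(table)),
        "n_elongated": int(len(elongated)),
        "interface": {
            "z_index": interface_loc.z_index,
            "peak_found": interface_loc.peak_found,
        },
        "pitch": summary_angles,
        "occupancy": occ_points,
        "sbr": sbr,
        "seeds": seeds,
    }

    if truth_prefix is not None:
        truth = crmio.read_truth(truth_prefix)
        true_pitches = [c.pitch_deg for c in truth.cells]
        true_sum = angle_summary(true_pitches, config.analysis.pitch_thresholds_deg)
        recovery = {"n_true_cells": len(truth.cells)}
        if summary_angles["mean_deg"] is not None and true_sum["mean_deg"] is not None:
            recovery["mean_pitch_abs_error_deg"] = abs(
                summary_angles["mean_deg"] - true_sum["mean_deg"]
            )
            recovery["frac_below_abs_error"] = {
                str(t): abs(summary_angles["frac_below"][t] - true_sum["frac_below"][t])
                for t in summary_angles["frac_below"]
            }
        if occ is not None and roi_mask is not None:
            mid = colony_slice_indices(occ.occupancy.to_numpy())["mid"]
            true_occ_mid = float((truth.labels[mid][roi_mask] > 0).mean())
            recovery["mid_occupancy_abs_error"] = abs(
                occ_points["mid"]["occupancy"] - true_occ_mid
            )
        summary["recovery"] = recovery

    crmio.write_measurements(table, outdir / "measurements.csv")
    table.to_csv(outdir / "measurements_full.csv", index=False)
    if occ is not None:
        occ.to_csv(outdir / "occupancy_profile.csv", index=False)
    if labels.n_labels:
        np.save(outdir / "heatmap.npy", density_heatmap(labels, config.analysis.tile_um))
    axial_intensity_profile(stack).to_csv(outdir / "axial_profile.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary


def cmd_report(run_dir: str | Path) -> Path:
    """Render figures + a markdown report page from an analyzed run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    stack_path = run_dir / "stack.ome.tif"
    meas_path = run_dir / "measurements_full.csv"
    if not meas_path.exists():
        raise FileNotFoundError(f"no analysis outputs in {run_dir} (missing {meas_path})")
    table = pd.read_csv(meas_path)
    figures: list[str] = []
    lines = ["# CRM biofilm analysis report", ""]

    occ_path = run_dir / "occupancy_profile.csv"
    if occ_path.exists():
        occ = pd.read_csv(occ_path)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(occ.z_um, 100 * occ.occupancy)
        ax.set_xlabel("z from interface (µm)")
        ax.set_ylabel("area occupation (%)")
        fig.tight_layout()
        fig.savefig(run_dir / "occupancy_vs_z.png", dpi=120)
        plt.close(fig)
        figures.append("occupancy_vs_z.png")

    if len(table):
        fig, ax = plt.subplots(figsize=(4, 3))
        sub = table[~table.flag_isotropic]
        ax.scatter(sub.pitch_deg, sub.z_um, s=12, alpha=0.6)
        ax.set_xlabel("pitch angle (°)")
        ax.set_ylabel("cell centroid z (µm)")
        ax.set_xlim(0, 90)
        fig.tight_layout()
        fig.savefig(run_dir / "pitch_vs_z.png", dpi=120)
        plt.close(fig)
        figures.append("pitch_vs_z.png")
    else:
        lines.append("**No cells measured.**")

    axial_path = run_dir / "axial_profile.csv"
    if axial_path.exists():
        prof = pd.read_csv(axial_path)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(prof.z_um, prof.mean_intensity)
        ax.set_xlabel("z from interface (µm)")
        ax.set_ylabel("mean intensity (a.u.)")
        fig.tight_layout()
        fig.savefig(run_dir / "axial_profile.png", dpi=120)
        plt.close(fig)
        figures.append("axial_profile.png")

    heatmap_path = run_dir / "heatmap.npy"
    if heatmap_path.exists():
        hm = np.load(heatmap_path)
        picks = np.linspace(0, hm.shape[0] - 1, min(4, hm.shape[0])).astype(int)
        fig, axes = plt.subplots(1, len(picks), figsize=(3 * len(picks), 3))
        for ax, zi in zip(np.atleast_1d(axes), picks):
            im = ax.imshow(hm[zi], vmin=0, vmax=max(hm.max(), 1e-6), cmap="inferno",
                           origin="lower")
            ax.set_title(f"slice {zi}")
            ax.axis("off")
        fig.colorbar(im, ax=np.atleast_1d(axes).tolist(), shrink=0.8, label="occupancy")
        fig.savefig(run_dir / "heatmap_montage.png", dpi=120)
        plt.close(fig)
        figures.append("heatmap_montage.png")

    if stack_path.exists():
        stack = crmio.read_stack(stack_path)
        mip = stack.data.max(axis=0)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(mip, cmap="gray", origin="lower")
        ax.set_title("maximum-intensity projection")
        ax.axis("off")
        fig.tight_layout()
        fig.savefig(run_dir / "mip.png", dpi=120)
        plt.close(fig)
        figures.append("mip.png")

    summary_path = run_dir / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        lines.append("## Summary")
        lines.append("```json")
        lines.append(json.dumps(summary, indent=1))
        lines.append("```")
        if "recovery" not in summary:
            pass  # no ground truth: recovery section omitted
        else:
            lines.append("## Recovery vs ground truth")
            lines.append("```json")
            lines.append(json.dumps(summary["recovery"], indent=1))
            lines.append("```")

    lines.append("## Figures")
    for f in figures:
        lines.append(f"![{f}]({f})")
    report = run_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
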