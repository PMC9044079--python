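"""End-to-end wiring: scene cloud -> grain segments -> 32-trait table.

``run_pipeline`` reproduces the full measurement chain on a merged stage
scene: voxel downsampling, principal-axis normalization, RANSAC stage
removal, statistical outlier removal, region-growing grain segmentation
and per-grain trait extraction.  ``extract_grain_traits`` is the
single-grain half, usable directly on an isolated grain cloud.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import pandas as pd

from .cloud_io import PointCloud
from .geometry import (
    align_grain,
    enclosed_volume,
    obb_dimensions,
    projected_outline,
    reconstruct_surface,
    surface_area,
)
from .preprocess import pca_align, remove_outliers, voxel_downsample
from .segmentation import fit_stage_plane, remove_stage, segment_grains
from .sulcus import measure_profile, select_max_hull_slice, slice_grain
from .traits import assemble_traits

log = logging.getLogger("grain3d")

__all__ = ["PipelineConfig", "extract_grain_traits", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable of the measurement chain, with field-ready defaults."""

    # preprocess
    voxel_size_mm: float = 0.1
    outlier_k: int = 20
    outlier_std_ratio: float = 2.0
    # stage plane
    ransac_threshold_mm: float = 0.15
    ransac_iterations: int = 1000
    ransac_seed: int = 0
    # region growing
    rg_k: int = 30
    rg_angle_deg: float = 12.0
    rg_curvature: float = 1.0
    cluster_min: int = 500
    cluster_max: int = 20000
    # projections
    outline_edge_factor: float = 3.0
    # sulcus
    n_slices: int = 9
    slice_interval_mm: float = 0.4
    slab_thickness_mm: float = 0.4
    circle_threshold_mm: float = 0.3
    circle_iterations: int = 500
    circle_seed: int = 0
    # volume
    hole_fill_max_edges: int = 30

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def extract_grain_traits(cloud: PointCloud, config: PipelineConfig | None = None):
    """Measure all 32 traits of one isolated grain cloud.

    Returns (trait record dict, AlignedGrain).  Raises when the grain is
    degenerate (too few points, too short for slicing, ...).
    """
    cfg = config or PipelineConfig()
    grain = align_grain(cloud)
    l, w, h = obb_dimensions(grain)
    mesh = reconstruct_surface(grain.cloud)
    area = surface_area(mesh)
    volume = enclosed_volume(mesh, hole_fill_max_edges=cfg.hole_fill_max_edges)
    outlines = {ax: projected_outline(grain, ax, edge_factor=cfg.outline_edge_factor)
                for ax in ("X", "Y", "Z")}
    profiles = slice_grain(
        grain, n_slices=cfg.n_slices, interval=cfg.slice_interval_mm,
        slab_thickness=cfg.slab_thickness_mm,
    )
    best = select_max_hull_slice(profiles)
    measure_profile(
        best, circle_threshold=cfg.circle_threshold_mm,
        circle_iterations=cfg.circle_iterations, circle_seed=cfg.circle_seed,
    )
    record = assemble_traits(l, w, h, volume, area, outlines, best)
    return record, grain


def run_pipeline(cloud: PointCloud, config: PipelineConfig | None = None):
    """Scene cloud -> (trait table, per-grain segment clouds, report dict).

    The report logs per-stage point counts (monotone non-increasing through
    preprocessing, plane removal and segmentation) and any per-grain
    failures; grains whose trait extraction fails are skipped with a
    warning rather than aborting the run.
    """
    cfg = config or PipelineConfig()
    if len(cloud) == 0:
        raise ValueError("no points in input cloud")
    report: dict = {"counts": {"input": len(cloud)}, "warnings": []}

    down = voxel_downsample(cloud, cfg.voxel_size_mm)
    report["counts"]["downsampled"] = len(down)
    aligned, _ = pca_align(down)

    plane = fit_stage_plane(
        aligned, distance_threshold=cfg.ransac_threshold_mm,
        max_iterations=cfg.ransac_iterations, seed=cfg.ransac_seed,
    )
    report["counts"]["stage_inliers"] = int(len(plane.inlier_indices))
    grains_cloud = remove_stage(aligned, plane, distance_threshold=cfg.ransac_threshold_mm)
    report["counts"]["after_stage_removal"] = len(grains_cloud)
    if len(grains_cloud) > cfg.outlier_k:
        grains_cloud = remove_outliers(grains_cloud, cfg.outlier_k, cfg.outlier_std_ratio)
    report["counts"]["after_outlier_removal"] = len(grains_cloud)
    if len(grains_cloud) == 0:
        raise ValueError("no grain points left after stage removal")

    segments = segment_grains(
        grains_cloud, k_neighbors=cfg.rg_k, angle_threshold=cfg.rg_angle_deg,
        curvature_threshold=cfg.rg_curvature, min_cluster_size=cfg.cluster_min,
        max_cluster_size=cfg.cluster_max,
    )
    report["counts"]["segments"] = len(segments)
    if not segments:
        raise ValueError("no grains found (all clusters filtered out)")

    rows = []
    segment_clouds = []
    for seg in segments:
        sub = grains_cloud.select(seg.indices)
        segment_clouds.append(sub)
        try:
            record, _ = extract_grain_traits(sub, cfg)
        except (ValueError, ZeroDivisionError) as exc:
            msg = f"grain {seg.label}: trait extraction failed: {exc}"
            log.warning(msg)
            report["warnings"].append(msg)
            continue
        rows.append({"id": seg.label, **record})
    table = pd.DataFrame(rows)
    report["n_grains_measured"] = len(rows)
    log.info(
        "pipeline: %d input -> %d after stage removal -> %d segments -> %d measured",
        report["counts"]["input"], report["counts"]["after_stage_removal"],
        len(segments), len(rows),
    )
    return table, segment_clouds, report
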