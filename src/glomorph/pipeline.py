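"""End-to-end glue: raw stack -> labels -> meshes -> feature table.

This is the per-volume path used by the cohort experiment and the CLI:
interpolate to isotropic sampling, Otsu binarize, refine with the geodesic
active contour, separate instances with the ellipsoid-fit gate, drop
edge-touching objects, randomly sample glomeruli, mesh each one and run
the morphometry.  The central base point of each glomerulus is located
from the label field itself: the voxels where the instance touches the
rest of the segmented foreground (its vascular attachment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import meshing, morphometry, segment
from .types import LabelMap, VolumeStack

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "segment_volume", "analyze_volume", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = ["id", "volume_um3", "hmax_um", "hmin_um", "nmax_um", "L_um",
                   "orientation_z", "orientation_y", "orientation_x"]


@dataclass
class PipelineConfig:
    """Every tunable of the detection + morphometry chain, with defaults."""

    bright_foreground: bool = True
    gac_iterations: int = 20
    gac_smoothing: int = 1
    gac_balloon: float = 0.0
    gac_sigma: float = 1.0
    fit_residual_max: float = 0.3
    min_volume: float = 5000.0
    max_axis_ratio: float = 3.0
    marker_h_um: float = 1.0
    instance_smoothing_sigma_um: float = 2.0
    edge_margin_frac: float = 0.05     # fraction of the smallest axis extent
    n_sample: int = 10
    step_height_um: float | None = None  # default: 2 × in-plane voxel size
    mesh_smooth_iterations: int = 10
    mesh_smooth_step: float = 0.1
    head_mode: str = "single_step"
    neck_mode: str = "waist"
    neck_fraction: float = 0.8

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def segment_volume(volume: VolumeStack, config: PipelineConfig | None = None
                   ) -> tuple[LabelMap, np.ndarray, VolumeStack]:
    """Run the detection chain; returns (labels, refined mask, iso volume)."""
    config = config or PipelineConfig()
    iso = segment.interpolate_isotropic(volume)
    mask = segment.binarize_otsu(iso, bright_foreground=config.bright_foreground)
    refined = segment.refine_geodesic_active_contour(
        iso, mask, iterations=config.gac_iterations, smoothing=config.gac_smoothing,
        balloon=config.gac_balloon, sigma=config.gac_sigma,
    )
    if not refined.any():
        refined = mask
    labels = segment.separate_instances_ellipse_fit(
        refined, iso,
        fit_residual_max=config.fit_residual_max,
        min_volume=config.min_volume,
        max_axis_ratio=config.max_axis_ratio,
        marker_h_um=config.marker_h_um,
        smoothing_sigma_um=config.instance_smoothing_sigma_um,
    )
    margin = config.edge_margin_frac * min(
        (n - 1) * s for n, s in zip(iso.shape, iso.voxel_size)
    )
    labels = segment.exclude_edge_objects(labels, margin)
    return labels, refined, iso


def _attachment_reference(labels: LabelMap, instance_id: int, foreground: np.ndarray):
    """World point where the instance touches the rest of the foreground.

    Returns None when the instance is isolated (no vascular attachment in
    the mask); the caller then falls back to the thin-end heuristic.
    """
    inst = labels.labels == instance_id
    other = foreground & ~inst
    ring = ndi.binary_dilation(inst, iterations=2) & other
    if not ring.any():
        return None
    pts = np.argwhere(ring) * np.asarray(labels.voxel_size)
    return pts.mean(axis=0)


def _thin_end_reference(labels: LabelMap, instance_id: int):
    """Fallback base point: centre of the thinner end along the principal axis."""
    idx = np.argwhere(labels.labels == instance_id).astype(float)
    pts = idx * np.asarray(labels.voxel_size)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    t = d @ axis
    lo, hi = np.quantile(t, [0.1, 0.9])
    for sel_lo, sel_hi in [(t <= lo, t >= hi)]:
        r_lo = np.linalg.norm(d[sel_lo] - np.outer(t[sel_lo], axis), axis=1).mean()
        r_hi = np.linalg.norm(d[sel_hi] - np.outer(t[sel_hi], axis), axis=1).mean()
    return pts[t <= lo].mean(axis=0) if r_lo <= r_hi else pts[t >= hi].mean(axis=0)


def analyze_volume(
    volume: VolumeStack,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-volume analysis: returns one feature row per sampled glomerulus.

    Volumes in which no instance survives the gates yield an empty table.
    Per-glomerulus failures are logged and skipped, mirroring interactive
    proofreading where undecodable objects are discarded.
    """
    config = config or PipelineConfig()
    labels, refined, iso = segment_volume(volume, config)
    if labels.n_instances == 0:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    ids = segment.sample_glomeruli(labels, config.n_sample, seed=seed)
    step_h = config.step_height_um or 2.0 * min(iso.voxel_size[1], iso.voxel_size[2])
    rows = []
    for gid in ids:
        try:
            ref = _attachment_reference(labels, gid, refined)
            if ref is None:
                ref = _thin_end_reference(labels, gid)
            mesh = meshing.mesh_from_label(labels, gid)
            rec = morphometry.glomerulus_features(
                mesh, base_reference=ref, step_height=step_h, glomerulus_id=gid,
                head_mode=config.head_mode, neck_mode=config.neck_mode,
                neck_fraction=config.neck_fraction,
                smooth_iterations=config.mesh_smooth_iterations,
                smooth_step=config.mesh_smooth_step,
            )
            rows.append(rec.to_dict())
        except Exception as exc:  # noqa: BLE001 - per-object robustness
            logger.warning("glomerulus %d failed: %s", gid, exc)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
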