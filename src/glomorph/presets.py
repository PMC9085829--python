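"""Shared phantom/pipeline presets.

Two regimes are bundled:

* :func:`default_phantom_spec` — full-scale conditions: 1 µm in-plane
  sampling with 4 µm z steps and mouse-kidney-like glomerulus sizes
  (head semi-axes ≈ 30–35 µm, necks ≈ 8 µm radius).
* :func:`reduced_cohort_spec` / :func:`reduced_pipeline_config` — the
  small-scale regime used for repeated cohort simulations: a
  (20, 64, 64)-voxel stack at (4, 2, 2) µm holding two glomeruli with
  head semi-axes 14 ± 1.4 µm and neck radius 6 ± 0.6 µm, chosen so the
  thinnest structure (the neck) still spans three in-plane voxels and a
  full detection→meshing→morphometry pass stays below a second.
"""

from __future__ import annotations

from .pipeline import PipelineConfig
from .synthetic import PhantomSpec

__all__ = ["default_phantom_spec", "reduced_cohort_spec", "reduced_pipeline_config"]


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Full-scale phantom conditions (1 µm in-plane, 4 µm z)."""
    return PhantomSpec(**overrides)


def reduced_cohort_spec(**overrides) -> PhantomSpec:
    """Reduced-scale phantom for repeated cohort simulations."""
    base = dict(
        grid_shape=(20, 64, 64),
        voxel_size=(4.0, 2.0, 2.0),
        n_glomeruli=2,
        head_semi_axes_dist=(14.0, 1.4),
        neck_radius_dist=(6.0, 0.6),
        neck_length_dist=(16.0, 2.0),
        vessel_density=0.0,
        edge_margin=6.0,
        psf_sigma=1.5,
        noise_sigma=15.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def reduced_pipeline_config(**overrides) -> PipelineConfig:
    """Pipeline settings matched to :func:`reduced_cohort_spec`."""
    base = dict(
        gac_iterations=10,
        min_volume=3000.0,
        mesh_smooth_iterations=5,
    )
    base.update(overrides)
    return PipelineConfig(**base)
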