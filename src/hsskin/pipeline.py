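"""The raw-measurement processing chain, radiance to feature stack.

Stages, with the number of hyperspectral images alive after each (per
measurement): Radiance (6 radiance cubes + their 6 white references = 12)
-> Reflectance (6) -> Combine VIS+VNIR (3) -> Albedo and normal (2)
-> Depth and albedo (2) -> Spectral smoothing (2).  The product is one
33-band albedo cube plus one depth map, assembled into the 34-channel
feature stack the classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    FeatureStack,
    build_feature_stack,
    combine_vis_vnir,
    compute_reflectance,
    tv_denoise_spectral,
)
from .scenes import Measurement
from .stereo import (
    DEFAULT_CLAMP_NZ,
    DEFAULT_EPSILON,
    NormalAlbedoMap,
    frankot_chellappa,
    gradients_from_normals,
    light_direction_matrix,
    solve_albedo_normals,
)
from .wavelengths import DEFAULT_DEPTH_WAVELENGTH_NM

__all__ = ["PipelineResult", "process_measurement"]


@dataclass
class PipelineResult:
    """Everything the Table-style processing chain produces for one scene."""

    albedo: np.ndarray  # (H, W, 33), spectrally smoothed
    normal_map: NormalAlbedoMap
    depth: np.ndarray  # (H, W) zero-mean relative height at depth_wavelength
    depth_wavelength_nm: float
    stack: FeatureStack
    stage_counts: list = field(default_factory=list)  # [(stage name, n images)]


def process_measurement(
    meas: Measurement,
    tv_weight: float = 10.0,
    epsilon: float = DEFAULT_EPSILON,
    clamp_nz: float = DEFAULT_CLAMP_NZ,
    depth_wavelength_nm: float = DEFAULT_DEPTH_WAVELENGTH_NM,
    upright: bool = True,
    log=None,
) -> PipelineResult:
    """Run the full chain on one measurement.

    ``log`` is an optional callable receiving one line per stage with the
    image count after that stage.
    """
    counts = []

    def stage(name, n):
        counts.append((name, n))
        if log is not None:
            log(f"stage {name}: {n} HS images")

    n_rad = len(meas.radiance_vis) + len(meas.radiance_vnir)
    stage("radiance", n_rad + n_rad)  # radiance cubes plus their white refs

    refl = []
    for i in range(3):
        vis = compute_reflectance(
            meas.radiance_vis[i],
            meas.white_vis,
            meas.dark_vis,
            wavelengths=meas.wavelengths[: meas.radiance_vis[i].shape[-1]],
            light_direction_id=i,
        )
        vnir = compute_reflectance(
            meas.radiance_vnir[i],
            meas.white_vnir,
            meas.dark_vnir,
            wavelengths=meas.wavelengths[meas.radiance_vis[i].shape[-1] :],
            light_direction_id=i,
        )
        refl.append((vis, vnir))
    stage("reflectance", sum(len(pair) for pair in refl))

    combined = [combine_vis_vnir(vis, vnir) for vis, vnir in refl]
    stage("combine", len(combined))

    L = light_direction_matrix(meas.light_geometry)
    nmap = solve_albedo_normals(
        [c.values for c in combined], L, wavelengths=combined[0].wavelengths
    )
    stage("albedo and normal", 2)

    band = nmap.band(depth_wavelength_nm)
    grad = gradients_from_normals(nmap, clamp_nz=clamp_nz, band=band, negate=upright)
    depth = frankot_chellappa(grad, epsilon=epsilon).Z
    stage("depth and albedo", 2)

    albedo = tv_denoise_spectral(nmap.albedo, weight=tv_weight)
    stage("smoothening", 2)

    stack = build_feature_stack(
        albedo,
        {depth_wavelength_nm: depth},
        wavelengths=nmap.wavelengths,
        depth_wavelength_nm=depth_wavelength_nm,
    )
    return PipelineResult(
        albedo=albedo,
        normal_map=nmap,
        depth=depth,
        depth_wavelength_nm=float(depth_wavelength_nm),
        stack=stack,
        stage_counts=counts,
    )
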