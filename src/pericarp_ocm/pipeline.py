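"""End-to-end synthetic phenotyping study.

Chains every stage on simulated seeds: raster acquisition of the entire
upper seed, spectral reconstruction, analysis-slice and site geometry,
tangent-aligned zoomed acquisitions at the ten standard sites, en-face
lateral thickness estimation, apex axial estimation, and genotype-level
statistics — with per-site ground truth carried along for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .axial import AxialFailure, AxialFitConfig, measure_axial
from .axial import _surface_depth_map
from .geometry import (
    GeometryError,
    midline_and_sites,
    refine_site_slice,
    segment_enface,
)
from .lateral import EstimatorError, LateralConfig, ProfileBlock, measure_block
from .phantom import (
    GENOTYPES,
    GenotypeParams,
    OpticalConfig,
    ScanConfig,
    SeedPhantom,
    build_phantom,
    simulate_tomogram,
)
from .reconstruct import PipelineConfig, Tomogram, assemble_tomogram


@dataclass(frozen=True)
class StudyConfig:
    """Problem sizes of the reduced synthetic study.

    The full-scale instrument acquires 1000x1000 entire-seed grids and
    100x1000 zoomed blocks with 10 repeats; the reduced study keeps the same
    physical extents and pixel pitches that matter (1.55 um zoomed pitch) at
    grid sizes that run on one core in minutes.
    """

    seeds_per_genotype: int = 3
    entire_nx: int = 200
    entire_ny: int = 200
    entire_extent_mm: float = 5.4
    block_lines: int = 64
    block_samples: int = 256
    block_pitch_um: float = 1.55
    block_repeats: int = 1
    lateral_methods: tuple[str, ...] = ("threshold",)
    measure_axial: bool = True


def scan_origin_um(scan: ScanConfig) -> tuple[float, float]:
    """Lab coordinates of pixel (row 0, col 0) of an axis-aligned scan."""
    ox = scan.x_center_mm * 1e3 - 0.5 * (scan.nx - 1) * scan.dx_um
    oy = scan.y_center_mm * 1e3 - 0.5 * (scan.ny - 1) * scan.dy_um
    return ox, oy


def parametric_site_angles(
    phantom: SeedPhantom, x_um: float, y_um: float, z_um: float
) -> tuple[float, float]:
    """Parametric (theta, phi) in degrees of a surface point near the seed."""
    cx, cy, cz = phantom.center_um
    a, b, c = phantom.semi_axes_um
    xt, yt, zt = (x_um - cx) / a, (y_um - cy) / b, (z_um - cz) / c
    m = max(np.sqrt(xt**2 + yt**2 + zt**2), 1e-12)
    theta = np.degrees(np.arccos(np.clip(zt / m, -1, 1)))
    phi = np.degrees(np.arctan2(yt, xt))
    return float(theta), float(phi)


def acquire_and_reconstruct(
    phantom: SeedPhantom,
    optical: OpticalConfig,
    scan: ScanConfig,
    rng_seed: int,
    pipeline: PipelineConfig = PipelineConfig(),
) -> Tomogram:
    acq = simulate_tomogram(phantom, optical, scan, rng_seed=rng_seed)
    return assemble_tomogram(acq, pipeline)


def measure_seed(
    phantom: SeedPhantom,
    optical: OpticalConfig,
    study: StudyConfig,
    seed_id: str,
    genotype: str,
    rng_seed: int,
    lateral_cfg: LateralConfig = LateralConfig(),
    axial_cfg: AxialFitConfig = AxialFitConfig(),
) -> pd.DataFrame:
    """Measure one phantom end to end; returns the measurement table.

    Rows carry method 'threshold'/'gauss1'/'gauss2' (lateral, per site) and
    'axial' (one per seed); the per-site ground-truth thickness is attached
    as ``true_um`` for validation against the generative field.
    """
    entire_scan = ScanConfig(
        nx=study.entire_nx,
        ny=study.entire_ny,
        x_extent_mm=study.entire_extent_mm,
        y_extent_mm=study.entire_extent_mm,
        repeats_per_pixel=1,
    )
    tomogram = acquire_and_reconstruct(phantom, optical, entire_scan, rng_seed)

    # measurement sites from the en-face footprint (max projection over
    # depth): its outline is the seed's widest perimeter and is far more
    # robust at coarse pitches than any single speckled slice
    footprint = tomogram.volume[5:].max(axis=0)
    mask = segment_enface(footprint, tomogram.dx_um)
    _, sites = midline_and_sites(mask)
    # rim-tangent depth estimate (deepest detected surface), used as the
    # fallback analysis slice when a block cannot be refined locally
    surf = _surface_depth_map(tomogram.volume)
    valid = surf[surf >= 0]
    if valid.size == 0:
        raise GeometryError("no surface detected in the entire-seed tomogram")
    z_eq = int(np.percentile(valid, 99.5))
    ox, oy = scan_origin_um(entire_scan)

    rows = []
    for site in sites:
        lab_x = ox + site.x_um  # mask coords are pixel-origin based
        lab_y = oy + site.y_um
        # the site sits on the widest perimeter, i.e. the equatorial plane
        theta_p, phi_p = parametric_site_angles(
            phantom, lab_x, lab_y, phantom.center_um[2]
        )
        true_um = float(
            phantom.thickness_um(np.deg2rad(theta_p), np.deg2rad(phi_p))
        )
        # tangent-aligned zoomed acquisition centered on the boundary point
        normal_lab = np.deg2rad(site.tangent_deg) - np.pi / 2
        # orient the scan's long (sample) axis along the outward normal
        out_dir = np.array([lab_x, lab_y]) - np.array(
            [ox + mask.mask.shape[1] / 2 * tomogram.dx_um,
             oy + mask.mask.shape[0] / 2 * tomogram.dy_um]
        )
        nx_, ny_ = np.cos(normal_lab), np.sin(normal_lab)
        if nx_ * out_dir[0] + ny_ * out_dir[1] < 0:
            nx_, ny_ = -nx_, -ny_
        rotation = np.degrees(np.arctan2(ny_, nx_))
        block_scan = ScanConfig(
            nx=study.block_samples,
            ny=study.block_lines,
            x_extent_mm=study.block_samples * study.block_pitch_um * 1e-3,
            y_extent_mm=study.block_lines * study.block_pitch_um * 1e-3,
            repeats_per_pixel=study.block_repeats,
            x_center_mm=lab_x * 1e-3,
            y_center_mm=lab_y * 1e-3,
            rotation_deg=rotation,
        )
        block_seed = rng_seed * 1009 + site.site_index + 1
        block_tom = acquire_and_reconstruct(phantom, optical, block_scan, block_seed)
        # refine the analysis slice per site: the zoomed block resolves the
        # local rim-tangent depth far better than the coarse entire-seed
        # grid — its deepest detected surface bounds the rim from above
        surf_b = _surface_depth_map(block_tom.volume)
        valid_b = surf_b[surf_b >= 0]
        if valid_b.size:
            z_rim = int(np.percentile(valid_b, 98.0))
        else:
            z_rim = z_eq
        try:
            z_site = refine_site_slice(block_tom.volume, z_rim - 12, z_rim + 18)
        except GeometryError:
            z_site = z_eq
        block = ProfileBlock(
            data=block_tom.volume[z_site],
            pitch_um=study.block_pitch_um,
            alpha_deg=0.0,
        )
        for method in study.lateral_methods:
            try:
                thickness, alpha = measure_block(block, lateral_cfg, method)
                qc = "ok"
            except EstimatorError as exc:
                thickness, alpha, qc = np.nan, np.nan, f"failed: {exc}"
            rows.append(
                dict(
                    seed_id=seed_id,
                    genotype=genotype,
                    site_index=site.site_index,
                    theta_deg=site.theta_deg,
                    method=method,
                    alpha_deg=alpha,
                    thickness_um=thickness,
                    true_um=true_um,
                    qc_flag=qc,
                )
            )
    if study.measure_axial:
        try:
            result = measure_axial(tomogram, axial_cfg)
            rows.append(
                dict(
                    seed_id=seed_id,
                    genotype=genotype,
                    site_index=-1,
                    theta_deg=np.nan,
                    method="axial",
                    alpha_deg=np.nan,
                    thickness_um=result.thickness_um if result.success else np.nan,
                    true_um=np.nan,
                    qc_flag="ok" if result.success else f"failed: {result.failure_reason}",
                )
            )
        except AxialFailure as exc:
            rows.append(
                dict(
                    seed_id=seed_id,
                    genotype=genotype,
                    site_index=-1,
                    theta_deg=np.nan,
                    method="axial",
                    alpha_deg=np.nan,
                    thickness_um=np.nan,
                    true_um=np.nan,
                    qc_flag=f"failed: {exc}",
                )
            )
    return pd.DataFrame(rows)


def run_study(
    rng_seed: int = 0,
    study: StudyConfig = StudyConfig(),
    optical: OpticalConfig | None = None,
    genotypes: dict[str, GenotypeParams] | None = None,
) -> pd.DataFrame:
    """Simulate and measure a two-genotype study; returns the pooled table."""
    optical = optical or OpticalConfig()
    genotypes = genotypes or GENOTYPES
    tables = []
    for g_idx, (name, params) in enumerate(sorted(genotypes.items())):
        for s in range(study.seeds_per_genotype):
            phantom_seed = int((rng_seed * 7919 + g_idx * 101 + s) % (2**31 - 1))
            phantom, _ = build_phantom(params, rng_seed=phantom_seed)
            tables.append(
                measure_seed(
                    phantom,
                    optical,
                    study,
                    seed_id=f"{name}-{s:02d}",
                    genotype=name,
                    rng_seed=phantom_seed,
                )
            )
    return pd.concat(tables, ignore_index=True)


def study_report(measurements: pd.DataFrame, **kwargs) -> dict:
    """Genotype report from the site-level lateral threshold measurements."""
    lat = measurements[
        (measurements["method"] == "threshold") & (measurements["qc_flag"] == "ok")
    ]
    return stats.build_report(lat, **kwargs)
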