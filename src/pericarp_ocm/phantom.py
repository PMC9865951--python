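"""Synthetic spectral-domain OCM acquisitions of ellipsoidal seed phantoms.

This module is the data source for the whole pipeline: it builds seed
phantoms — an ellipsoidal kernel with a densely scattering pericarp shell of
angularly varying thickness around a weakly scattering endosperm — and
simulates the raw line-camera interferograms a Fourier-domain OCM instrument
would record while raster-scanning a focused beam over the seed.

The forward model is standard spectral interferometry: for camera pixel m
sampling wavelength lambda_m (the camera is equidistant in *wavelength*, so
downstream k-space resampling is genuinely required),

    I(lambda_m) = S(lambda_m) * [ R_r + sum_j w_j R_j
                                  + 2 sum_j w_j sqrt(R_r R_j) cos(2 k_m OPL_j) ]
                  + eps_m

with S a Gaussian source envelope, R_r the reference reflectivity, R_j the
scatterer reflectivities, w_j = exp(-2 d_j^2 / w(z_j)^2) the Gaussian lateral
beam weight, OPL_j the cumulative optical path from the zero-delay plane to
scatterer j (physical segments times local refractive index), and eps_m
additive Gaussian detector noise.  Scatterer-scatterer (autocorrelation)
interference is neglected: reference-dominated regime.

Every random element is driven by explicit integer seeds; identical
configurations and seeds reproduce acquisitions byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from ._fringes import accumulate_fringes

TWO_PI = 2.0 * np.pi

# Spectrometer depth calibration: single-sided depth pitch lambda0^2/(2*span)
# for the defaults below is ~11.05 um, matching the printed 11 um voxel size.


class ParameterError(ValueError):
    """A physically inconsistent phantom or scan parameterization."""


@dataclass(frozen=True)
class OpticalConfig:
    """Source, spectrometer, beam and detector parameters of the instrument.

    Defaults reproduce a broadband 1030 nm source with ~20 um axial
    resolution in air, a 2.6 um lateral resolution (1.3 um beam waist
    radius) maintained over a 326 um depth of focus, and a 2048-pixel line
    camera spanning 48 nm, which yields an ~11 um single-sided depth pitch.
    """

    center_wavelength_nm: float = 1030.0
    source_fwhm_bandwidth_nm: float = 23.0
    camera_pixels: int = 2048
    wavelength_span_nm: float = 48.0
    reference_reflectivity: float = 1.0
    beam_waist_radius_um: float = 1.3
    depth_of_focus_um: float = 326.0
    focus_depth_um: float = 2050.0
    read_noise_sd: float = 0.001
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "center_wavelength_nm",
            "source_fwhm_bandwidth_nm",
            "wavelength_span_nm",
            "reference_reflectivity",
            "beam_waist_radius_um",
            "depth_of_focus_um",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.camera_pixels < 8 or self.camera_pixels % 2:
            raise ParameterError("camera_pixels must be even and >= 8")
        if self.read_noise_sd < 0:
            raise ParameterError("read_noise_sd must be >= 0")
        if not np.isfinite(self.depth_pitch_um) or self.depth_pitch_um <= 0:
            raise ParameterError("derived depth pitch is not finite/positive")

    @property
    def wavelength_nm(self) -> np.ndarray:
        """Camera wavelength grid, strictly increasing, equidistant."""
        half = 0.5 * self.wavelength_span_nm
        return np.linspace(
            self.center_wavelength_nm - half,
            self.center_wavelength_nm + half,
            self.camera_pixels,
        )

    @property
    def k_rad_per_nm(self) -> np.ndarray:
        """Angular wavenumber at each camera pixel (decreasing with pixel)."""
        return TWO_PI / self.wavelength_nm

    @property
    def depth_pitch_um(self) -> float:
        """Single-sided optical depth per FFT bin after k-linearization (um)."""
        k = self.k_rad_per_nm
        dk = (k.max() - k.min()) / (self.camera_pixels - 1)
        return float(np.pi / (self.camera_pixels * dk) * 1e-3)

    @property
    def depth_range_um(self) -> float:
        """Unambiguous single-sided optical depth range (um)."""
        return self.depth_pitch_um * (self.camera_pixels // 2)

    @property
    def axial_fwhm_air_um(self) -> float:
        """Transform-limited axial FWHM in air for a Gaussian source (um)."""
        lam0 = self.center_wavelength_nm
        return float(
            (2.0 * np.log(2.0) / np.pi)
            * lam0**2
            / self.source_fwhm_bandwidth_nm
            * 1e-3
        )

    def source_envelope(self) -> np.ndarray:
        """Gaussian spectral envelope S(lambda), peak-normalized."""
        lam = self.wavelength_nm
        return np.exp(
            -4.0
            * np.log(2.0)
            * (lam - self.center_wavelength_nm) ** 2
            / self.source_fwhm_bandwidth_nm**2
        )

    def beam_radius_um(self, z_um: np.ndarray | float) -> np.ndarray:
        """1/e^2 beam radius at physical depth z: constant waist inside the
        depth of focus, linear growth outside it."""
        z = np.asarray(z_um, dtype=float)
        half_dof = 0.5 * self.depth_of_focus_um
        dist = np.abs(z - self.focus_depth_um)
        w = np.where(
            dist <= half_dof,
            self.beam_waist_radius_um,
            self.beam_waist_radius_um * dist / half_dof,
        )
        return w


@dataclass(frozen=True)
class ScanConfig:
    """Raster-scan geometry: an nx-by-ny grid of A-scan positions.

    ``nx`` samples run along the block's long (x) axis, ``ny`` along the
    short (y) axis; the rectangle may be re-centered and rotated in the lab
    frame so zoomed acquisitions can be aligned with the local seed edge.
    """

    nx: int = 1000
    ny: int = 1000
    x_extent_mm: float = 5.4
    y_extent_mm: float = 5.4
    repeats_per_pixel: int = 1
    x_center_mm: float = 2.7
    y_center_mm: float = 2.7
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ParameterError("scan grid must be non-empty")
        if self.x_extent_mm <= 0 or self.y_extent_mm <= 0:
            raise ParameterError("scan extents must be > 0")
        if self.repeats_per_pixel < 1:
            raise ParameterError("repeats_per_pixel must be >= 1")

    @property
    def dx_um(self) -> float:
        return self.x_extent_mm * 1e3 / self.nx

    @property
    def dy_um(self) -> float:
        return self.y_extent_mm * 1e3 / self.ny

    def positions_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Lab-frame (x, y) coordinates of every A-scan, shape [ny, nx]."""
        jx = (np.arange(self.nx) - 0.5 * (self.nx - 1)) * self.dx_um
        iy = (np.arange(self.ny) - 0.5 * (self.ny - 1)) * self.dy_um
        gx, gy = np.meshgrid(jx, iy)
        ang = np.deg2rad(self.rotation_deg)
        ca, sa = np.cos(ang), np.sin(ang)
        x = self.x_center_mm * 1e3 + ca * gx - sa * gy
        y = self.y_center_mm * 1e3 + sa * gx + ca * gy
        return x, y


@dataclass(frozen=True)
class GenotypeParams:
    """Genotype-level generative parameters for pericarp thickness.

    ``mean_um`` is the genotype mean; per-seed means are drawn with SD
    ``between_seed_sd_um`` and the within-seed angular field has SD
    ``within_seed_sd_um``, so pooled site-level measurements have SD close to
    sqrt(between^2 + within^2).
    """

    name: str
    mean_um: float
    between_seed_sd_um: float
    within_seed_sd_um: float

    @property
    def total_sd_um(self) -> float:
        return float(np.hypot(self.between_seed_sd_um, self.within_seed_sd_um))


#: Thick-pericarp genotype: pooled mean 74 um, pooled SD ~14 um.
THICK_GENOTYPE = GenotypeParams("thick", 74.0, 5.0, 13.08)
#: Thin-pericarp genotype: pooled mean 43 um, pooled SD ~6 um.
THIN_GENOTYPE = GenotypeParams("thin", 43.0, 3.0, 5.20)

GENOTYPES = {"thick": THICK_GENOTYPE, "thin": THIN_GENOTYPE}

_MAX_HARMONIC_ORDER = 6
_CALIBRATION_POINTS = 4096


def _assoc_legendre(l_max: int, x: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Associated Legendre P_l^m(x) for all 0 <= m <= l <= l_max.

    Standard upward recurrence with the Condon-Shortley phase (matching
    scipy.special.lpmv), vectorized over the evaluation points — evaluating
    the band-limited thickness field for millions of scatterer candidates
    must not go through per-point special-function calls.
    """
    x = np.asarray(x, dtype=float)
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    out: dict[tuple[int, int], np.ndarray] = {}
    pmm = np.ones_like(x)
    for m in range(l_max + 1):
        if m > 0:
            pmm = pmm * (-(2 * m - 1)) * s
        out[(m, m)] = pmm
        if m < l_max:
            out[(m + 1, m)] = x * (2 * m + 1) * pmm
            for l in range(m + 1, l_max):
                out[(l + 1, m)] = (
                    (2 * l + 1) * x * out[(l, m)] - (l + m) * out[(l - 1, m)]
                ) / (l - m + 1)
    return out


def _fibonacci_sphere(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Area-uniform sample of (theta, phi) on the unit sphere."""
    i = np.arange(n) + 0.5
    cos_t = 1.0 - 2.0 * i / n
    theta = np.arccos(cos_t)
    phi = np.mod(i * np.pi * (3.0 - np.sqrt(5.0)), TWO_PI)
    return theta, phi


@dataclass(frozen=True)
class SeedPhantom:
    """Ellipsoidal seed with a scattering pericarp shell of known thickness.

    The outer surface is the ellipsoid |x~/a|^2+|y~/b|^2+|z~/c|^2 = 1; the
    pericarp occupies the band within a normal distance t(theta, phi) of that
    surface, where t is the band-limited angular thickness field.  The inner
    boundary is therefore a normal-offset surface, not exactly an ellipsoid;
    for 40-80 um thickness against mm-scale axes the difference is O(t^2/a).
    """

    center_um: tuple[float, float, float] = (2700.0, 2700.0, 2050.0)
    semi_axes_um: tuple[float, float, float] = (2000.0, 1750.0, 1250.0)
    mean_thickness_um: float = 74.0
    thickness_sd_um: float = 13.08
    pericarp_scatterer_density: float = 0.004  # um^-3
    endosperm_scatterer_density: float = 0.0004  # um^-3
    reflectivity_log_mu: float = float(np.log(2e-4))
    reflectivity_log_sigma: float = 0.5
    pericarp_refractive_index: float = 1.33
    surround_refractive_index: float = 1.0
    layer_fractions: tuple[float, ...] = (0.125, 0.375, 0.625, 0.875)
    layer_weight: float = 0.4
    layer_rel_sigma: float = 0.08
    rng_seed: int = 0
    # derived: real-harmonic coefficients (l, m, a_lm, b_lm) and field scale
    _harmonics: tuple = field(default=None, repr=False)
    _field_scale: float = field(default=0.0, repr=False)
    _field_offset: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes_um
        if min(a, b, c) <= 0:
            raise ParameterError("semi-axes must be positive")
        if self.mean_thickness_um <= 0:
            raise ParameterError("mean thickness must be > 0")
        if self.thickness_sd_um < 0:
            raise ParameterError("thickness SD must be >= 0")
        if self.pericarp_scatterer_density <= self.endosperm_scatterer_density:
            raise ParameterError(
                "pericarp scatterer density must exceed endosperm density"
            )
        if self.pericarp_refractive_index < 1:
            raise ParameterError("refractive index must be >= 1")
        if self._harmonics is None:
            object.__setattr__(self, "_harmonics", self._draw_harmonics())
            self._calibrate_field()
        # worst-case field excursion: reject shells thicker than the kernel
        tmax = self.mean_thickness_um + 6.0 * self.thickness_sd_um
        if tmax >= min(a, b, c):
            raise ParameterError(
                f"thickness (mean {self.mean_thickness_um} um, SD "
                f"{self.thickness_sd_um} um) can exceed the smallest semi-axis"
            )

    def _draw_harmonics(self) -> tuple:
        rng = np.random.default_rng(np.random.SeedSequence([self.rng_seed, 0x7F]))
        ls, ms, av, bv = [], [], [], []
        for l in range(1, _MAX_HARMONIC_ORDER + 1):
            for m in range(0, l + 1):
                # normalize lpmv so every (l, m) term has comparable variance
                norm = np.sqrt(
                    (2 * l + 1)
                    / (4.0 * np.pi)
                    * np.prod(1.0 / np.arange(l - m + 1, l + m + 1, dtype=float))
                    if m > 0
                    else (2 * l + 1) / (4.0 * np.pi)
                )
                decay = 1.0 / (1.0 + l)
                ls.append(l)
                ms.append(m)
                av.append(rng.standard_normal() * decay * norm)
                bv.append((rng.standard_normal() * decay * norm) if m else 0.0)
        return (
            np.array(ls),
            np.array(ms),
            np.array(av),
            np.array(bv),
        )

    def _raw_field(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        ls, ms, av, bv = self._harmonics
        theta = np.atleast_1d(theta)
        phi = np.atleast_1d(phi)
        x = np.cos(theta)
        legendre = _assoc_legendre(_MAX_HARMONIC_ORDER, x)
        cos_m = {m: np.cos(m * phi) for m in np.unique(ms)}
        sin_m = {m: np.sin(m * phi) for m in np.unique(ms) if m}
        out = np.zeros(np.broadcast_shapes(theta.shape, phi.shape))
        for l, m, a, b in zip(ls, ms, av, bv):
            term = a * cos_m[m]
            if m:
                term = term + b * sin_m[m]
            out = out + legendre[(l, m)] * term
        return out

    def _calibrate_field(self) -> None:
        theta, phi = _fibonacci_sphere(_CALIBRATION_POINTS)
        f = self._raw_field(theta, phi)
        mean, sd = float(f.mean()), float(f.std())
        if self.thickness_sd_um == 0 or sd == 0:
            object.__setattr__(self, "_field_scale", 0.0)
            object.__setattr__(self, "_field_offset", mean)
        else:
            object.__setattr__(self, "_field_scale", self.thickness_sd_um / sd)
            object.__setattr__(self, "_field_offset", mean)

    def thickness_um(self, theta, phi) -> np.ndarray:
        """Local pericarp thickness t(theta, phi) in um.

        theta is the polar angle from the +z (beam) axis of the parametric
        surface direction (x~/a, y~/b, z~/c); phi the azimuth from +x.
        Deterministic given ``rng_seed``.
        """
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(phi))):
            raise ParameterError("angles must be finite")
        if self._field_scale == 0.0:
            t = np.full(np.broadcast_shapes(theta.shape, phi.shape),
                        self.mean_thickness_um)
        else:
            f = self._raw_field(theta, phi).reshape(
                np.broadcast_shapes(theta.shape, phi.shape)
            )
            t = self.mean_thickness_um + self._field_scale * (f - self._field_offset)
        # the generative field is effectively band-limited and 6-sigma safe,
        # but clip defensively to keep the shell physical
        tmin = 1.0
        tmax = 0.9 * min(self.semi_axes_um)
        return np.clip(t, tmin, tmax)

    def layer_density_profile(self, u: np.ndarray) -> np.ndarray:
        """Relative scatterer density versus relative depth u = d/t in [0, 1].

        Mixture of a uniform background and narrow Gaussian sub-shells at
        ``layer_fractions`` — several scattering interfaces spaced below the
        axial resolution, emulating the epicarp/mesocarp/endocarp fine
        structure.  Integrates to ~1 over [0, 1].
        """
        u = np.asarray(u, dtype=float)
        out = np.full_like(u, 1.0 - self.layer_weight)
        if self.layer_weight > 0 and self.layer_fractions:
            amp = self.layer_weight / len(self.layer_fractions)
            s = self.layer_rel_sigma
            for f in self.layer_fractions:
                out = out + amp * np.exp(-0.5 * ((u - f) / s) ** 2) / (
                    s * np.sqrt(TWO_PI)
                )
        return out

    @property
    def layer_density_max(self) -> float:
        u = np.linspace(0.0, 1.0, 2001)
        return float(self.layer_density_profile(u).max())


@dataclass
class GroundTruth:
    """Known thickness truth carried alongside synthetic acquisitions."""

    site_theta_deg: np.ndarray
    site_thickness_um: np.ndarray
    dense_phi_deg: np.ndarray
    dense_thickness_um: np.ndarray
    equatorial_slice_index: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "site_index": np.arange(len(self.site_theta_deg)),
                "theta_deg": self.site_theta_deg,
                "true_thickness_um": self.site_thickness_um,
            }
        )


#: Standard measurement-site angles (degrees from the hilum-stylar midline):
#: every 30 degrees with the two poles (0 and 180) excluded.
SITE_ANGLES_DEG = np.array([30, 60, 90, 120, 150, 210, 240, 270, 300, 330], float)


def build_phantom(
    genotype: GenotypeParams | str = THICK_GENOTYPE,
    rng_seed: int = 0,
    **overrides,
) -> tuple[SeedPhantom, GroundTruth]:
    """Build one seed phantom of the given genotype plus its ground truth.

    The per-seed mean thickness is drawn from N(genotype mean, between-seed
    SD) and the angular field SD equals the within-seed SD.  Ground truth
    holds the thickness at the ten standard equatorial site angles and a
    dense equatorial ring sample.
    """
    if isinstance(genotype, str):
        genotype = GENOTYPES[genotype]
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0x5EED]))
    seed_mean = genotype.mean_um + genotype.between_seed_sd_um * rng.standard_normal()
    seed_mean = max(seed_mean, 5.0)
    phantom = SeedPhantom(
        mean_thickness_um=seed_mean,
        thickness_sd_um=genotype.within_seed_sd_um,
        rng_seed=rng_seed,
        **overrides,
    )
    dense_phi = np.arange(0.0, 360.0, 0.5)
    truth = GroundTruth(
        site_theta_deg=SITE_ANGLES_DEG.copy(),
        site_thickness_um=true_thickness_at(
            phantom, np.full_like(SITE_ANGLES_DEG, 90.0), SITE_ANGLES_DEG
        ),
        dense_phi_deg=dense_phi,
        dense_thickness_um=true_thickness_at(
            phantom, np.full_like(dense_phi, 90.0), dense_phi
        ),
    )
    return phantom, truth


def true_thickness_at(phantom: SeedPhantom, theta_deg, phi_deg) -> np.ndarray:
    """Evaluate the phantom's thickness field at angles given in degrees."""
    return phantom.thickness_um(np.deg2rad(theta_deg), np.deg2rad(phi_deg))


# ----------------------------------------------------------------------------
# scatterer population and spectrum synthesis
# ----------------------------------------------------------------------------

_CAPTURE_RADIUS_WAISTS = 2.5


def _column_scatterers(
    phantom: SeedPhantom,
    optical: OpticalConfig,
    x_um: np.ndarray,
    y_um: np.ndarray,
    rng: np.random.Generator,
):
    """Draw the scatterer population seen by each beam column.

    Columns are the flattened (x, y) arrays.  Returns (col_ptr, opl2_nm,
    amp, dc) where opl2 = 2*OPL in nm, amp the fringe amplitude per
    scatterer, and dc[c] = sum_j w_j R_j for column c.
    """
    x = np.asarray(x_um, float).ravel()
    y = np.asarray(y_um, float).ravel()
    ncol = x.size
    cx, cy, cz = phantom.center_um
    a, b, c = phantom.semi_axes_um
    n_med = phantom.pericarp_refractive_index

    # axis-ray intersection with the outer ellipsoid
    q = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2
    hit = q < 1.0
    root = np.sqrt(np.clip(1.0 - q, 0.0, None))
    z1 = cz - c * root  # entry (top)
    z2 = cz + c * root  # exit (bottom)

    r_cap = _CAPTURE_RADIUS_WAISTS * optical.beam_waist_radius_um
    area = np.pi * r_cap**2
    rho_env = phantom.pericarp_scatterer_density * phantom.layer_density_max
    lam = np.where(hit, rho_env * area * (z2 - z1), 0.0)
    counts = rng.poisson(lam)
    total = int(counts.sum())
    col_of = np.repeat(np.arange(ncol), counts)

    # candidate positions: uniform in the capture cylinder over [z1, z2]
    z = z1[col_of] + (z2[col_of] - z1[col_of]) * rng.random(total)
    rr = r_cap * np.sqrt(rng.random(total))
    ang = TWO_PI * rng.random(total)
    dx = rr * np.cos(ang)
    dy = rr * np.sin(ang)
    px = x[col_of] + dx
    py = y[col_of] + dy

    # ellipsoidal coordinates of each candidate
    xt = (px - cx) / a
    yt = (py - cy) / b
    zt = (z - cz) / c
    m = np.sqrt(xt**2 + yt**2 + zt**2)
    m = np.maximum(m, 1e-12)
    gnorm = np.sqrt((xt / a) ** 2 + (yt / b) ** 2 + (zt / c) ** 2)
    d_surf = (1.0 - m) * m / np.maximum(gnorm, 1e-300)  # normal depth below surface
    inside = (m < 1.0) & (d_surf > 0)

    # evaluate the (expensive) angular thickness field only near the shell
    t_upper = phantom.mean_thickness_um + 6.5 * phantom.thickness_sd_um
    near = inside & (d_surf <= t_upper)
    accept_p = np.zeros(total)
    if near.any():
        theta = np.arccos(np.clip(zt[near] / m[near], -1.0, 1.0))
        phi = np.arctan2(yt[near], xt[near])
        t_loc = phantom.thickness_um(theta, phi)
        u = d_surf[near] / t_loc
        p_near = np.where(
            u <= 1.0,
            phantom.layer_density_profile(np.clip(u, 0.0, 1.0))
            / phantom.layer_density_max,
            phantom.endosperm_scatterer_density / rho_env,
        )
        accept_p[near] = p_near
    deep = inside & (d_surf > t_upper)
    accept_p[deep] = phantom.endosperm_scatterer_density / rho_env
    keep = rng.random(total) < accept_p

    # reflectivities and beam weights (draw in fixed order for determinism)
    refl = np.exp(
        phantom.reflectivity_log_mu
        + phantom.reflectivity_log_sigma * rng.standard_normal(total)
    )
    wz = optical.beam_radius_um(z)
    w_lat = np.exp(-2.0 * (dx**2 + dy**2) / wz**2)

    opl = z1[col_of] + n_med * (z - z1[col_of])  # um, surround index 1.0 above
    amp = 2.0 * np.sqrt(optical.reference_reflectivity * refl) * w_lat
    dc_terms = w_lat * refl

    col_kept = col_of[keep]
    order = np.argsort(col_kept, kind="stable")
    col_kept = col_kept[order]
    opl2_nm = (2.0e3 * opl[keep])[order]
    amp_k = amp[keep][order]
    dc = np.bincount(col_kept, weights=dc_terms[keep][order], minlength=ncol)
    col_ptr = np.zeros(ncol + 1, dtype=np.int64)
    np.cumsum(np.bincount(col_kept, minlength=ncol), out=col_ptr[1:])
    return col_ptr, opl2_nm, amp_k, dc


def simulate_spectrum(
    phantom: SeedPhantom,
    optical: OpticalConfig,
    x_um: float,
    y_um: float,
    rng_seed: int | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Simulate one raw camera spectrum for the beam at (x, y).

    An empty beam column yields the fringeless DC spectrum S*R_r (+ noise).
    """
    seed = optical.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5CA]))
    col_ptr, opl2, amp, dc = _column_scatterers(
        phantom, optical, np.array([x_um]), np.array([y_um]), rng
    )
    return _synthesize(optical, col_ptr, opl2, amp, dc, rng, noise)[0]


def fringe_spectrum(
    optical: OpticalConfig,
    opl_um,
    reflectivity,
    noise: bool = False,
    rng_seed: int = 0,
) -> np.ndarray:
    """Raw spectrum of ideal point reflectors at the given optical depths.

    Bypasses the phantom geometry; used to probe the reconstruction chain
    with analytically known inputs.
    """
    opl = np.atleast_1d(np.asarray(opl_um, float))
    refl = np.broadcast_to(np.asarray(reflectivity, float), opl.shape)
    col_ptr = np.array([0, opl.size], dtype=np.int64)
    amp = 2.0 * np.sqrt(optical.reference_reflectivity * refl)
    dc = np.array([refl.sum()])
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xF1B]))
    return _synthesize(
        optical, col_ptr, 2.0e3 * opl, np.ascontiguousarray(amp), dc, rng, noise
    )[0]


def _synthesize(optical, col_ptr, opl2_nm, amp, dc, rng, noise) -> np.ndarray:
    ncol = col_ptr.size - 1
    fringes = np.zeros((ncol, optical.camera_pixels))
    accumulate_fringes(
        fringes,
        np.ascontiguousarray(col_ptr),
        np.ascontiguousarray(opl2_nm, dtype=np.float64),
        np.ascontiguousarray(amp, dtype=np.float64),
        np.ascontiguousarray(optical.k_rad_per_nm),
    )
    s = optical.source_envelope()
    out = s[None, :] * (
        optical.reference_reflectivity + dc[:, None] + fringes
    )
    if noise and optical.read_noise_sd > 0:
        dc_level = optical.reference_reflectivity * s.max()
        out = out + rng.normal(
            0.0, optical.read_noise_sd * dc_level, size=out.shape
        )
    return out


@dataclass
class SpectralAcquisition:
    """Raw per-(x, y) camera spectra plus scan and optics metadata."""

    spectra: np.ndarray  # [ny, nx, repeats, camera_pixels] float32
    wavelength_nm: np.ndarray
    optical: OpticalConfig
    scan: ScanConfig
    rng_seed: int
    truth: GroundTruth | None = None

    @property
    def n_spectra(self) -> int:
        return int(np.prod(self.spectra.shape[:3]))


MAX_SPECTRA = 8_000_000


def simulate_tomogram(
    phantom: SeedPhantom,
    optical: OpticalConfig,
    scan: ScanConfig,
    rng_seed: int = 0,
    truth: GroundTruth | None = None,
    chunk_columns: int = 8192,
) -> SpectralAcquisition:
    """Simulate a full raster acquisition: nx*ny*repeats raw spectra.

    The scatterer population of each column is fixed across repeats; only
    detector noise varies, so magnitude-averaging the reconstructed repeats
    improves SNR by ~sqrt(repeats).  Deterministic given the seeds.
    """
    n_total = scan.nx * scan.ny * scan.repeats_per_pixel
    if n_total > MAX_SPECTRA:
        raise ParameterError(
            f"acquisition of {n_total} spectra exceeds the cap of {MAX_SPECTRA}"
        )
    x, y = scan.positions_um()
    xf, yf = x.ravel(), y.ravel()
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xACF]))
    ncol = xf.size
    spectra = np.empty(
        (ncol, scan.repeats_per_pixel, optical.camera_pixels), dtype=np.float32
    )
    for start in range(0, ncol, chunk_columns):
        sl = slice(start, min(start + chunk_columns, ncol))
        col_ptr, opl2, amp, dc = _column_scatterers(
            phantom, optical, xf[sl], yf[sl], rng
        )
        clean = _synthesize(optical, col_ptr, opl2, amp, dc, rng, noise=False).astype(
            np.float32
        )
        s_max = optical.source_envelope().max() * optical.reference_reflectivity
        sd = np.float32(optical.read_noise_sd * s_max)
        for r in range(scan.repeats_per_pixel):
            if optical.read_noise_sd > 0:
                spectra[sl, r, :] = clean + sd * rng.standard_normal(
                    clean.shape, dtype=np.float32
                )
            else:
                spectra[sl, r, :] = clean
    spectra = spectra.reshape(
        scan.ny, scan.nx, scan.repeats_per_pixel, optical.camera_pixels
    )
    if truth is not None:
        cz = phantom.center_um[2]
        truth = dataclasses.replace(
            truth, equatorial_slice_index=int(round(cz / optical.depth_pitch_um))
        )
    return SpectralAcquisition(
        spectra=spectra,
        wavelength_nm=optical.wavelength_nm,
        optical=optical,
        scan=scan,
        rng_seed=rng_seed,
        truth=truth,
    )


# ----------------------------------------------------------------------------
# container I/O
# ----------------------------------------------------------------------------


def save_acquisition(path, acq: SpectralAcquisition) -> None:
    """Write an acquisition to an HDF5 container (+ truth table if present)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=acq.spectra, compression="gzip", shuffle=True)
        f.create_dataset("wavelength_nm", data=acq.wavelength_nm)
        f.attrs["optical"] = json.dumps(dataclasses.asdict(acq.optical))
        f.attrs["scan"] = json.dumps(dataclasses.asdict(acq.scan))
        f.attrs["rng_seed"] = acq.rng_seed
        if acq.truth is not None:
            g = f.create_group("truth")
            g.create_dataset("site_theta_deg", data=acq.truth.site_theta_deg)
            g.create_dataset("site_thickness_um", data=acq.truth.site_thickness_um)
            g.create_dataset("dense_phi_deg", data=acq.truth.dense_phi_deg)
            g.create_dataset("dense_thickness_um", data=acq.truth.dense_thickness_um)
            if acq.truth.equatorial_slice_index is not None:
                g.attrs["equatorial_slice_index"] = acq.truth.equatorial_slice_index


def load_acquisition(path) -> SpectralAcquisition:
    with h5py.File(path, "r") as f:
        optical = OpticalConfig(**json.loads(f.attrs["optical"]))
        scan = ScanConfig(**json.loads(f.attrs["scan"]))
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = GroundTruth(
                site_theta_deg=g["site_theta_deg"][:],
                site_thickness_um=g["site_thickness_um"][:],
                dense_phi_deg=g["dense_phi_deg"][:],
                dense_thickness_um=g["dense_thickness_um"][:],
                equatorial_slice_index=int(g.attrs["equatorial_slice_index"])
                if "equatorial_slice_index" in g.attrs
                else None,
            )
        return SpectralAcquisition(
            spectra=f["spectra"][:],
            wavelength_nm=f["wavelength_nm"][:],
            optical=optical,
            scan=scan,
            rng_seed=int(f.attrs["rng_seed"]),
            truth=truth,
        )
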