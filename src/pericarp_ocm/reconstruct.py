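"""Spectral-domain reconstruction: raw spectra -> A-scans -> tomograms.

The processing chain per A-scan is the standard FD-OCT pipeline:

1. subtract a reference spectrum (the mean of all spectra in the acquisition),
2. apply an apodization window (Hann by default),
3. interpolate the wavelength-sampled spectrum onto an equidistant angular
   wavenumber (k) grid with a cubic spline,
4. Fourier transform and keep the magnitude of the first half of the result —
   the single-sided axial profile (the second half is the complex-conjugate
   mirror and carries no extra information).

Repeated spectra of the same pixel are reconstructed individually and their
magnitudes averaged.  Volumes are stored [z, y, x] with explicit pitches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.interpolate import make_interp_spline

from .phantom import SpectralAcquisition

TWO_PI = 2.0 * np.pi


class ReconstructionError(ValueError):
    pass


def validate_wavelength_grid(wavelength_nm: np.ndarray) -> np.ndarray:
    """Check a camera wavelength grid: strictly increasing, equidistant."""
    lam = np.asarray(wavelength_nm, dtype=float)
    if lam.ndim != 1 or lam.size < 4:
        raise ReconstructionError("wavelength grid must be a 1-D array")
    d = np.diff(lam)
    if np.any(d <= 0):
        raise ReconstructionError("wavelength grid must be strictly increasing")
    if (d.max() - d.min()) > 1e-9 * abs(d.mean()):
        raise ReconstructionError("wavelength grid must be equidistant")
    return lam


def available_windows(n: int) -> dict[str, np.ndarray]:
    return {"hann": np.hanning(n), "rect": np.ones(n)}


def get_window(name: str, n: int) -> np.ndarray:
    try:
        return available_windows(n)[name]
    except KeyError:
        raise ReconstructionError(f"unknown window {name!r}") from None


def compute_reference(acquisition) -> np.ndarray:
    """Element-wise mean over all spectra (all x, y and repeats)."""
    if isinstance(acquisition, SpectralAcquisition):
        spectra = acquisition.spectra
    else:
        spectra = np.asarray(acquisition)
    if spectra.size == 0:
        raise ReconstructionError("empty acquisition: no spectra to average")
    flat = spectra.reshape(-1, spectra.shape[-1])
    return flat.mean(axis=0, dtype=np.float64)


def preprocess(raw, reference, window) -> np.ndarray:
    """Baseline-corrected, apodized spectrum: (raw - reference) * window."""
    raw = np.asarray(raw, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    window = np.asarray(window, dtype=np.float64)
    if raw.shape[-1] != reference.shape[-1] or raw.shape[-1] != window.shape[-1]:
        raise ReconstructionError("raw, reference and window lengths differ")
    return (raw - reference) * window


class KResampler:
    """Cubic-spline resampling from a wavelength grid to equidistant k.

    Target wavenumbers are equidistant between the minimum and maximum of the
    input k range with the same sample count, so the endpoints are preserved
    exactly.  The same object can resample single spectra or stacks.
    """

    def __init__(self, wavelength_nm: np.ndarray):
        lam = np.asarray(wavelength_nm, dtype=float)
        if lam.ndim != 1 or lam.size < 4:
            raise ReconstructionError("wavelength grid must be a 1-D array")
        if np.any(np.diff(lam) <= 0):
            raise ReconstructionError("wavelength grid must be strictly increasing")
        k = TWO_PI / lam  # decreasing
        self.k_source = k[::-1].copy()  # increasing
        self.k_target = np.linspace(k.min(), k.max(), lam.size)
        self.dk = (self.k_target[-1] - self.k_target[0]) / (lam.size - 1)
        self._operator = None

    @property
    def depth_pitch_nm(self) -> float:
        """Optical depth per output FFT bin (single-sided)."""
        n = self.k_target.size
        return float(np.pi / (n * self.dk))

    def _build_operator(self):
        """Sparse matrix form of the spline interpolation.

        Cubic-spline interpolation is linear in the data, so the map from
        samples to resampled values is a fixed matrix; its rows decay
        exponentially away from the diagonal and truncate to a sparse
        operator (relative error < 1e-10), letting large stacks resample as
        one sparse mat-mul instead of per-call spline construction.
        """
        from scipy.sparse import csr_matrix

        n = self.k_source.size
        spline = make_interp_spline(self.k_source, np.eye(n), k=3, axis=0)
        dense = spline(self.k_target)
        dense[np.abs(dense) < 1e-12] = 0.0
        self._operator = csr_matrix(dense)

    def __call__(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.asarray(spectra)
        if spectra.dtype != np.float32:
            spectra = spectra.astype(np.float64)
        rev = spectra[..., ::-1]
        if spectra.ndim == 1 or spectra.shape[0] < 32:
            spline = make_interp_spline(
                self.k_source, rev.astype(np.float64), k=3, axis=-1
            )
            return spline(self.k_target)
        if self._operator is None:
            self._build_operator()
        op = self._operator
        if spectra.dtype == np.float32:
            if not hasattr(self, "_operator32"):
                self._operator32 = op.astype(np.float32)
            op = self._operator32
        flat = rev.reshape(-1, rev.shape[-1])
        out = (op @ flat.T).T
        return np.ascontiguousarray(out.reshape(spectra.shape))


def resample_to_wavenumber(spectrum, wavelength_nm) -> np.ndarray:
    """Resample one (or a stack of) spectra onto an equidistant k grid."""
    return KResampler(wavelength_nm)(spectrum)


@dataclass
class AScan:
    """Single-sided axial magnitude profile."""

    magnitude: np.ndarray
    depth_pitch_optical_um: float

    def __post_init__(self):
        if np.any(self.magnitude < 0):
            raise ReconstructionError("A-scan magnitudes must be >= 0")


def to_ascan(spectrum_k, dk: float, return_complex: bool = False):
    """Fourier transform an equidistant-k spectrum into an axial profile.

    Keeps bins 0 .. N/2-1.  ``dk`` is the k sample spacing (rad/nm);
    the depth pitch follows as pi / (N * dk).
    """
    spectrum_k = np.asarray(spectrum_k, dtype=np.float64)
    n = spectrum_k.shape[-1]
    if n % 2:
        raise ReconstructionError("spectrum length must be even")
    z = np.fft.rfft(spectrum_k, axis=-1)[..., : n // 2]
    pitch_um = float(np.pi / (n * dk) * 1e-3)
    if return_complex:
        return z, pitch_um
    if spectrum_k.ndim == 1:
        return AScan(np.abs(z), pitch_um)
    return np.abs(z), pitch_um


@dataclass
class PipelineConfig:
    """Reconstruction options (window choice, k-resampling on/off)."""

    window: str = "hann"
    resample: bool = True


@dataclass
class Tomogram:
    """Reconstructed magnitude volume, indexed [z, y, x], pitches in um.

    ``dz_um`` is the optical (in-air) depth pitch; conversion to physical
    depth inside a medium divides by its refractive index.
    """

    volume: np.ndarray
    dx_um: float
    dy_um: float
    dz_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if min(self.dx_um, self.dy_um, self.dz_um) <= 0:
            raise ReconstructionError("pitches must be > 0")

    @property
    def nz(self) -> int:
        return self.volume.shape[0]

    def enface(self, z: int) -> np.ndarray:
        return self.volume[z]


def reconstruct_spectra(
    spectra: np.ndarray,
    wavelength_nm: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Run the full per-spectrum pipeline on a [..., npix] stack.

    Returns (magnitudes [..., npix/2], depth_pitch_optical_um).
    """
    lam = validate_wavelength_grid(wavelength_nm)
    if reference is None:
        reference = compute_reference(spectra)
    window = get_window(config.window, lam.size)
    corrected = preprocess(spectra, reference, window)
    resampler = KResampler(lam)
    if config.resample:
        corrected = resampler(corrected)
    result = to_ascan(corrected, resampler.dk)
    if isinstance(result, AScan):
        return result.magnitude, result.depth_pitch_optical_um
    return result


def assemble_tomogram(
    acquisition: SpectralAcquisition,
    config: PipelineConfig = PipelineConfig(),
    chunk_columns: int = 4096,
) -> Tomogram:
    """Reconstruct a raster acquisition into a [z, y, x] magnitude volume.

    Per-pixel repeats are reconstructed individually and magnitude-averaged.
    """
    spectra = acquisition.spectra
    if spectra.ndim != 4:
        raise ReconstructionError("acquisition spectra must be [ny, nx, rep, npix]")
    ny, nx, nrep, npix = spectra.shape
    expected = ~np.all(np.isfinite(spectra), axis=(2, 3))
    if expected.any():
        missing = np.argwhere(expected)[:10]
        raise ReconstructionError(
            f"acquisition has non-finite spectra at (y, x) {missing.tolist()}"
        )
    lam = validate_wavelength_grid(acquisition.wavelength_nm)
    reference = compute_reference(spectra)
    window = get_window(config.window, npix)
    resampler = KResampler(lam)

    flat = spectra.reshape(ny * nx, nrep, npix)
    nz = npix // 2
    out = np.empty((ny * nx, nz), dtype=np.float32)
    ref32 = reference.astype(np.float32)
    win32 = window.astype(np.float32)
    for start in range(0, flat.shape[0], chunk_columns):
        sl = slice(start, min(start + chunk_columns, flat.shape[0]))
        # single-precision fast path: speckle dominates far above float32
        # rounding, and the estimators only consume magnitudes
        corrected = (flat[sl].astype(np.float32) - ref32) * win32
        if config.resample:
            corrected = resampler(corrected)
        z = np.fft.rfft(corrected, axis=-1)[..., : npix // 2]
        pitch = float(np.pi / (npix * resampler.dk) * 1e-3)
        out[sl] = np.abs(z).mean(axis=1, dtype=np.float64).astype(np.float32)
    volume = out.reshape(ny, nx, nz).transpose(2, 0, 1)
    meta = {
        "window": config.window,
        "resample": config.resample,
        "repeats": nrep,
        "rng_seed": acquisition.rng_seed,
        "scan_rotation_deg": acquisition.scan.rotation_deg,
        "scan_center_mm": [acquisition.scan.x_center_mm, acquisition.scan.y_center_mm],
    }
    if acquisition.truth is not None and acquisition.truth.equatorial_slice_index is not None:
        meta["equatorial_slice_index"] = acquisition.truth.equatorial_slice_index
    return Tomogram(
        volume=np.ascontiguousarray(volume),
        dx_um=acquisition.scan.dx_um,
        dy_um=acquisition.scan.dy_um,
        dz_um=pitch,
        meta=meta,
    )


def save_tomogram(path, tomogram: Tomogram) -> None:
    """Write a multi-page 32-bit float TIFF (one page per z) + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, tomogram.volume.astype(np.float32), photometric="minisblack"
    )
    sidecar = {
        "axis_order": "zyx",
        "dx_um": tomogram.dx_um,
        "dy_um": tomogram.dy_um,
        "dz_um": tomogram.dz_um,
        "dz_is_optical": True,
        **tomogram.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_tomogram(path) -> Tomogram:
    path = Path(path)
    volume = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    meta = {
        k: v
        for k, v in sidecar.items()
        if k not in {"axis_order", "dx_um", "dy_um", "dz_um", "dz_is_optical"}
    }
    return Tomogram(
        volume=volume,
        dx_um=sidecar["dx_um"],
        dy_um=sidecar["dy_um"],
        dz_um=sidecar["dz_um"],
        meta=meta,
    )
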