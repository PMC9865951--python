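"""Shared fixtures: small optical configs, synthetic profile factories, and
the session-wide reduced phenotyping study used by the end-to-end checks."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from pericarp_ocm import OpticalConfig
from pericarp_ocm.lateral import ProfileBlock
from pericarp_ocm.pipeline import StudyConfig, run_study

STUDY_SEED = 7


@pytest.fixture(scope="session")
def optical_default() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def optical_small() -> OpticalConfig:
    """Short camera for cheap reconstruction unit tests (same 11 um pitch)."""
    return OpticalConfig(camera_pixels=512)


def make_tophat_block(
    width_um: float,
    pitch_um: float = 1.55,
    n_samples: int = 256,
    n_lines: int = 16,
    sigma_um: float = 1.06,
    alpha_deg: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ProfileBlock:
    """Block whose lines cross a smoothed top-hat band of *perpendicular*
    width ``width_um``, optionally rotated by ``alpha_deg`` to the line axis."""
    x = np.arange(n_samples) * pitch_um
    c = 0.5 * n_samples * pitch_um
    ca = np.cos(np.deg2rad(alpha_deg))
    drift = np.tan(np.deg2rad(alpha_deg)) * pitch_um  # um per line
    apparent = width_um / ca
    data = np.zeros((n_lines, n_samples))
    for i in range(n_lines):
        sh = (i - 0.5 * (n_lines - 1)) * drift
        prof = ((x > c - sh - apparent / 2) & (x < c - sh + apparent / 2)).astype(float)
        data[i] = gaussian_filter1d(prof, sigma_um / pitch_um / ca)
        if noise_sd > 0:
            data[i] += rng.normal(0.0, noise_sd, n_samples)
    return ProfileBlock(data=data, pitch_um=pitch_um, alpha_deg=0.0)


@pytest.fixture(scope="session")
def study_results():
    """Reduced two-genotype study: 3 seeds per genotype, 200x200 entire-seed
    grids, 64x256 zoomed blocks — the package's full pipeline end to end."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(rng_seed=STUDY_SEED, study=StudyConfig())
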