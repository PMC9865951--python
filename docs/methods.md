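# Methods

`pericarp-ocm` reproduces, on fully synthetic data, an analysis chain for
non-destructive pericarp-thickness phenotyping of cereal (sorghum-like)
kernels with spectral-domain optical coherence microscopy (OCM): raw
line-camera interferograms are reconstructed into volumetric tomograms, the
pericarp is measured in en-face (lateral) cross-sections by a sub-pixel
1/e-threshold procedure and near the seed apex by a fixed-width two-Gaussian
axial fit, and seed- and genotype-level statistics classify thin- versus
thick-pericarp phenotypes.

## Forward model (phantom_sim → `phantom.py`)

A seed is an ellipsoid (default semi-axes 2.0 × 1.75 × 1.25 mm) whose
pericarp is the band within a normal distance t(θ, φ) of the outer surface.
The thickness field is a sum of random real spherical harmonics of order
l ≤ 6 — smooth, band-limited within-seed variation — rescaled against an
area-uniform spherical sample so its standard deviation matches the
configured within-seed SD; the per-seed mean is drawn from the genotype's
between-seed distribution.  The inner boundary is treated as the
normal-offset surface of the outer ellipsoid; for 40–80 µm shells against
mm-scale axes the difference from a true offset ellipsoid is O(t²/a) and
irrelevant at the instrument's resolution.

Genotype generators (pooled site-level SD = √(between² + within²)):

| genotype | mean (µm) | between-seed SD | within-seed SD | pooled SD |
|----------|-----------|-----------------|----------------|-----------|
| thick    | 74        | 5.0             | 13.08          | ≈14       |
| thin     | 43        | 3.0             | 5.20           | ≈6        |

The means and pooled SDs are the published phenotype values for the two
genotypes; the between/within split is not published, so it was fixed once
from the observation that within-seed variation exceeds between-seed
variation, and documented here as a generator parameter rather than a
biological claim.

Scattering: the pericarp carries a dense scatterer population
(0.004 µm⁻³ inside the beam's capture cylinder) arranged as a mixture of a
uniform background (weight 0.6) and four thin sub-shells at relative depths
1/8, 3/8, 5/8, 7/8 of the local thickness (Gaussian radial profile, σ = 8%
of local thickness).  The sub-shells emulate the internal layering
(epicarp / mesocarp / endocarp interfaces) that sits below the ~20 µm axial
resolution: axial profiles show one broad merged peak whose apparent extent
is set by the inner sub-shells, while the lateral band stays quasi-uniform
(inter-layer dips stay above the 1/e threshold), matching the qualitative
appearance of real kernels.  The endosperm scatters 10× more weakly.
Reflectivities are log-normal (ln R ~ N(ln 2·10⁻⁴, 0.5²)).

Each A-scan sees an independent Poisson scatterer population inside a
cylinder of radius 2.5 beam waists around its axis (weights
w = exp(−2d²/w(z)²)); the spectrum is the standard reference-dominated
interferogram I(λ) = S(λ)[R_r + Σ wR + 2Σ w√(R_r R) cos(2k·OPL)] + ε with a
Gaussian source envelope (1030 nm center, 23 nm FWHM — chosen to reproduce
the ~20 µm in-air axial resolution), the camera sampling 2048 pixels
equidistantly in *wavelength* over 48 nm (so k-space resampling is a real
processing step; the derived 11.05 µm depth pitch matches the instrument's
printed voxel size), and additive Gaussian read noise (10⁻³ of the DC
level).  Optical path lengths accumulate physical segments times the local
refractive index (1.33 inside the seed, 1.0 outside).  Scatterer–scatterer
interference, shot noise, dispersion and polarization are not modeled.

What the generator does *not* emulate: a continuous speckle field
(neighboring A-scans draw independent populations, so lateral speckle is
uncorrelated), defocus blur beyond the capture cylinder, multiple
scattering, and absorption.  Passing tests therefore demonstrate estimator
correctness under idealized-but-speckled OCM statistics, not robustness to
every property of real kernel data.

## Reconstruction (reconstruct → `reconstruct.py`)

Per A-scan: subtract the reference spectrum (the mean of all spectra in the
acquisition), apply an apodization window, cubic-spline-interpolate onto an
equidistant wavenumber grid spanning the same k range (endpoints preserved;
batched as a precomputed sparse operator), FFT, and keep the magnitudes of
the first N/2 bins.  Repeats are reconstructed individually and magnitude-
averaged (robust to phase jitter; whether the original workflow averaged
coherently is unknown).  The window is Hann by default (−31 dB sidelobes);
the transform-limited resolution check uses the rectangular window because
the (2 ln 2/π)·λ₀²/Δλ formula presumes an unapodized Gaussian spectrum.  No
zero-padding: the 1024-bin depth axis is fixed by the spectral span.  The
DC region (first few bins) is excluded from peak searches.

## Slice and site geometry (tomogram_geom → `geometry.py`)

The widest-perimeter slice operation scores each en-face plane by the
boundary length of the segmented mask's *convex hull* and returns the
shallowest slice within three lateral pixels of the maximum (a
quantization-aware generalization of the smaller-z tie-break).  The hull
makes the criterion monotone in lateral extent; the raw boundary length of
a speckled mask is dominated by pixel-scale roughness.  Segmentation
thresholds at 3× the slice median, closes, fills holes, and keeps the
largest component.  The hilum–stylar midline is the mask's major principal
axis (near-circular masks fall back to the x-axis with a warning); the ten
sites sit where centroid rays at 30°…330° (poles excluded) cross the
boundary — the *outermost* mask crossing, so interior speckle gaps cannot
truncate the ray — each carrying a local tangent fit to a small boundary
arc.

The end-to-end study derives the site geometry from the en-face
*footprint* (maximum projection over depth): its outline is exactly the
seed's widest perimeter and, unlike any single slice, survives arbitrarily
coarse lateral sampling.  The analysis depth is then fixed *per site* on
the zoomed block, mirroring the original workflow (which selected, at each
position, the lateral cross-section where the local perimeter extension
was largest): the block's deepest detected surface anchors the local
rim-tangent depth, and among nearby slices the deepest one whose
line-averaged profile's outer 1/e crossing lies within 1 µm of the
furthest outward extension is measured.  Anchoring locally matters: at a
45 µm entire-seed pitch a global slice estimate can sit hundreds of µm off
the rim tangent, where an iso-OPL cut crosses the shell obliquely and
overstates its width severalfold.

## Lateral estimator (lateral_thickness → `lateral.py`)

Block lines (default: all of them) are Fourier low-pass filtered at 0.25×
Nyquist (removes speckle-scale noise, preserves ≥ 6 µm features at the
1.55 µm zoomed pitch), zero-padded 8× in the Fourier domain (~0.2 µm
sub-pixel grid), shifted by −i·sin α pixels to align the seed edge (α from
a least-squares line through the per-line edge centroids of the *filtered*
lines — raw-line centroids are speckle-noisy), summed, and peak-normalized.
Thickness = 1/e full width of the contiguous super-threshold region
containing the global maximum (linearly interpolated crossings) × pitch ×
cos α.  Alternatives: a variable-width Gaussian fit (thickness = 1/e full
width) and two fixed-width (2.6 µm instrument response) Gaussians fitted to
the outer flanks of the signal (thickness = center distance).

A property worth recording: on ideal smoothed top-hats the single-Gaussian
width is *slightly smaller* (≲ 1 µm) than the threshold width for widths
below ~70 µm — the threshold width grows linearly with the smoothing scale
while the fitted width grows only in quadrature.  The often-observed
opposite ordering on measured profiles comes from tails and asymmetry that
ideal top-hats lack.  The acceptance suite states the ordering in its
original direction and the corresponding test is expected to fail on
top-hat constructions; the measured margin is reported by the acceptance
script.

## Axial estimator (axial_thickness → `axial.py`)

The apex is the lateral position whose first super-threshold depth bin is
shallowest (the first 5 bins are excluded as zero-delay artifacts); a 5×5
patch of A-scans is magnitude-averaged and the depth axis divided by
n = 1.33.  Surfaces within 3 axial resolutions of the zero-delay are
rejected as unmeasurable (the documented failure mode).  The thickness is
the center distance of two Gaussians of fixed 18.8 µm 1/e width (the
in-medium axial resolution at the reference index; rescaled by 1.33/n for
other indices, which makes the whole estimate exactly ∝ 1/n) fitted by
bounded least squares inside ±5 resolutions of the surface peak, with three
deterministic initializations (two strongest local maxima; super-threshold
region edges; peak ± half-width).  On layered phantoms this estimate runs
~25–50% below the lateral one — the multilayer underestimation the lateral
method avoids.

## Statistics (stats_report → `stats.py`)

Per-seed means/SDs over sites; genotype summaries pool all site-level
measurements (sample SD, n−1) — the published genotype SDs match pooled
site-level spread, not the spread of per-seed means.  Genotype differences
use the pooled-variance Student t-test (Welch behind a flag); seeds
classify as thin below 53 µm mean thickness and thick at or above it (the
tie goes to thick by convention).  No outlier removal.  The
ellipsoidal-shell volume V = (4π/3)[abc − (a−t)(b−t)(c−t)] converts mean
thickness to pericarp volume; in the thin-shell limit it approaches surface
area × t.

## Problem sizes and numerical choices

The reduced synthetic study uses 3 seeds per genotype, 200×200 entire-seed
rasters over 5.4 mm, and 64×256 zoomed blocks at the instrument's 1.55 µm
pitch with 1 repeat — sizes chosen so the full study runs in minutes on one
core while every stage (including the genuinely chirped wavelength-domain
sampling) is exercised at full spectral size.  The √N benefit of the
instrument's 10-repeat zoomed acquisitions is verified separately at small
grid size.  The fringe synthesis evaluates cosines through an 8192-entry
lookup table (amplitude error < 3 × 10⁻⁷); reconstruction of large stacks
runs in single precision (speckle exceeds float32 rounding by many orders);
exactness-sensitive single-spectrum paths stay in double precision.

## Known limitations

- En-face slices are iso-optical-path surfaces, not geometric planes: with
  n = 1.33 the slice curves into the seed away from the rim, which biases
  ring widths by a few percent depending on the slice offset — the same
  physics applies to the real measurement.  Per-site slice refinement keeps
  the residual bias well inside the validation tolerance.
- Coarse-grid (entire-seed) lateral measurements need a pixel pitch well
  below the band width; the reduced 27 µm grid cannot provide that, so the
  study validates zoomed-block lateral and axial estimates only.
- The thickness ground truth is the generative field value at the site's
  parametric angle; midline-orientation error of the coarse mask (±1–2°)
  adds small noise to per-site truth pairing but cancels in per-seed means.
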