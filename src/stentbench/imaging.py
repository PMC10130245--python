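"""Linear system model: PSF blur, slice averaging, detector binning, noise.

A reconstruction is emulated as

1. in-plane convolution of the ground-truth grid with an isotropic Gaussian
   of FWHM ``cfg.psf_fwhm_mm``,
2. axial averaging of the fine slices that make up one detector slice of
   thickness ``cfg.slice_thickness_mm`` (contiguous, non-overlapping),
3. area-average binning onto the detector pixel grid (``cfg.pixel_mm``),
4. additive white Gaussian noise with SD ``cfg.effective_noise_sd()``.

Steps 1-3 are deterministic and exposed separately as :func:`degrade` so
noise realizations can be drawn cheaply from one degraded volume; the full
chain is :func:`apply_system`.  Every step is an averaging operation, so
with zero noise the volume mean is conserved up to boundary effects of the
blur (negligible when the field edge is uniform background).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ResolutionError
from .phantom import ImageVolume
from .systems import SystemConfig

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _integer_factor(coarse: float, fine: float, what: str) -> int:
    f = coarse / fine
    fi = int(round(f))
    if fi < 1 or abs(f - fi) > 1e-3 * f:
        raise ResolutionError(
            f"{what}: target spacing {coarse} mm is not an integer multiple "
            f"of the ground-truth spacing {fine} mm"
        )
    return fi


def degrade(truth: ImageVolume, cfg: SystemConfig) -> ImageVolume:
    """Deterministic part of the chain: blur, slice-average, pixel-bin.

    The ground-truth grid must either coincide with the detector grid
    (identity resampling) or oversample it by at least 3x in-plane, with
    integer spacing ratios in-plane and axially so binning is an exact mean.
    """
    dx, dy, dz = truth.spacing_mm
    if not math.isclose(dx, dy, rel_tol=1e-9):
        raise ResolutionError("ground-truth in-plane spacing must be isotropic")
    f = _integer_factor(cfg.pixel_mm, dx, "in-plane")
    fz = _integer_factor(cfg.slice_thickness_mm, dz, "axial")
    if f > 1 and dx > cfg.pixel_mm / 3.0 + 1e-9:
        raise ResolutionError(
            f"ground-truth spacing {dx} mm must be <= pixel_mm/3 "
            f"({cfg.pixel_mm / 3.0:.4f} mm) for adequate oversampling"
        )
    nz, ny, nx = truth.voxels.shape
    if nx % f or ny % f or nz % fz:
        raise ResolutionError(
            f"grid shape {truth.voxels.shape} not divisible by binning factors "
            f"(in-plane {f}, axial {fz})"
        )
    nx_o, ny_o, nz_o = nx // f, ny // f, nz // fz

    sigma_px = cfg.psf_fwhm_mm * _FWHM_TO_SIGMA / dx
    out = np.empty((nz_o, ny_o, nx_o), dtype=np.float32)

    # blur each fine slice once; axially constant stretches reuse the result
    prev_slice: np.ndarray | None = None
    prev_blurred: np.ndarray | None = None
    acc = np.zeros((ny, nx), dtype=np.float64)
    for j in range(nz_o):
        acc[:] = 0.0
        for k in range(j * fz, (j + 1) * fz):
            sl = truth.voxels[k]
            if prev_slice is not None and np.array_equal(sl, prev_slice):
                blurred = prev_blurred
            elif sigma_px > 0:
                blurred = gaussian_filter(
                    sl.astype(np.float32, copy=False), sigma_px, mode="nearest"
                )
            else:
                blurred = sl
            prev_slice, prev_blurred = sl, blurred
            acc += blurred
        zmean = acc / fz
        out[j] = zmean.reshape(ny_o, f, nx_o, f).mean(axis=(1, 3))

    x0 = truth.origin_mm[0] + (f - 1) / 2.0 * dx
    y0 = truth.origin_mm[1] + (f - 1) / 2.0 * dy
    z0 = truth.origin_mm[2] + (fz - 1) / 2.0 * dz
    return ImageVolume(
        out,
        spacing_mm=(cfg.pixel_mm, cfg.pixel_mm, cfg.slice_thickness_mm),
        origin_mm=(x0, y0, z0),
    )


def add_noise(volume: ImageVolume, cfg: SystemConfig, seed) -> ImageVolume:
    """Add i.i.d. Gaussian HU noise at the configuration's effective SD.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; identical
    seeds give bit-identical output.  A zero-noise configuration returns an
    unmodified copy.
    """
    sd = cfg.effective_noise_sd()
    vox = volume.voxels.astype(np.float32, copy=True)
    if sd > 0:
        rng = np.random.Generator(np.random.PCG64(seed))
        vox += rng.normal(0.0, sd, size=vox.shape).astype(np.float32)
    return ImageVolume(vox, spacing_mm=volume.spacing_mm, origin_mm=volume.origin_mm)


def apply_system(truth: ImageVolume, cfg: SystemConfig, seed) -> ImageVolume:
    """Full degradation chain: :func:`degrade` followed by :func:`add_noise`."""
    return add_noise(degrade(truth, cfg), cfg, seed)
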