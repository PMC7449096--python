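"""Denoising and foreground extraction.

The raw reconstruction contains the nuts, the low-attenuation foam holder,
air, and acquisition noise.  Preprocessing smooths the volume, thresholds it
at a greyscale level τ chosen between the foam and kernel populations (the
foam is picked precisely because it attenuates far less than nut material),
and cleans the resulting binary mask morphologically.  The voxels at or
below τ are discarded; strictly above τ are kept.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from . import partition
from .volume_io import BinaryMask, Volume3D

__all__ = [
    "PreprocessParams",
    "gaussian_smooth",
    "binarize",
    "estimate_tau",
    "clean_mask",
    "preprocess_volume",
]


@dataclasses.dataclass
class PreprocessParams:
    """Knobs of the preprocessing stage.

    ``tau`` — greyscale threshold (None → estimated from the histogram);
    ``gaussian_sigma_mm`` — denoising kernel width;
    ``morph_radius_vox`` — ball radius for opening/closing;
    ``min_spot_mm3`` — small-component rejection volume.  The default of
    100 mm³ sits two orders of magnitude below the smallest real nut
    (≈ 10,000 mm³), so it can only ever remove debris.
    """

    tau: float | None = None
    gaussian_sigma_mm: float = 0.05
    morph_radius_vox: int = 1
    min_spot_mm3: float = 100.0
    histogram_k: int = 4


def gaussian_smooth(vol: Volume3D, sigma_mm: float) -> Volume3D:
    """Gaussian denoising with the kernel width given in mm."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return Volume3D(data=vol.data.copy(), voxel_size_mm=vol.voxel_size_mm)
    sigma_vox = sigma_mm / vol.voxel_size_mm
    data = ndimage.gaussian_filter(np.asarray(vol.data, dtype=np.float64), sigma_vox)
    return Volume3D(data=data, voxel_size_mm=vol.voxel_size_mm)


def binarize(vol: Volume3D, tau: float) -> BinaryMask:
    """Foreground mask: 0 where intensity <= τ, 1 where intensity > τ."""
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    return BinaryMask(data=vol.data > tau, voxel_size_mm=vol.voxel_size_mm)


def estimate_tau(vol: Volume3D, k: int | None = None) -> float:
    """Estimate the foreground threshold from the intensity histogram.

    Clusters the histogram into ``k`` populations (default 4: air, foam,
    kernel, shell; use 3 when no foam is present) and returns the midpoint
    between the two populations directly below the shell — i.e. the boundary
    separating foam/air from kernel material.  With k = 2 the single
    between-cluster midpoint is returned.
    """
    if k is None:
        k = 4
    last_err: Exception | None = None
    for kk in range(k, 1, -1):
        try:
            clusters = partition.cluster_histogram(vol, kk)
        except ValueError as exc:
            last_err = exc
            continue
        if clusters.k >= 3:
            return float((clusters.centers[-3] + clusters.centers[-2]) / 2.0)
        return float(clusters.centers.mean())
    raise ValueError(f"histogram too degenerate to estimate tau: {last_err}")


def clean_mask(
    mask: BinaryMask, morph_radius_vox: int = 1, min_spot_mm3: float = 100.0
) -> BinaryMask:
    """Morphological opening then closing, then small-component removal."""
    if morph_radius_vox < 0:
        raise ValueError("morph_radius_vox must be >= 0")
    data = mask.data
    if morph_radius_vox > 0:
        selem = ball(morph_radius_vox)
        data = ndimage.binary_opening(data, structure=selem)
        data = ndimage.binary_closing(data, structure=selem)
    if min_spot_mm3 > 0 and data.any():
        lab, n = ndimage.label(data, structure=ndimage.generate_binary_structure(3, 3))
        if n:
            counts = np.bincount(lab.ravel())
            keep = counts * mask.voxel_volume_mm3 >= min_spot_mm3
            keep[0] = False
            data = keep[lab]
    return BinaryMask(data=data, voxel_size_mm=mask.voxel_size_mm)


def preprocess_volume(
    vol: Volume3D, params: PreprocessParams | None = None
) -> tuple[BinaryMask, float]:
    """Full preprocessing chain: smooth → threshold → clean.

    Returns the cleaned foreground mask and the τ actually used.
    """
    params = params or PreprocessParams()
    smoothed = gaussian_smooth(vol, params.gaussian_sigma_mm)
    tau = params.tau if params.tau is not None else estimate_tau(
        smoothed, k=params.histogram_k
    )
    mask = binarize(smoothed, tau)
    mask = clean_mask(mask, params.morph_radius_vox, params.min_spot_mm3)
    return mask, float(tau)
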