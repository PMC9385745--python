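"""Speckle-variance OCT angiogram processing.

Repeated B-scans acquired at each slow-axis location decorrelate over time
wherever red blood cells move, while speckle in static bulk tissue is frozen.
The temporal variance of the OCT intensity across the repetition axis is
therefore a label-free angiographic contrast: high in perfused vessels, low in
static tissue.  This module turns a raw repeated-B-scan acquisition into a
denoised 3D angiogram volume:

1. :func:`speckle_variance` — per-voxel temporal variance over repetitions;
2. :func:`lateral_average` — block averaging of adjacent slow-axis lines
   (the acquisition oversamples the slow axis to mitigate motion artifacts);
3. :func:`denoise` — grayscale morphological opening/closing with a ball
   element followed by Gaussian smoothing, which suppresses salt-and-pepper
   outliers and thin B-scan streak artifacts.

Axis convention, project-wide: raw acquisitions are ``(X, Y, R, Z)`` =
(fast lateral, slow lateral, repetition, depth); angiogram volumes are
``(X, Y, Z)``.  All indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import ball


@dataclass
class AngioVolume:
    """A 3D speckle-variance angiogram with acquisition provenance.

    Parameters
    ----------
    variance
        Non-negative float array of shape ``(X, Y, Z)``.
    voxel_pitch_um
        Physical voxel pitch ``(x, y, z)`` in micrometres.
    mouse_id, day, dose_class
        Provenance of the originating acquisition.
    """

    variance: np.ndarray
    voxel_pitch_um: tuple[float, float, float]
    mouse_id: str = ""
    day: int = 0
    dose_class: str = ""

    def __post_init__(self) -> None:
        self.variance = np.asarray(self.variance)
        if self.variance.ndim != 3:
            raise ValueError("AngioVolume.variance must be 3D (X, Y, Z)")
        if np.any(self.variance < 0):
            raise ValueError("speckle variance must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.variance.shape


@dataclass
class DenoiseParams:
    """Parameters of the morphological + Gaussian denoising step.

    ``morph_radius`` is the radius (voxels) of the ball structuring element
    used for grayscale opening then closing; ``gaussian_sigma`` the isotropic
    smoothing sigma in voxels.  Either may be zero to skip that stage.
    ``streak_suppression`` additionally rescales each slow-axis plane towards
    the median plane level, flattening whole-B-scan intensity streaks caused
    by muscle spasms during acquisition.
    """

    morph_radius: int = 1
    gaussian_sigma: float = 1.0
    streak_suppression: bool = False

    def __post_init__(self) -> None:
        if int(self.morph_radius) != self.morph_radius or self.morph_radius < 0:
            raise ValueError("morph_radius must be a non-negative integer")
        self.morph_radius = int(self.morph_radius)
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")


def speckle_variance(raw, ddof: int = 0) -> AngioVolume:
    """Compute the per-voxel temporal variance across repeated B-scans.

    Parameters
    ----------
    raw
        A ``RawAcquisition`` (or any object with ``intensity`` of shape
        ``(X, Y, R, Z)`` plus ``voxel_pitch_um``/provenance attributes).
    ddof
        Delta degrees of freedom; 0 (default) gives the population variance
        (divide by R).  The normalisation is a constant factor at fixed R and
        irrelevant to classification, but is exposed for completeness.

    Returns
    -------
    AngioVolume
        Variance volume of shape ``(X, Y, Z)``, computed in float64.
    """
    intensity = np.asarray(raw.intensity)
    if intensity.ndim != 4:
        raise ValueError("raw intensity must be 4D (X, Y, R, Z)")
    n_rep = intensity.shape[2]
    if n_rep < 2:
        raise ValueError(f"need at least 2 repetitions, got R={n_rep}")
    if np.isnan(intensity).any():
        raise ValueError("raw intensity contains NaN")
    var = np.var(intensity.astype(np.float64, copy=False), axis=2, ddof=ddof)
    return AngioVolume(
        variance=var,
        voxel_pitch_um=tuple(raw.voxel_pitch_um),
        mouse_id=getattr(raw, "mouse_id", ""),
        day=getattr(raw, "day", 0),
        dose_class=getattr(raw, "dose_class", ""),
    )


def lateral_average(vol: AngioVolume, factor: int) -> AngioVolume:
    """Average non-overlapping blocks of ``factor`` adjacent slow-axis lines.

    The slow lateral axis (Y) is oversampled during acquisition; block
    averaging restores an isotropic lateral grid (e.g. 1600 -> 800 lines at
    factor 2).  Fast-lateral and depth axes are unchanged.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return vol
    x, y, z = vol.variance.shape
    if y % factor != 0:
        raise ValueError(
            f"slow lateral axis (Y, extent {y}) is not divisible by factor {factor}"
        )
    avg = vol.variance.reshape(x, y // factor, factor, z).mean(axis=2)
    px, py, pz = vol.voxel_pitch_um
    return replace(vol, variance=avg, voxel_pitch_um=(px, py * factor, pz))


def _suppress_streaks(var: np.ndarray) -> np.ndarray:
    """Rescale each slow-axis plane to the median-filtered plane baseline."""
    plane_mean = var.mean(axis=(0, 2))
    baseline = ndimage.median_filter(plane_mean, size=7, mode="nearest")
    gain = np.divide(baseline, plane_mean, out=np.ones_like(plane_mean),
                     where=plane_mean > 0)
    return var * gain[None, :, None]


def denoise(vol: AngioVolume, params: Optional[DenoiseParams] = None) -> AngioVolume:
    """Morphological opening/closing then Gaussian smoothing of an angiogram.

    Opening with a small ball removes isolated bright outliers
    (salt noise and residual streak fragments); the subsequent closing fills
    comparably small dark pits; Gaussian smoothing raises vessel-to-background
    contrast.  Output is non-negative with the input's shape.
    """
    if params is None:
        params = DenoiseParams()
    var = vol.variance
    if params.streak_suppression:
        var = _suppress_streaks(var)
    if params.morph_radius > 0:
        selem = ball(params.morph_radius)
        var = ndimage.grey_opening(var, footprint=selem)
        var = ndimage.grey_closing(var, footprint=selem)
    if params.gaussian_sigma > 0:
        var = ndimage.gaussian_filter(var, sigma=params.gaussian_sigma)
    var = np.clip(var, 0.0, None)
    return replace(vol, variance=var)
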