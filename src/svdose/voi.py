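"""Tumour volume-of-interest (VOI) construction and CNN-ready resizing.

The imaged field of view contains the window-chamber glass, an air gap,
surrounding healthy tissue and the tumour itself.  Restricting the analysis
to the tumour keeps the classifier's feature space free of non-contributory
structure.  The VOI is built in two parts:

* **laterally** — the tumour footprint is taken from a fluorescence image of
  the labelled tumour, binarized at a fixed 8-bit threshold, and registered
  into the OCT en-face frame with a similarity transform estimated from
  user-picked fiducial pairs between the white-light and OCT images;
* **axially** — tumour surface contours drawn every 20 B-scans are linearly
  interpolated along the slow axis into a dense surface depth map; the VOI
  keeps everything from the surface down to the full acquired depth.

The final mask is the conjunction of the cylindrically projected lateral ROI
and the at-or-below-surface condition.  2D masks are indexed ``[x, y]`` and
points are ``(x, y)`` in the same index order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform


@dataclass
class SimilarityTransform:
    """Scale + rotation + translation mapping source (x, y) to target (x, y).

    ``apply`` maps points as ``s * R(theta) @ p + t`` with no reflection.
    """

    scale: float
    rotation_deg: float
    translation: tuple[float, float]
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.translation[0]],
                [self.scale * s, self.scale * c, self.translation[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]

    def inverse(self) -> "SimilarityTransform":
        inv = np.linalg.inv(self.matrix)
        scale = float(np.hypot(inv[0, 0], inv[1, 0]))
        rot = float(np.rad2deg(np.arctan2(inv[1, 0], inv[0, 0])))
        return SimilarityTransform(scale, rot, (inv[0, 2], inv[1, 2]))


@dataclass
class FiducialSet:
    """Corresponding point pairs (source frame -> target frame), in px."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise ValueError("source/target must be matching (n, 2) arrays")
        if len(self.source) < 2:
            raise ValueError("need at least 2 fiducial pairs")

    def __len__(self) -> int:
        return len(self.source)


@dataclass
class TumourVOIMask:
    """Boolean 3D tumour mask with its lateral ROI and surface contours."""

    mask: np.ndarray
    lateral_roi: np.ndarray
    surface_contours: list  # list of (b-scan index, depth profile over X)

    def __post_init__(self) -> None:
        if self.mask.ndim != 3 or self.mask.dtype != bool:
            raise ValueError("mask must be a boolean 3D array (X, Y, Z)")


def estimate_similarity(fiducials: FiducialSet) -> SimilarityTransform:
    """Least-squares similarity transform from fiducial pairs.

    Finds scale, proper rotation (no reflection) and translation minimising
    the sum of squared target residuals (Umeyama closed form, as implemented
    by scikit-image).  The RMS of the residuals is stored on the result.
    """
    src, dst = fiducials.source, fiducials.target
    if np.allclose(src, src[0]):
        raise ValueError("degenerate fiducials: all source points coincide")
    if hasattr(sktransform.SimilarityTransform, "from_estimate"):
        tf = sktransform.SimilarityTransform.from_estimate(src, dst)
        if not tf or not np.all(np.isfinite(tf.params)):
            raise ValueError("similarity estimation failed (degenerate fiducials)")
    else:  # scikit-image < 0.26
        tf = sktransform.SimilarityTransform()
        if not tf.estimate(src, dst) or not np.all(np.isfinite(tf.params)):
            raise ValueError("similarity estimation failed (degenerate fiducials)")
    scale = float(tf.scale)
    if scale <= 0 or np.linalg.det(tf.params[:2, :2]) <= 0:
        raise ValueError("degenerate fiducials: no proper similarity fits")
    rot = float(np.rad2deg(tf.rotation))
    trans = (float(tf.translation[0]), float(tf.translation[1]))
    out = SimilarityTransform(scale, rot, trans)
    resid = out.apply(src) - dst
    out.residual_rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return out


def binarize_fluorescence(image: np.ndarray, threshold: int = 77) -> np.ndarray:
    """Threshold an 8-bit fluorescence image and keep the tumour component.

    ``mask = image >= threshold`` (threshold on the 0-255 scale, default 77),
    then the largest connected component is retained and its holes filled:
    the labelled tumour is a single closed region and noise specks must not
    enter the ROI.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("fluorescence image must be 8-bit (0-255)")
    mask = img >= threshold
    if not mask.any():
        raise ValueError(f"empty mask: no pixel reaches threshold {threshold}")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


def warp_mask(
    mask: np.ndarray, tf: SimilarityTransform, target_shape: tuple[int, int]
) -> np.ndarray:
    """Resample a 2D mask into the target frame of a similarity transform.

    Inverse mapping with nearest-neighbour interpolation preserves binarity;
    pixels that map outside the source extent are False.
    """
    inv = tf.inverse()
    tx, ty = target_shape
    xx, yy = np.meshgrid(np.arange(tx), np.arange(ty), indexing="ij")
    src_pts = inv.apply(np.column_stack([xx.ravel(), yy.ravel()]))
    sx = np.rint(src_pts[:, 0]).astype(int)
    sy = np.rint(src_pts[:, 1]).astype(int)
    inside = (sx >= 0) & (sx < mask.shape[0]) & (sy >= 0) & (sy < mask.shape[1])
    out = np.zeros(target_shape, dtype=bool)
    flat = out.ravel()
    flat[inside] = mask[sx[inside], sy[inside]]
    return flat.reshape(target_shape)


def interpolate_surface(
    contours: list[tuple[int, np.ndarray]],
    n_bscans: int,
) -> np.ndarray:
    """Densify sparse per-B-scan surface contours along the slow axis.

    Parameters
    ----------
    contours
        List of ``(b-scan index, depth profile over X)`` pairs, e.g. manual
        tumour-surface contours drawn every 20 B-scans.
    n_bscans
        Slow-axis extent of the output map.

    Returns
    -------
    ndarray
        Float surface depth map of shape ``(X, n_bscans)``; linear
        interpolation between contoured B-scans, constant extrapolation
        beyond the first/last contour.
    """
    if len(contours) == 0:
        raise ValueError("need at least one contour")
    contours = sorted(contours, key=lambda c: c[0])
    ys = np.array([c[0] for c in contours])
    profiles = np.stack([np.asarray(c[1], dtype=float) for c in contours])  # (k, X)
    if len(contours) == 1:
        warnings.warn("single contour: surface is constant along the slow axis")
        return np.repeat(profiles[0][:, None], n_bscans, axis=1)
    yq = np.arange(n_bscans)
    # vectorised piecewise-linear interpolation with edge clamping
    idx = np.clip(np.searchsorted(ys, yq, side="right") - 1, 0, len(ys) - 2)
    y0, y1 = ys[idx], ys[idx + 1]
    w = np.clip((yq - y0) / (y1 - y0), 0.0, 1.0)
    dense = profiles[idx] * (1 - w)[:, None] + profiles[idx + 1] * w[:, None]
    return dense.T  # (X, n_bscans)


def build_voi(
    lateral_roi: np.ndarray,
    surface: np.ndarray,
    depth_extent: int,
    contours: list | None = None,
) -> TumourVOIMask:
    """Conjoin the projected lateral ROI with the at-or-below-surface mask.

    Voxel ``(x, y, z)`` is kept iff ``lateral_roi[x, y]`` and
    ``z >= surface[x, y]``; the mask extends from the tumour surface (just
    below the window-chamber glass) to the full acquired depth.
    """
    roi = np.asarray(lateral_roi, dtype=bool)
    surf = np.asarray(surface, dtype=float)
    if roi.shape != surf.shape:
        raise ValueError("lateral ROI and surface map shapes differ")
    z = np.arange(depth_extent)
    mask = roi[:, :, None] & (z[None, None, :] >= surf[:, :, None])
    return TumourVOIMask(mask=mask, lateral_roi=roi,
                         surface_contours=list(contours or []))


def mask_and_resize(vol, voi: TumourVOIMask, target_shape=(200, 200, 400)):
    """Zero everything outside the VOI, resample, and rescale to [0, 1].

    The masked angiogram is resampled to the CNN input shape by trilinear
    interpolation and linearly rescaled so its maximum is 1 (all-zero volumes
    stay zero).  Returns a :class:`svdose.dataset.LabeledVolume` carrying the
    acquisition provenance.
    """
    from .dataset import LabeledVolume  # local import to avoid a cycle

    var = np.asarray(vol.variance, dtype=np.float32)
    if var.shape != voi.mask.shape:
        raise ValueError(
            f"volume shape {var.shape} != VOI shape {voi.mask.shape}"
        )
    masked = np.where(voi.mask, var, 0.0).astype(np.float32)
    if tuple(target_shape) != masked.shape:
        zoom = [t / s for t, s in zip(target_shape, masked.shape)]
        masked = ndimage.zoom(masked, zoom, order=1, mode="nearest",
                              grid_mode=True)
        masked = np.clip(masked, 0.0, None)
        # grid_mode zoom can land one voxel short/long on awkward ratios;
        # guard the contract explicitly
        if masked.shape != tuple(target_shape):
            raise RuntimeError(
                f"resampling produced {masked.shape}, expected {tuple(target_shape)}"
            )
    peak = float(masked.max())
    if peak > 0:
        masked /= peak
    return LabeledVolume(
        volume=masked,
        dose_class=getattr(vol, "dose_class", ""),
        mouse_id=getattr(vol, "mouse_id", ""),
        day=getattr(vol, "day", 0),
        augmentation="original",
    )
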