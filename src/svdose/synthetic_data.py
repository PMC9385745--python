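"""Synthetic svOCT cohorts of irradiated tumour microvasculature.

The animal data this analysis was designed around (pancreatic tumours in
dorsal skinfold window chambers, imaged 2-4 weeks after single 10 Gy or
30 Gy doses) is not publicly deposited, so this module generates seeded
synthetic cohorts carrying every structure the downstream stages consume:

* a branching 3D vessel network whose volume density declines exponentially
  with time after irradiation, faster at the high dose;
* a 4D raw acquisition ``(X, Y, R, Z)`` with fully developed speckle
  (exponential intensities), temporally decorrelating inside vessels and
  frozen (replicated + small jitter) elsewhere, plus salt-and-pepper
  outliers and whole-B-scan streak artifacts;
* the window-chamber geometry: a low-signal glass/air gap above a tumour
  surface, an elliptical tumour footprint, and fiducial pairs relating the
  white-light microscope frame to the OCT en-face frame through a known
  similarity transform;
* per-volume ground truth used as oracles by the processing and VOI stages.

This is phenomenological image synthesis, not wave-optics: the contract is
that the *statistics* downstream stages rely on (temporal variance contrast,
density/dose/time trends, artifact morphology) are present and controllable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .voi import FiducialSet, SimilarityTransform, interpolate_surface

DOSE_CLASSES = ("low", "high")
DOSE_GY = {"low": 10, "high": 30}

#: Mouse/time-point layout of the two imaging cohorts: five mice per dose
#: class, each imaged at 2-3 time points between day 14 and day 32 after
#: irradiation, giving 13 low-dose and 14 high-dose volumes.
TABLE1_LAYOUT: dict[str, dict[str, tuple[int, ...]]] = {
    "low": {
        "L1": (17, 24, 31),
        "L2": (17, 24, 31),
        "L3": (15, 22),
        "L4": (15, 24, 29),
        "L5": (15, 21),
    },
    "high": {
        "H1": (16, 25, 32),
        "H2": (15, 22),
        "H3": (14, 22, 29),
        "H4": (14, 22, 29),
        "H5": (17, 26, 32),
    },
}

#: Slow-axis spacing (in B-scans) of the tumour surface contours.
CONTOUR_SPACING = 20

FULL_SCALE_SHAPE = (800, 1600, 8, 500)
DESK_SCALE_SHAPE = (128, 128, 8, 96)

#: Physical field of view: 6 x 6 mm laterally, ~2.03 mm in depth.
FOV_UM = (6000.0, 6000.0, 2030.0)


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    The defaults are the study conditions of the analysis: the published
    mouse/day layout, a base vascular volume density of 8%, and a
    dose-dependent exponential density decay anchored at day 14 (the earliest
    imaging day), with the 30 Gy class decaying much faster so that by
    day 21 its density is below a third of the 10 Gy class.
    """

    n_mice_per_class: int = 5
    days_by_mouse: dict = field(default_factory=lambda: {
        cls: dict(mice) for cls, mice in TABLE1_LAYOUT.items()
    })
    base_density: float = 0.08
    decay_per_day: dict = field(default_factory=lambda: {"low": 0.005, "high": 0.20})
    seed: int = 0
    raw_shape: tuple[int, int, int, int] = DESK_SCALE_SHAPE
    lateral_average_factor: int = 2

    # speckle / artifact model
    tissue_mean: float = 5.0
    vessel_mean: float = 40.0
    air_mean: float = 0.3
    jitter_sigma: float = 1.0
    outlier_rate: float = 0.005
    outlier_amplitude: float = 300.0
    n_streaks: int = 3
    streak_gain: float = 3.0

    # vessel geometry (voxels)
    root_radius: tuple[float, float] = (1.5, 2.4)
    branch_prob: float = 0.12
    step_length: tuple[float, float] = (3.0, 7.0)

    def __post_init__(self) -> None:
        for cls in DOSE_CLASSES:
            if cls not in self.days_by_mouse or cls not in self.decay_per_day:
                raise ValueError(f"missing dose class '{cls}'")
            for mouse, days in self.days_by_mouse[cls].items():
                if any(d < 14 or d > 32 for d in days):
                    raise ValueError(
                        f"{mouse}: days {days} outside the 2-4 week window [14, 32]"
                    )
        if not (0.0 < self.base_density < 1.0):
            raise ValueError("base_density must be in (0, 1)")
        dlo, dhi = self.decay_per_day["low"], self.decay_per_day["high"]
        if dlo < 0 or dhi < dlo:
            raise ValueError("need decay(high) >= decay(low) >= 0")
        if len(self.raw_shape) != 4:
            raise ValueError("raw_shape must be (X, Y, R, Z)")

    @classmethod
    def full_scale(cls, **kw) -> "CohortSpec":
        """The acquisition geometry of the real system (~5 GB per volume)."""
        return cls(raw_shape=FULL_SCALE_SHAPE, **kw)

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        x, y, r, z = self.raw_shape
        return (x, y, z)

    @property
    def processed_lateral_shape(self) -> tuple[int, int]:
        x, y, _, _ = self.raw_shape
        return (x, y // self.lateral_average_factor)

    @property
    def voxel_pitch_um(self) -> tuple[float, float, float]:
        x, y, _, z = self.raw_shape
        return (FOV_UM[0] / x, FOV_UM[1] / y, FOV_UM[2] / z)

    def expected_density(self, dose_class: str, day: int) -> float:
        """Expected vascular volume fraction: base * exp(-decay * (day-14))."""
        if dose_class not in DOSE_CLASSES:
            raise ValueError(f"unknown dose class '{dose_class}'")
        return self.base_density * math.exp(
            -self.decay_per_day[dose_class] * (day - 14)
        )

    def layout(self) -> list[tuple[str, str, int]]:
        """Flat cohort layout as (mouse_id, dose_class, day) records."""
        out = []
        for cls in DOSE_CLASSES:
            for mouse, days in self.days_by_mouse[cls].items():
                out.extend((mouse, cls, int(d)) for d in days)
        return out


@dataclass
class VesselNetwork:
    """A union of branching vessel trees as line segments with radii."""

    segments: list  # (start xyz, end xyz, radius) in voxel units
    shape: tuple[int, int, int]
    min_depth: Optional[np.ndarray] = None  # (X, Y) shallowest allowed vessel depth

    def __post_init__(self) -> None:
        for p0, p1, r in self.segments:
            if r <= 0:
                raise ValueError("segment radius must be positive")

    def voxelize(self) -> np.ndarray:
        """Rasterise the network into a boolean occupancy mask (X, Y, Z)."""
        mask = np.zeros(self.shape, dtype=bool)
        for p0, p1, r in self.segments:
            _stamp_segment(mask, np.asarray(p0), np.asarray(p1), r, self.min_depth)
        return mask

    @property
    def volume_fraction(self) -> float:
        return float(self.voxelize().mean())


@dataclass
class RawAcquisition:
    """4D OCT intensity array (fast X, slow Y, repetitions R, depth Z)."""

    intensity: np.ndarray
    voxel_pitch_um: tuple[float, float, float]
    mouse_id: str
    day: int
    dose_class: str

    def __post_init__(self) -> None:
        if self.intensity.ndim != 4:
            raise ValueError("intensity must be 4D (X, Y, R, Z)")
        if self.intensity.shape[2] < 2:
            raise ValueError("need at least 2 B-scan repetitions")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.intensity.shape


@dataclass
class GroundTruth:
    """Per-volume ground truth for downstream oracles.

    ``vessel_mask`` and ``surface_depth_map`` live in the raw lateral frame
    ``(X, Y)``; ``footprint`` lives in the processed (laterally averaged)
    en-face frame, which is the frame the white-light/fluorescence images are
    registered to.  ``transform`` maps white-light (x, y) to processed OCT
    (x, y) and is consistent with ``fiducials`` by construction.
    """

    vessel_mask: np.ndarray
    footprint: np.ndarray
    surface_depth_map: np.ndarray
    fiducials: FiducialSet
    transform: SimilarityTransform
    wl_shape: tuple[int, int]
    ellipse_center: tuple[float, float]
    ellipse_radii: tuple[float, float]


# ---------------------------------------------------------------------------
# geometry helpers

def surface_knots(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Integer tumour-surface depths at every CONTOUR_SPACING-th B-scan.

    The synthetic surface is piecewise-linear along the slow axis with
    integer depths at the knots, so the every-20-B-scan contour subsampling
    used downstream reconstructs it exactly.  Deterministic given the spec.
    """
    x_ext, y_ext, _, z_ext = spec.raw_shape
    ys = np.arange(0, y_ext, CONTOUR_SPACING)
    z0 = int(round(0.18 * z_ext))
    amp = max(1, int(round(0.05 * z_ext)))
    xs = np.arange(x_ext)
    knots = np.empty((x_ext, len(ys)), dtype=int)
    for k, y in enumerate(ys):
        prof = (
            z0
            + np.round(amp * np.sin(2 * np.pi * xs / x_ext)
                       * np.cos(2 * np.pi * y / y_ext)).astype(int)
            + int(round(0.01 * z_ext * y / y_ext))
        )
        knots[:, k] = np.clip(prof, 2, max(3, z_ext // 3))
    return ys, knots


def surface_depth_map(spec: CohortSpec) -> np.ndarray:
    """Dense integer surface depth map (X, Y) in the raw lateral frame."""
    ys, knots = surface_knots(spec)
    _, y_ext, _, _ = spec.raw_shape
    contours = [(int(y), knots[:, k]) for k, y in enumerate(ys)]
    dense = interpolate_surface(contours, y_ext)
    return np.ceil(dense - 1e-9).astype(int)


def _registration_geometry(spec: CohortSpec):
    """Deterministic white-light frame, tumour ellipse and true transform."""
    x_ext, y2_ext = spec.processed_lateral_shape
    wl = int(round(1.25 * x_ext))
    wl_shape = (wl, wl)
    rot_deg = 8.0
    scale = 0.8 * x_ext / wl
    centre_oct = np.array([x_ext / 2.0, y2_ext / 2.0])
    centre_wl = np.array([wl / 2.0, wl / 2.0])
    th = np.deg2rad(rot_deg)
    rotm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    translation = centre_oct - scale * rotm @ centre_wl
    tf = SimilarityTransform(scale, rot_deg, tuple(translation))
    # ellipse axis-aligned in the white-light frame, sized to sit inside the
    # processed OCT frame after mapping
    radii_oct = np.array([0.36 * x_ext, 0.30 * y2_ext])
    ellipse_radii = tuple(radii_oct / scale)
    ellipse_center = tuple(centre_wl)
    return wl_shape, ellipse_center, ellipse_radii, tf


def _ellipse_mask_wl(shape, center, radii) -> np.ndarray:
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (((xx - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2) <= 1.0


def _footprint_oct(spec: CohortSpec, center, radii, tf) -> np.ndarray:
    """Rasterise the white-light ellipse in the processed OCT frame exactly."""
    x_ext, y2_ext = spec.processed_lateral_shape
    inv = tf.inverse()
    xx, yy = np.meshgrid(np.arange(x_ext), np.arange(y2_ext), indexing="ij")
    pts = inv.apply(np.column_stack([xx.ravel(), yy.ravel()]))
    inside = (((pts[:, 0] - center[0]) / radii[0]) ** 2
              + ((pts[:, 1] - center[1]) / radii[1]) ** 2) <= 1.0
    return inside.reshape(x_ext, y2_ext)


def _fiducial_pairs(wl_shape, tf, n: int = 5) -> FiducialSet:
    wx, wy = wl_shape
    rel = np.array([
        [0.15, 0.15], [0.85, 0.20], [0.80, 0.85], [0.20, 0.80], [0.55, 0.50],
    ])[:n]
    src = rel * np.array([wx, wy])
    return FiducialSet(source=src, target=tf.apply(src))


# ---------------------------------------------------------------------------
# vessel growth

_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _sphere_offsets(radius: float) -> np.ndarray:
    key = int(round(radius * 4))
    if key not in _SPHERE_CACHE:
        r = key / 4.0
        n = int(math.floor(r))
        ax = np.arange(-n, n + 1)
        dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
        keep = dx**2 + dy**2 + dz**2 <= r**2
        _SPHERE_CACHE[key] = np.column_stack(
            [dx[keep], dy[keep], dz[keep]]
        )
    return _SPHERE_CACHE[key]


def _stamp_segment(mask, p0, p1, radius, min_depth=None) -> int:
    """Rasterise one cylinder-ish segment; returns #voxels newly set."""
    length = float(np.linalg.norm(p1 - p0))
    n_pts = max(2, int(math.ceil(length / 0.5)) + 1)
    ts = np.linspace(0.0, 1.0, n_pts)
    centers = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    pts = (centers[:, None, :] + _sphere_offsets(radius)[None, :, :]).reshape(-1, 3)
    ijk = np.rint(pts).astype(int)
    sx, sy, sz = mask.shape
    ok = ((ijk[:, 0] >= 0) & (ijk[:, 0] < sx)
          & (ijk[:, 1] >= 0) & (ijk[:, 1] < sy)
          & (ijk[:, 2] >= 0) & (ijk[:, 2] < sz))
    ijk = ijk[ok]
    if min_depth is not None:
        ijk = ijk[ijk[:, 2] >= min_depth[ijk[:, 0], ijk[:, 1]]]
    if len(ijk) == 0:
        return 0
    flat = np.unique(np.ravel_multi_index(ijk.T, mask.shape))
    new = int(np.count_nonzero(~mask.ravel()[flat]))
    mask.ravel()[flat] = True
    return new


def generate_vessel_network(
    spec: CohortSpec, dose_class: str, day: int, seed
) -> VesselNetwork:
    """Grow a branching vessel network to the dose/day target density.

    Trees are grown by biased random walks from seeded roots with a
    per-step branching probability and radius tapering; growth stops when
    the voxelized volume fraction reaches
    ``base_density * exp(-decay(dose) * (day - 14))``.  Vessels are confined
    to at least two voxels below the tumour surface (the glass/air gap above
    the surface is avascular).  Deterministic given the seed.
    """
    if dose_class not in DOSE_CLASSES:
        raise ValueError(f"unknown dose class '{dose_class}'")
    rng = np.random.default_rng(seed)
    target = spec.expected_density(dose_class, day)
    x_ext, y_ext, _, z_ext = spec.raw_shape
    shape = (x_ext, y_ext, z_ext)
    min_depth = surface_depth_map(spec) + 2
    mask = np.zeros(shape, dtype=bool)
    total = mask.size
    segments: list = []
    active: list = []
    count = 0
    max_segments = 200_000
    lo_step, hi_step = spec.step_length
    while count / total < target and len(segments) < max_segments:
        if not active:
            x = rng.uniform(3, x_ext - 3)
            y = rng.uniform(3, y_ext - 3)
            zmin = float(min_depth[int(x), int(y)])
            z = rng.uniform(min(zmin + 1, z_ext - 4), z_ext - 3)
            d = rng.normal(size=3)
            d[2] *= 0.4  # bias towards en-face wandering
            d /= np.linalg.norm(d)
            active.append((np.array([x, y, z]), d, rng.uniform(*spec.root_radius)))
        pos, direction, radius = active.pop()
        direction = direction + 0.45 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        step = rng.uniform(lo_step, hi_step)
        nxt = pos + direction * step
        nxt[0] = np.clip(nxt[0], 1, x_ext - 2)
        nxt[1] = np.clip(nxt[1], 1, y_ext - 2)
        zmin = float(min_depth[int(nxt[0]), int(nxt[1])])
        nxt[2] = np.clip(nxt[2], min(zmin, z_ext - 3), z_ext - 2)
        count += _stamp_segment(mask, pos, nxt, radius, min_depth)
        segments.append((pos.copy(), nxt.copy(), float(radius)))
        if rng.uniform() < spec.branch_prob and radius > 0.9:
            for _ in range(2):
                child = direction + 0.8 * rng.normal(size=3)
                child /= np.linalg.norm(child)
                active.append((nxt.copy(), child, radius * 0.8))
        elif radius > 0.7 and rng.uniform() > 0.03:
            active.append((nxt.copy(), direction, radius * 0.985))
    return VesselNetwork(segments=segments, shape=shape, min_depth=min_depth)


# ---------------------------------------------------------------------------
# rendering

def render_acquisition(
    network: VesselNetwork, spec: CohortSpec, seed,
    mouse_id: str = "", day: int = 0, dose_class: str = "",
) -> tuple[RawAcquisition, GroundTruth]:
    """Render a 4D speckle acquisition plus ground truth from a network.

    Static (tissue and air-gap) voxels get one exponential speckle draw
    replicated across repetitions plus Gaussian jitter; vessel voxels are
    redrawn independently per repetition (temporal decorrelation).
    Salt-and-pepper outliers corrupt a random repetition at a configurable
    rate, and whole-B-scan streaks multiply single (y, repetition) frames.
    """
    x_ext, y_ext, n_rep, z_ext = spec.raw_shape
    if n_rep < 2:
        raise ValueError("need at least 2 B-scan repetitions")
    if network.shape != (x_ext, y_ext, z_ext):
        raise ValueError(
            f"network shape {network.shape} does not match acquisition "
            f"extents {(x_ext, y_ext, z_ext)}"
        )
    rng = np.random.default_rng(seed)
    vessel = network.voxelize()
    surface = surface_depth_map(spec)
    zz = np.arange(z_ext)
    air = zz[None, None, :] < surface[:, :, None]

    base = rng.standard_exponential((x_ext, y_ext, z_ext), dtype=np.float32)
    base *= np.where(air, spec.air_mean, spec.tissue_mean).astype(np.float32)
    intensity = np.empty((x_ext, y_ext, n_rep, z_ext), dtype=np.float32)
    intensity[:] = base[:, :, None, :]
    if spec.jitter_sigma > 0:
        intensity += spec.jitter_sigma * rng.standard_normal(
            intensity.shape, dtype=np.float32
        )
    n_vessel = int(vessel.sum())
    if n_vessel:
        for r in range(n_rep):
            draws = rng.standard_exponential(n_vessel, dtype=np.float32)
            intensity[:, :, r, :][vessel] = spec.vessel_mean * draws
    if spec.outlier_rate > 0:
        n_out = int(round(spec.outlier_rate * x_ext * y_ext * z_ext))
        if n_out:
            ox = rng.integers(0, x_ext, n_out)
            oy = rng.integers(0, y_ext, n_out)
            oz = rng.integers(0, z_ext, n_out)
            orep = rng.integers(0, n_rep, n_out)
            val = np.where(rng.uniform(size=n_out) < 0.5,
                           spec.outlier_amplitude, 0.0).astype(np.float32)
            intensity[ox, oy, orep, oz] = val
    for _ in range(spec.n_streaks):
        sy = int(rng.integers(0, y_ext))
        sr = int(rng.integers(0, n_rep))
        intensity[:, sy, sr, :] *= spec.streak_gain
    np.clip(intensity, 0.0, None, out=intensity)

    wl_shape, centre, radii, tf = _registration_geometry(spec)
    gt = GroundTruth(
        vessel_mask=vessel,
        footprint=_footprint_oct(spec, centre, radii, tf),
        surface_depth_map=surface,
        fiducials=_fiducial_pairs(wl_shape, tf),
        transform=tf,
        wl_shape=wl_shape,
        ellipse_center=centre,
        ellipse_radii=radii,
    )
    raw = RawAcquisition(
        intensity=intensity,
        voxel_pitch_um=spec.voxel_pitch_um,
        mouse_id=mouse_id,
        day=day,
        dose_class=dose_class,
    )
    return raw, gt


def generate_fluorescence_image(
    gt: GroundTruth, seed, inside: float = 200.0, outside: float = 20.0,
    noise_sigma: float = 10.0,
) -> np.ndarray:
    """8-bit fluorescence image of the tumour in the white-light frame.

    Pixels inside the tumour footprint sit well above the downstream
    binarization threshold (77/256) and pixels outside well below it; the
    image is related to the OCT en-face frame by the ground-truth similarity
    transform.
    """
    rng = np.random.default_rng(seed)
    ell = _ellipse_mask_wl(gt.wl_shape, gt.ellipse_center, gt.ellipse_radii)
    img = np.where(ell, float(inside), float(outside))
    if noise_sigma > 0:
        img = img + noise_sigma * rng.standard_normal(img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# cohorts

def _volume_seed_seq(spec: CohortSpec, dose_class: str, mouse_id: str, day: int):
    cls_idx = DOSE_CLASSES.index(dose_class)
    mouse_idx = sorted(spec.days_by_mouse[dose_class]).index(mouse_id)
    return np.random.SeedSequence([spec.seed, cls_idx, mouse_idx, int(day)])


def iter_cohort(spec: CohortSpec) -> Iterator[tuple[RawAcquisition, GroundTruth]]:
    """Yield (acquisition, ground truth) per cohort volume, lazily.

    One global seed expands deterministically into independent per-volume
    streams, so cohorts are reproducible piecewise.
    """
    for mouse_id, dose_class, day in spec.layout():
        ss = _volume_seed_seq(spec, dose_class, mouse_id, day)
        net_seed, render_seed = ss.spawn(2)
        network = generate_vessel_network(spec, dose_class, day, net_seed)
        yield render_acquisition(
            network, spec, render_seed,
            mouse_id=mouse_id, day=day, dose_class=dose_class,
        )


def cohort_manifest(spec: CohortSpec, out_dir=None) -> pd.DataFrame:
    """Manifest with one record per volume: mouse_id, dose_class, day, path."""
    records = [
        {
            "mouse_id": m,
            "dose_class": c,
            "day": d,
            "path": f"{m}_day{d:02d}.h5" if out_dir is None else
                    str(out_dir / f"{m}_day{d:02d}.h5"),
        }
        for m, c, d in spec.layout()
    ]
    return pd.DataFrame.from_records(records)


def generate_cohort(
    spec: CohortSpec, out_dir=None, storage: str = "hdf5"
) -> list[tuple[RawAcquisition, GroundTruth]]:
    """Generate the full cohort; optionally write volumes and the manifest.

    With the default layout this produces 13 low-dose and 14 high-dose
    volumes from 10 mice.  When ``out_dir`` is given, each acquisition is
    written in the requested container format alongside a ``manifest.csv``.
    """
    from . import io as _io

    out = list(iter_cohort(spec))
    if out_dir is not None:
        import pathlib

        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = cohort_manifest(spec, out_dir=out_dir)
        for (raw, _gt), path in zip(out, manifest["path"]):
            if storage == "hdf5":
                _io.write_acquisition_h5(raw, path)
            elif storage == "tiff":
                _io.write_acquisition_tiff(raw, str(path).replace(".h5", ""))
            else:
                raise ValueError(f"unknown storage '{storage}'")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out
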