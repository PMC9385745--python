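"""Mouse-level train/test splits and 3D augmentation.

With only 27 unique volumes from 10 mice, two safeguards matter:

* **No mouse leakage** — train/test splits are made at the *mouse* level, so
  all time points of an animal travel together and no animal contributes to
  both sets of a run.  Five disjoint runs hold out each mouse as a test
  mouse exactly once per class.
* **Label-preserving augmentation** — 3D horizontal/vertical flips and
  en-face rotations (angles in [-40, 90] degrees about the depth axis),
  singly and composed, scale each class up to fixed counts (100 training /
  16 testing per class by default) while preserving labels, mouse ids and
  shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

ROTATION_RANGE_DEG = (-40.0, 90.0)
POSITIVE_CLASS = "low"  # positive = low dose (10 Gy)


@dataclass
class LabeledVolume:
    """A CNN-ready volume with dose label and provenance."""

    volume: np.ndarray
    dose_class: str
    mouse_id: str
    day: int
    augmentation: str = "original"

    def __post_init__(self) -> None:
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D")
        if not self.dose_class or not self.mouse_id:
            raise ValueError("dose class and mouse id must be non-empty")

    @property
    def label(self) -> int:
        return encode_label(self.dose_class)


@dataclass(frozen=True)
class SplitPlan:
    """One train/test combination at the mouse level."""

    run_id: int
    train_mice: frozenset
    test_mice: frozenset
    seed: int

    def __post_init__(self) -> None:
        if self.train_mice & self.test_mice:
            raise ValueError(
                f"run {self.run_id}: mice {sorted(self.train_mice & self.test_mice)} "
                "appear in both train and test"
            )


@dataclass
class InputTensor:
    """Samples stacked as (n, length, width, depth, colour channel)."""

    samples: np.ndarray
    labels: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.samples.ndim != 5 or self.samples.shape[-1] != 1:
            raise ValueError(
                "samples must be (n, length, width, depth, 1); got "
                f"{self.samples.shape}"
            )
        if len(self.labels) != len(self.samples):
            raise ValueError("labels/samples length mismatch")


def encode_label(dose_class: str) -> int:
    """low dose (10 Gy) -> 1 (positive); high dose (30 Gy) -> 0."""
    if dose_class == POSITIVE_CLASS:
        return 1
    if dose_class == "high":
        return 0
    raise ValueError(f"unknown dose class '{dose_class}'")


def decode_label(label: int) -> str:
    return POSITIVE_CLASS if int(label) == 1 else "high"


def make_splits(
    manifest: pd.DataFrame, n_runs: int = 5, seed: int = 0,
    n_test_per_class: int = 1,
) -> list[SplitPlan]:
    """Plan disjoint-test-mouse train/test runs from a cohort manifest.

    Each run holds out ``n_test_per_class`` test mice per dose class and
    trains on all remaining mice; across ``n_runs`` runs every mouse serves
    as a test mouse exactly once (requires at least ``n_runs`` mice per
    class).  Volumes (time points) follow their mouse.
    """
    classes = sorted(manifest["dose_class"].unique())
    rng = np.random.default_rng(seed)
    perms = {}
    for cls in classes:
        mice = sorted(manifest.loc[manifest["dose_class"] == cls, "mouse_id"].unique())
        if len(mice) < n_runs * n_test_per_class:
            raise ValueError(
                f"class '{cls}' has {len(mice)} mice; "
                f"{n_runs} disjoint runs need at least {n_runs * n_test_per_class}"
            )
        perms[cls] = [mice[i] for i in rng.permutation(len(mice))]
    all_mice = frozenset(manifest["mouse_id"].unique())
    plans = []
    for run in range(n_runs):
        test = frozenset(
            m
            for cls in classes
            for m in perms[cls][run * n_test_per_class:(run + 1) * n_test_per_class]
        )
        plans.append(
            SplitPlan(run_id=run + 1, train_mice=all_mice - test,
                      test_mice=test, seed=seed)
        )
    return plans


def split_volumes(
    volumes: Sequence[LabeledVolume], plan: SplitPlan
) -> tuple[list[LabeledVolume], list[LabeledVolume]]:
    """Partition volumes by the plan's mouse sets, asserting zero leakage."""
    train = [v for v in volumes if v.mouse_id in plan.train_mice]
    test = [v for v in volumes if v.mouse_id in plan.test_mice]
    if len(train) + len(test) != len(volumes):
        missing = {v.mouse_id for v in volumes} - plan.train_mice - plan.test_mice
        raise ValueError(f"volumes from mice {sorted(missing)} not covered by plan")
    assert not ({v.mouse_id for v in train} & {v.mouse_id for v in test})
    return train, test


# ---------------------------------------------------------------------------
# augmentation

def flip_horizontal(vol: np.ndarray) -> np.ndarray:
    """Mirror along the fast lateral (X) axis."""
    return vol[::-1, :, :].copy()


def flip_vertical(vol: np.ndarray) -> np.ndarray:
    """Mirror along the slow lateral (Y) axis."""
    return vol[:, ::-1, :].copy()


def rotate_enface(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate in the en-face (X-Y) plane about the depth axis.

    Linear interpolation with zero padding; the depth-anisotropic geometry of
    the acquisition is respected by never rotating through depth.
    """
    if angle_deg == 0.0:
        return vol.copy()
    return ndimage.rotate(
        vol, angle_deg, axes=(0, 1), reshape=False, order=1,
        mode="constant", cval=0.0,
    )


def _sample_transform(rng: np.random.Generator):
    """A random flip/rotation composition; never the identity."""
    while True:
        do_h = rng.uniform() < 0.5
        do_v = rng.uniform() < 0.5
        do_r = rng.uniform() < 0.9
        if do_h or do_v or do_r:
            break
    ops, tags = [], []
    if do_h:
        ops.append(flip_horizontal)
        tags.append("hflip")
    if do_v:
        ops.append(flip_vertical)
        tags.append("vflip")
    if do_r:
        angle = float(rng.uniform(*ROTATION_RANGE_DEG))
        ops.append(lambda v, a=angle: rotate_enface(v, a))
        tags.append(f"rot{angle:.1f}")
    return ops, "+".join(tags)


def apply_transform(vol: LabeledVolume, ops, tag: str) -> LabeledVolume:
    out = vol.volume
    for op in ops:
        out = op(out)
    return replace(vol, volume=out, augmentation=tag)


def augment_to_count(
    volumes: Sequence[LabeledVolume], target_per_class: int, seed,
) -> list[LabeledVolume]:
    """Augment each dose class up to a fixed count, originals retained.

    The extra copies are distributed near-equally over the originals of each
    class (ceiling-balanced), each produced by a freshly sampled flip/rotation
    composition.  Labels, mouse ids, days and shapes are preserved; the
    ``augmentation`` tag records the transform chain.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabeledVolume]] = {}
    for v in volumes:
        by_class.setdefault(v.dose_class, []).append(v)
    out: list[LabeledVolume] = []
    for cls in sorted(by_class):
        originals = by_class[cls]
        if target_per_class < len(originals):
            raise ValueError(
                f"class '{cls}': target {target_per_class} below the "
                f"{len(originals)} originals"
            )
        n_extra = target_per_class - len(originals)
        base, rem = divmod(n_extra, len(originals))
        out.extend(originals)
        for i, orig in enumerate(originals):
            for _ in range(base + (1 if i < rem else 0)):
                ops, tag = _sample_transform(rng)
                out.append(apply_transform(orig, ops, tag))
    return out


def assemble_tensor(volumes: Sequence[LabeledVolume]) -> InputTensor:
    """Stack volumes into the (n, length, width, depth, 1) input tensor."""
    if len(volumes) == 0:
        raise ValueError("no volumes to assemble")
    shapes = {v.volume.shape for v in volumes}
    if len(shapes) > 1:
        offenders = sorted(
            f"{v.mouse_id}/day{v.day}/{v.augmentation}:{v.volume.shape}"
            for v in volumes
        )
        raise ValueError(f"heterogeneous volume shapes: {offenders}")
    samples = np.stack(
        [v.volume.astype(np.float32, copy=False) for v in volumes]
    )[..., None]
    labels = np.array([v.label for v in volumes], dtype=np.int8)
    provenance = [
        {"mouse_id": v.mouse_id, "dose_class": v.dose_class, "day": v.day,
         "augmentation": v.augmentation}
        for v in volumes
    ]
    return InputTensor(samples=samples, labels=labels, provenance=provenance)
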