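"""Assemble masked slice stacks into normalized 3-D volumes and provide the
in-plane rotation augmentation used during classifier training."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import SliceStack


@dataclass
class Volume3D:
    """Background-eliminated slices resized and stacked, values in [0, 1]."""

    embryo_id: str
    voxels: np.ndarray  # (n_slices, H, W), bottom -> top
    intensity_scale: str = "minmax"
    degenerate: bool = False  # constant input volume (min == max)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be (n_slices, H, W)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")


def _area_weights(n_src: int, n_dst: int) -> np.ndarray:
    """Row-stochastic (n_dst, n_src) box-overlap matrix for exact
    area-weighted 1-D downsampling."""
    w = np.zeros((n_dst, n_src))
    scale = n_src / n_dst
    for i in range(n_dst):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_src)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / scale


def area_resize(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Exact area-weighted (box-average) resize of a 2-D image."""
    wr = _area_weights(image.shape[0], target[0])
    wc = _area_weights(image.shape[1], target[1])
    return wr @ image @ wc.T


def reconstruct_volume(masked: SliceStack, target_px: int = 111) -> Volume3D:
    """Downsample each slice by area-weighted interpolation and min-max
    normalize the assembled volume to [0, 1].

    A constant (or all-zero) input maps to an all-zero volume flagged
    degenerate, per the min-max convention when min == max.
    """
    slices = masked.as_array()
    if slices.shape[1] != slices.shape[2]:
        raise ValueError("slices must be square")
    if slices.shape[1] < target_px:
        raise ValueError(
            f"slice size {slices.shape[1]} smaller than target {target_px}"
        )
    resized = np.stack([area_resize(s, (target_px, target_px)) for s in slices])
    lo, hi = resized.min(), resized.max()
    if hi - lo > 1e-12 * max(abs(hi), 1.0):
        vox = (resized - lo) / (hi - lo)
        degenerate = False
    else:
        vox = np.zeros_like(resized)
        degenerate = True
    return Volume3D(embryo_id=masked.embryo_id, voxels=vox,
                    intensity_scale=f"minmax[{lo:.6g},{hi:.6g}]",
                    degenerate=degenerate)


def rotate_array(voxels: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate every slice of a (D, H, W) array by the same in-plane angle
    about the slice center (bilinear, zero fill). Positive angles follow the
    ``np.rot90(..., axes=(1, 2))`` direction; multiples of 360 are exact."""
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    a = angle_deg % 360.0
    if a == 0.0:
        return voxels.copy()
    return ndimage.rotate(voxels, a, axes=(2, 1), reshape=False, order=1,
                          mode="constant", cval=0.0, prefilter=False)


def rotate_volume(vol: Volume3D, angle_deg: float) -> Volume3D:
    """Rigid rotation about the optical (vertical) axis; see :func:`rotate_array`."""
    return Volume3D(embryo_id=vol.embryo_id,
                    voxels=np.clip(rotate_array(vol.voxels, angle_deg), 0.0, 1.0),
                    intensity_scale=vol.intensity_scale,
                    degenerate=vol.degenerate)


@dataclass
class AugmentedSet:
    """Training volumes after rotation augmentation; labels and embryo ids
    are copied onto every rotated duplicate (leakage checks rely on ids)."""

    volumes: np.ndarray  # (N, D, H, W) float32
    labels: np.ndarray
    ids: np.ndarray
    angles: np.ndarray = field(default=None)


def augment_arrays(volumes: np.ndarray, labels, ids, times: int,
                   seed: int) -> AugmentedSet:
    """Each input plus (times - 1) copies rotated by seeded uniform angles."""
    if times < 1:
        raise ValueError("times must be >= 1")
    volumes = np.asarray(volumes)
    labels = np.asarray(labels)
    ids = np.asarray(ids)
    if times == 1:
        return AugmentedSet(volumes=volumes.copy(), labels=labels.copy(),
                            ids=ids.copy(), angles=np.zeros(len(labels)))
    rng = np.random.default_rng([int(seed), 0xA06])
    n = volumes.shape[0]
    angles = rng.uniform(0.0, 360.0, size=(times - 1, n))
    out_v = [volumes]
    out_a = [np.zeros(n)]
    for t in range(times - 1):
        rot = np.stack([
            rotate_array(volumes[i].astype(np.float64), angles[t, i])
            for i in range(n)
        ]).astype(volumes.dtype)
        out_v.append(rot)
        out_a.append(angles[t])
    return AugmentedSet(
        volumes=np.concatenate(out_v, axis=0),
        labels=np.tile(labels, times),
        ids=np.tile(ids, times),
        angles=np.concatenate(out_a),
    )


def augment_dataset(volumes: list[Volume3D], labels, times: int,
                    seed: int) -> tuple[list[Volume3D], np.ndarray]:
    """:func:`augment_arrays` over Volume3D objects; applies only to training
    folds — the CV harness asserts augmented ids never reach validation/test."""
    arr = np.stack([v.voxels for v in volumes])
    ids = np.array([v.embryo_id for v in volumes])
    aug = augment_arrays(arr, labels, ids, times, seed)
    out = [
        Volume3D(embryo_id=aug.ids[i], voxels=np.clip(aug.volumes[i], 0.0, 1.0))
        for i in range(aug.volumes.shape[0])
    ]
    return out, aug.labels
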