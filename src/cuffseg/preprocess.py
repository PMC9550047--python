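"""Spacing resampling, intensity normalization, patch sampling, augmentation.

All spatial operations keep the (slice, row, col) axis convention with the
slice axis the anisotropic one.  Intensity volumes are interpolated linearly
and label maps by nearest neighbour, so resampling can never invent a class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import ImageVolume, LabelMap

__all__ = [
    "PatchSpec",
    "AugmentParams",
    "resample_to_spacing",
    "normalize_intensity",
    "sample_patches",
    "augment",
]

FULL_SLICE = "full-slice"  # 2D mode marker: patches are whole single slices


@dataclass(frozen=True)
class PatchSpec:
    """Sub-volume sampling geometry.

    ``patch_shape`` is a (slice,row,col) voxel triple, or the string
    ``"full-slice"`` for 2D mode where each patch is one full-resolution
    slice.  ``foreground_bias`` is the probability that a sampled patch is
    centred on a foreground voxel.
    """

    patch_shape: tuple[int, int, int] | str = (8, 32, 32)
    foreground_bias: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.foreground_bias <= 1.0:
            raise ValueError(f"foreground_bias must be in [0,1], got {self.foreground_bias}")
        if isinstance(self.patch_shape, str):
            if self.patch_shape != FULL_SLICE:
                raise ValueError(f"unknown patch mode {self.patch_shape!r}")
        elif len(self.patch_shape) != 3 or any(int(p) < 1 for p in self.patch_shape):
            raise ValueError(f"patch_shape must be 3 positive ints, got {self.patch_shape}")

    @property
    def is_2d(self) -> bool:
        return isinstance(self.patch_shape, str)

    def shape_for(self, volume_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """Concrete patch shape for a given volume (resolves 2D mode)."""
        if self.is_2d:
            return (1, volume_shape[1], volume_shape[2])
        return tuple(int(p) for p in self.patch_shape)


def resample_to_spacing(vol, target_spacing_mm):
    """Resample a volume or label map to a new voxel spacing.

    The output shape per axis is ``round(shape * spacing / target)``.
    Intensities are interpolated linearly; labels by nearest neighbour.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if len(target) != 3 or any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be 3 positive values, got {target}")

    is_label = isinstance(vol, LabelMap)
    data = vol.labels if is_label else vol.values
    in_shape = np.array(data.shape, dtype=float)
    in_spacing = np.array(vol.spacing_mm, dtype=float)
    out_shape = np.round(in_shape * in_spacing / np.array(target)).astype(int)
    out_shape = np.maximum(out_shape, 1)

    if tuple(out_shape) == data.shape and np.allclose(in_spacing, target):
        return (
            LabelMap(labels=data.copy(), spacing_mm=target, n_classes=vol.n_classes)
            if is_label
            else ImageVolume(values=data.copy(), spacing_mm=target)
        )

    # map output voxel centres onto input index space
    coords = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * t / s - 0.5
            for n, t, s in zip(out_shape, target, in_spacing)
        ],
        indexing="ij",
    )
    if is_label:
        out = ndimage.map_coordinates(
            vol.labels, coords, order=0, mode="nearest", output=vol.labels.dtype
        )
        return LabelMap(labels=out, spacing_mm=target, n_classes=vol.n_classes)
    out = ndimage.map_coordinates(
        vol.values.astype(np.float32), coords, order=1, mode="nearest"
    )
    return ImageVolume(values=out.astype(np.float32), spacing_mm=target)


def normalize_intensity(vol: ImageVolume) -> ImageVolume:
    """Percentile-clipped z-score normalization of one volume.

    Values are clipped to the [0.5, 99.5] percentile band, then shifted and
    scaled to zero mean / unit variance over the whole volume.  A constant
    volume maps to all zeros (with a warning), the only degenerate case.
    """
    v = vol.values.astype(np.float32)
    lo, hi = np.percentile(v, [0.5, 99.5])
    v = np.clip(v, lo, hi)
    sd = float(v.std())
    if sd == 0.0:
        warnings.warn("constant volume: normalization returns all zeros", stacklevel=2)
        return ImageVolume(values=np.zeros_like(v), spacing_mm=vol.spacing_mm)
    v = (v - float(v.mean())) / sd
    return ImageVolume(values=v, spacing_mm=vol.spacing_mm)


def _pad_to(arr, shape, constant):
    pads = [(0, max(0, t - s)) for s, t in zip(arr.shape, shape)]
    if any(p[1] for p in pads):
        arr = np.pad(arr, pads, constant_values=constant)
    return arr


def sample_patches(case, spec: PatchSpec, n: int, rng: np.random.Generator):
    """Draw ``n`` co-located (image, label) patch pairs from one case.

    With probability ``foreground_bias`` the patch centre lands on a voxel
    with a foreground label.  Volumes smaller than the patch are zero-padded
    (labels padded with background) with a warning.
    """
    image, truth = case.image.values, case.truth.labels
    pshape = spec.shape_for(image.shape)
    if any(p > s for p, s in zip(pshape, image.shape)):
        warnings.warn(
            f"patch {pshape} exceeds volume {image.shape}; zero-padding", stacklevel=2
        )
        target = tuple(max(p, s) for p, s in zip(pshape, image.shape))
        image = _pad_to(image, target, 0.0)
        truth = _pad_to(truth, target, 0)

    fg = np.argwhere(truth != 0)
    out = []
    for _ in range(n):
        if fg.size and rng.random() < spec.foreground_bias:
            centre = fg[rng.integers(len(fg))]
        else:
            centre = np.array([rng.integers(s) for s in truth.shape])
        starts = [
            int(np.clip(c - p // 2, 0, s - p))
            for c, p, s in zip(centre, pshape, truth.shape)
        ]
        sl = tuple(slice(st, st + p) for st, p in zip(starts, pshape))
        out.append((image[sl].copy(), truth[sl].copy()))
    return out


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the five training-time augmentations.

    Spatial transforms (in-plane rotation about the slice axis, isotropic
    in-plane scaling) are applied identically to image and label (nearest
    neighbour for labels); brightness / contrast / gamma touch the image
    only.  Degenerate ranges disable a transform exactly.
    """

    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    scale: tuple[float, float] = (0.9, 1.1)
    brightness: tuple[float, float] = (-0.1, 0.1)
    contrast: tuple[float, float] = (0.9, 1.1)
    gamma: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if self.gamma[0] <= 0 or self.gamma[1] <= 0:
            raise ValueError(f"gamma range must be positive, got {self.gamma}")
        if self.scale[0] <= 0 or self.scale[1] <= 0:
            raise ValueError(f"scale range must be positive, got {self.scale}")

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(
            rotation_deg=(0.0, 0.0),
            scale=(1.0, 1.0),
            brightness=(0.0, 0.0),
            contrast=(1.0, 1.0),
            gamma=(1.0, 1.0),
        )


def _inplane_rotate(arr, angle_deg, order):
    cval = 0
    return ndimage.rotate(
        arr, angle_deg, axes=(1, 2), reshape=False, order=order, mode="constant", cval=cval
    )


def _inplane_scale(arr, factor, order):
    zoomed = ndimage.zoom(arr, (1.0, factor, factor), order=order, mode="constant", cval=0)
    out = np.zeros_like(arr)
    # centre-crop or centre-pad back to the original in-plane shape
    src, dst = [], []
    for s_out, s_in in zip(arr.shape, zoomed.shape):
        if s_in >= s_out:
            off = (s_in - s_out) // 2
            src.append(slice(off, off + s_out))
            dst.append(slice(0, s_out))
        else:
            off = (s_out - s_in) // 2
            src.append(slice(0, s_in))
            dst.append(slice(off, off + s_in))
    out[tuple(dst)] = zoomed[tuple(src)]
    return out


def augment(image_patch, label_patch, params: AugmentParams, rng: np.random.Generator):
    """Apply one random draw of the five augmentations to a patch pair."""
    img = np.asarray(image_patch, dtype=np.float32)
    lbl = np.asarray(label_patch)

    angle = float(rng.uniform(*params.rotation_deg))
    scale = float(rng.uniform(*params.scale))
    bright = float(rng.uniform(*params.brightness))
    contr = float(rng.uniform(*params.contrast))
    gamma = float(rng.uniform(*params.gamma))

    if angle != 0.0:
        img = _inplane_rotate(img, angle, order=1)
        lbl = _inplane_rotate(lbl, angle, order=0)
    if scale != 1.0:
        img = _inplane_scale(img, scale, order=1)
        lbl = _inplane_scale(lbl, scale, order=0)
    if bright != 0.0:
        img = img + bright
    if contr != 1.0:
        m = img.mean()
        img = m + contr * (img - m)
    if gamma != 1.0:
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = ((img - lo) / (hi - lo)) ** gamma * (hi - lo) + lo
    return img.astype(np.float32), lbl
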