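"""Volume/label data model, NIfTI I/O, dataset splitting and mesh export.

The in-memory unit of every pipeline stage is a 3-D scalar array with
millimetre voxel spacing, axis order ``(slice, row, col)`` with the slice
axis the anisotropic one (e.g. 2.5 mm slices vs 0.29 mm in-plane).  Only
spacing is tracked; full affine orientation is out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelMap",
    "DatasetSplit",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "split_dataset",
    "labelmap_to_mesh",
    "write_mesh_stl",
]


@dataclass
class ImageVolume:
    """A 3-D intensity volume with per-axis voxel spacing in millimetres.

    ``values`` is indexed ``(slice, row, col)``; ``spacing_mm`` follows the
    same order, slice axis first.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"ImageVolume requires a rank-3 array, got rank {self.values.ndim}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageVolume values must be finite (no NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LabelMap:
    """An integer class map on the same grid convention as :class:`ImageVolume`.

    Labels lie in ``[0, n_classes)`` with 0 reserved for background.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(
                f"LabelMap requires a rank-3 array, got rank {self.labels.ndim}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise ValueError("LabelMap values must be integral")
            self.labels = self.labels.astype(np.int16)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if self.labels.size:
            lo, hi = int(self.labels.min()), int(self.labels.max())
            if lo < 0 or hi >= self.n_classes:
                raise ValueError(
                    f"labels must lie in [0, {self.n_classes}), found range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class DatasetSplit:
    """Disjoint train / tune / test case-id lists covering a cohort."""

    train_ids: list[str]
    tune_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        groups = [set(self.train_ids), set(self.tune_ids), set(self.test_ids)]
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise ValueError("split groups must be pairwise disjoint")

    @property
    def all_ids(self) -> list[str]:
        return list(self.train_ids) + list(self.tune_ids) + list(self.test_ids)


def _spacing_to_affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    # axis order (slice,row,col) is stored as-is; the affine only carries spacing
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write an intensity volume to NIfTI (.nii / .nii.gz), float32 storage."""
    img = nib.Nifti1Image(
        np.asarray(vol.values, dtype=np.float32), _spacing_to_affine(vol.spacing_mm)
    )
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a 3-D NIfTI intensity volume; rejects non-3D files."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, file has rank {data.ndim}: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(values=np.asarray(data, dtype=np.float32), spacing_mm=spacing)


def write_labelmap(lm: LabelMap, path: str | os.PathLike) -> None:
    """Write a label map to NIfTI with integer storage (lossless round-trip)."""
    img = nib.Nifti1Image(
        np.asarray(lm.labels, dtype=np.int16), _spacing_to_affine(lm.spacing_mm)
    )
    img.header.set_zooms(lm.spacing_mm)
    nib.save(img, os.fspath(path))


def read_labelmap(path: str | os.PathLike, n_classes: int) -> LabelMap:
    """Read an integer label map, validating the label range against n_classes."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D label map, file has rank {data.ndim}: {path}")
    if not np.all(data == np.round(data)):
        raise ValueError(f"label map contains non-integral values: {path}")
    data = data.astype(np.int16)
    if data.size and (data.min() < 0 or data.max() >= n_classes):
        raise ValueError(
            f"label {int(data.max())} out of range for n_classes={n_classes}: {path}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(labels=data, spacing_mm=spacing, n_classes=n_classes)


def split_dataset(
    case_ids: list[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Randomly partition case ids into train / tune / test sets.

    Group sizes are the largest-remainder rounding of ``fractions * n``, with
    ties broken toward the earlier group (train first), which reproduces the
    conventional 34/11/11 split of a 56-case cohort at (0.6, 0.2, 0.2).
    """
    case_ids = list(case_ids)
    n = len(case_ids)
    if n < 3:
        raise ValueError(f"need at least 3 cases to split, got {n}")
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be 3 positive values summing to 1, got {fr}")

    raw = [f * n for f in fr]
    sizes = [int(np.floor(r)) for r in raw]
    rema = [r - s for r, s in zip(raw, sizes)]
    # hand out the remainder to the largest fractional parts; ties favour train
    order = sorted(range(3), key=lambda i: (-rema[i], i))
    for i in order[: n - sum(sizes)]:
        sizes[i] += 1

    rng = np.random.default_rng(seed)
    perm = [case_ids[i] for i in rng.permutation(n)]
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(train_ids=perm[:a], tune_ids=perm[a:b], test_ids=perm[b:])


def labelmap_to_mesh(lm: LabelMap, class_id: int):
    """Extract a closed triangle surface of one class at the 0.5 iso-level.

    Returns ``(vertices, faces)`` with vertices in millimetre coordinates
    (index times spacing). Raises if the class is absent.
    """
    from skimage import measure

    indicator = (lm.labels == class_id).astype(np.float32)
    if not indicator.any():
        raise ValueError(f"class {class_id} absent from label map")
    # zero-pad so structures touching the border still yield a watertight surface
    padded = np.pad(indicator, 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=lm.spacing_mm)
    verts = verts - np.asarray(lm.spacing_mm)  # undo the pad offset
    return verts, faces


def write_mesh_stl(verts: np.ndarray, faces: np.ndarray, path: str | os.PathLike) -> None:
    """Write a triangle mesh to STL."""
    import trimesh

    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(os.fspath(path))


def mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Signed volume enclosed by a closed triangle mesh, in mm^3."""
    import trimesh

    return float(abs(trimesh.Trimesh(vertices=verts, faces=faces, process=False).volume))
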