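"""Labelled voxel volumes with world geometry.

A :class:`LabelVolume` is the computational domain for all field and coverage
computations: an integer label grid (0 = surrounding soft tissue, 1 = bone,
2 = tumor) together with voxel spacing and world origin in millimetres.

Conventions
-----------
* Array axes are (x, y, z) in a right-handed frame: x = left->right,
  y = posterior->anterior, z = inferior->superior.
* Voxel indices are 0-based; world coordinates refer to voxel *centers*:
  ``world = origin + index * spacing``.
* Files are read and written through SimpleITK (NIfTI ``.nii``/``.nii.gz`` and
  MetaImage ``.mha``/``.mhd``), which stores arrays as (z, y, x); the transpose
  is applied centrally here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

SURROUNDING = 0
BONE = 1
TUMOR = 2

DEFAULT_LEGEND: dict[int, str] = {
    SURROUNDING: "surrounding tissue",
    BONE: "bone",
    TUMOR: "tumor",
}


@dataclass
class LabelVolume:
    """Labelled voxel grid with world geometry (mm).

    Parameters
    ----------
    labels : ndarray of int, shape (nx, ny, nz)
        Tissue label per voxel.
    spacing : tuple of float
        Per-axis voxel size in mm; strictly positive.
    origin : tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    legend : dict
        Mapping of label value to tissue name.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        unknown = sorted(set(np.unique(self.labels)) - set(self.legend))
        if unknown:
            raise ValueError(
                "unknown label" + ("s" if len(unknown) > 1 else "")
                + " " + ", ".join(str(u) for u in unknown)
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent of the grid (mm), counting full voxel widths."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D world coordinates (mm) of voxel centers along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    def index_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of voxel center(s); index may be (..., 3)."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_to_index(self, point) -> np.ndarray:
        """Nearest voxel index for world point(s) (mm)."""
        rel = (np.asarray(point) - np.asarray(self.origin)) / np.asarray(self.spacing)
        return np.rint(rel).astype(int)

    def contains_point(self, point) -> bool:
        """True if the world point lies within the physical grid extent."""
        idx = (np.asarray(point) - np.asarray(self.origin)) / np.asarray(self.spacing)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def write_label_volume(volume: LabelVolume, path) -> None:
    """Write a label volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = str(path)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(volume.labels, (2, 1, 0)).astype(np.int16))
    )
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, path)


def read_label_volume(path, legend: dict[int, str] | None = None) -> LabelVolume:
    """Read a label volume from NIfTI or MetaImage.

    Raises
    ------
    ValueError
        If the file holds non-integer voxel values, labels not present in the
        legend, or a non-axis-aligned orientation.
    """
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(path)
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError("only axis-aligned (identity direction) volumes are supported")
    arr = sitk.GetArrayFromImage(img)
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.rint(arr)):
            bad = arr[arr != np.rint(arr)].flat[0]
            raise ValueError(f"non-integer voxel value {bad!r} in label volume")
        arr = np.rint(arr).astype(np.int64)
    labels = np.transpose(arr, (2, 1, 0)).astype(np.int64)
    return LabelVolume(
        labels=labels,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        legend=dict(legend) if legend is not None else dict(DEFAULT_LEGEND),
    )
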