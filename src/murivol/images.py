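"""Core image containers: scalar images, integer label maps, transforms.

All grids are 3-D, indexed ``[i, j, k]`` with 0-based voxel indices. World
coordinates are ``affine @ (i, j, k, 1)`` in mm (RAS on disk). Intensity
images and label maps that belong together share a grid and an affine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "LabeledImage",
    "LabelMap",
    "LabelInfo",
    "AffineTransform",
    "DeformationField",
]


def _spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass(frozen=True)
class LabeledImage:
    """A 3-D scalar image with voxel spacing and a grid-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.dtype != np.float32:  # float32 retained to bound large-grid memory
            data = data.astype(np.float64)
        if data.ndim != 3:
            raise ValueError(f"image must be 3-D, got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("image intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be 3 positive values, got {spacing}")
        affine = self.affine
        if affine is None:
            affine = _spacing_affine(spacing)
        affine = np.asarray(affine, dtype=np.float64)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "LabeledImage":
        return replace(self, data=data)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "LabeledImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj, dtype=np.float64),
                   tuple(float(z) for z in zooms), img.affine)


@dataclass(frozen=True)
class LabelInfo:
    """Dictionary entry for one structure label."""

    name: str
    tissue: str  # GM | WM | CSF
    hemisphere: str = "unsplit"  # L | R | midline | unsplit
    bilateral: bool = False

    def to_dict(self) -> dict:
        return {"name": self.name, "tissue": self.tissue,
                "hemisphere": self.hemisphere, "bilateral": self.bilateral}


@dataclass(frozen=True)
class LabelMap:
    """Integer label grid aligned to a :class:`LabeledImage`.

    ``labels[id]`` describes every nonzero id present in the grid; 0 is
    reserved for background.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    labels: Mapping[int, LabelInfo]
    affine: np.ndarray | None = None

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"label map must be 3-D, got ndim={data.ndim}")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("label map must hold integers")
            data = np.round(data).astype(np.int32)
        if data.min() < 0:
            raise ValueError("label ids must be non-negative")
        present = set(np.unique(data).tolist()) - {0}
        labels = dict(self.labels)
        missing = present - set(labels)
        if missing:
            raise ValueError(f"label ids present in grid but not in dictionary: {sorted(missing)}")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be positive")
        affine = self.affine
        if affine is None:
            affine = _spacing_affine(spacing)
        affine = np.asarray(affine, dtype=np.float64)
        object.__setattr__(self, "data", data.astype(np.int32))
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data, labels=None) -> "LabelMap":
        return LabelMap(data, self.spacing, self.labels if labels is None else labels,
                        self.affine)

    def save(self, path: str | Path) -> None:
        """Write the grid as NIfTI plus a JSON label-dictionary sidecar."""
        path = Path(path)
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))
        sidecar = path.with_suffix("").with_suffix(".labels.json")
        sidecar.write_text(json.dumps(
            {str(k): v.to_dict() for k, v in self.labels.items()}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LabelMap":
        path = Path(path)
        img = nib.load(str(path))
        sidecar = path.with_suffix("").with_suffix(".labels.json")
        raw = json.loads(sidecar.read_text())
        labels = {int(k): LabelInfo(**v) for k, v in raw.items()}
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj), tuple(float(z) for z in zooms),
                   labels, img.affine)


@dataclass(frozen=True)
class AffineTransform:
    """4x4 affine mapping moving-image world coordinates to fixed world coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError("affine transform must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last affine row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("affine transform is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out.reshape(np.shape(points))

    def save(self, path: str | Path) -> None:
        np.savetxt(str(path), self.matrix, fmt="%.17g")

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform":
        return cls(np.loadtxt(str(path)))


@dataclass(frozen=True)
class DeformationField:
    """Displacement field (mm) from a cubic-B-spline control grid composed
    with an affine.

    Maps fixed-image world points ``x`` to moving-image world points
    ``affine(x) + disp(x)`` (pull-back convention: resampling the moving image
    at the mapped points warps it onto the fixed grid). The displacement is
    stored on its own grid (``grid_affine``: index -> world), which may be
    coarser than the fixed image; it is interpolated where needed.
    """

    affine: AffineTransform
    displacement: np.ndarray  # (nx, ny, nz, 3) mm on the field's grid
    control_spacing: tuple[int, int, int] = (4, 4, 4)  # voxels
    control_grid: np.ndarray | None = field(default=None, repr=False)
    grid_affine: np.ndarray | None = None  # default: identity-spacing grid

    def __post_init__(self):
        disp = np.asarray(self.displacement, dtype=np.float64)
        if disp.ndim != 4 or disp.shape[-1] != 3:
            raise ValueError("displacement must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(disp)):
            raise ValueError("displacement must be finite")
        cs = tuple(int(c) for c in self.control_spacing)
        if any(c < 2 for c in cs):
            raise ValueError("control-grid spacing must be >= 2 voxels")
        ga = np.eye(4) if self.grid_affine is None else np.asarray(self.grid_affine,
                                                                   dtype=np.float64)
        object.__setattr__(self, "displacement", disp)
        object.__setattr__(self, "control_spacing", cs)
        object.__setattr__(self, "grid_affine", ga)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]

    def displacement_at(self, world: np.ndarray) -> np.ndarray:
        """Linearly interpolate the displacement (mm) at (n, 3) world points."""
        from scipy import ndimage  # local import keeps module load light
        inv = np.linalg.inv(self.grid_affine)
        idx = (world @ inv[:3, :3].T + inv[:3, 3]).T
        out = np.empty_like(world)
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(self.displacement[..., c], idx,
                                                order=1, mode="nearest")
        return out

    def save(self, path: str | Path) -> None:
        """Plain-text serialization: affine matrix + control-grid (or dense) array."""
        path = Path(path)
        self.affine.save(path.with_suffix(".affine.txt"))
        arr = self.control_grid if self.control_grid is not None else self.displacement
        with open(path.with_suffix(".disp.txt"), "w") as fh:
            fh.write("# shape " + " ".join(str(s) for s in arr.shape) + "\n")
            fh.write("# control_spacing " + " ".join(str(c) for c in self.control_spacing) + "\n")
            np.savetxt(fh, np.asarray(arr).reshape(-1, 3), fmt="%.10g")
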