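"""Voxel-grid data model and NIfTI I/O shared by all analysis stages.

All geometry in this package lives in a single RAS world frame (+x right,
+y anterior, +z superior), in millimetres.  A :class:`VoxelGrid` describes a
regular grid of voxel *centers*: voxel index ``(0, 0, 0)`` is centered at
``origin`` and indices are 0-based.  Every volume taking part in one analysis
shares an identical grid unless it is explicitly resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "IntensityVolume",
    "LabelVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "flip_lateral",
    "resample_mask_affine",
    "percentile",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a regular voxel grid in RAS world coordinates.

    Parameters
    ----------
    dims
        Number of voxels along (x, y, z).  Each entry must be >= 1.
    spacing
        Voxel edge lengths in mm, all > 0.
    origin
        World coordinate (mm) of the *center* of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def centered(
        cls,
        dims: tuple[int, int, int],
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> "VoxelGrid":
        """Grid whose voxel centers are symmetric about the world origin.

        With an even number of voxels no voxel center lies exactly on a
        coordinate plane, but mirroring indices about the grid midplane then
        corresponds exactly to negating the world coordinate — which is what
        lateral flipping about the midsagittal plane x = 0 requires.
        """
        origin = tuple(-(d - 1) / 2.0 * s for d, s in zip(dims, spacing))
        return cls(tuple(dims), tuple(spacing), origin)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, RAS)."""
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.spacing
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)


def _check_shape(grid: VoxelGrid, data: np.ndarray) -> None:
    if tuple(data.shape) != grid.dims:
        raise ValueError(f"data shape {data.shape} does not match grid dims {grid.dims}")


@dataclass
class IntensityVolume:
    """A scalar MR intensity volume (arbitrary units) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_shape(self.grid, self.values)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity volume contains non-finite values")


@dataclass
class LabelVolume:
    """Integer nucleus labels on a grid, with a code -> name dictionary."""

    grid: VoxelGrid
    labels: np.ndarray
    label_map: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(np.asarray(self.labels, dtype=float))
            if not np.allclose(self.labels, rounded, atol=1e-6):
                raise ValueError("label volume contains non-integer values")
            self.labels = rounded.astype(np.int32)
        _check_shape(self.grid, self.labels)
        if self.labels.min() < 0:
            raise ValueError("label codes must be nonnegative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_map)
        if self.label_map and missing:
            raise ValueError(f"label codes {sorted(missing)} missing from label_map")

    def mask_for(self, *names: str) -> "BinaryMask":
        """Binary mask of the union of the named nuclei (e.g. whole thalamus)."""
        codes = [c for c, n in self.label_map.items() if n in names]
        if not codes:
            raise KeyError(f"no label codes named {names!r}")
        return BinaryMask(self.grid, np.isin(self.labels, codes))


@dataclass
class BinaryMask:
    """Boolean voxel membership on a grid."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            vals = np.asarray(self.data, dtype=float)
            if not np.all(np.isclose(vals, 0.0, atol=1e-6) | np.isclose(vals, 1.0, atol=1e-6)):
                raise ValueError("mask data is not binary (values other than 0/1)")
            self.data = vals > 0.5
        _check_shape(self.grid, self.data)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.grid.voxel_volume_mm3

    def indices(self) -> np.ndarray:
        """Member voxel indices as an (n, 3) array in lexicographic order."""
        return np.argwhere(self.data)


Volume = IntensityVolume | LabelVolume | BinaryMask


def _grid_from_image(img: nib.Nifti1Image) -> VoxelGrid:
    img = nib.as_closest_canonical(img)  # reorient to RAS
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-4):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelGrid(tuple(img.shape[:3]), spacing, origin)


def read_volume(
    path: str | Path,
    kind: str = "intensity",
    label_map: Mapping[int, str] | None = None,
) -> Volume:
    """Read a NIfTI-1 volume as an intensity, label, or mask volume.

    ``kind='mask'`` requires the on-disk data to be binary (0/1 within 1e-6);
    ``kind='intensity'`` rejects NaN voxels; ``kind='label'`` rejects
    non-integer or negative codes.
    """
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    grid = _grid_from_image(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        data = np.squeeze(data)
    if kind == "intensity":
        if np.isnan(data).any():
            raise ValueError(f"{path}: intensity volume contains NaN voxels")
        return IntensityVolume(grid, data)
    if kind == "label":
        return LabelVolume(grid, data, label_map or {})
    if kind == "mask":
        return BinaryMask(grid, data)
    raise ValueError(f"unknown volume kind {kind!r}")


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal RAS affine."""
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    elif isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int16)
    else:
        data = vol.values.astype(np.float64)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))


def _flip_array(arr: np.ndarray) -> np.ndarray:
    return np.flip(arr, axis=0).copy()


def flip_lateral(vol: Volume) -> Volume:
    """Mirror a volume left-right: voxel (i, j, k) -> (dims_x-1-i, j, k).

    Used so that, as in the treatment convention, ablations of right-treated
    patients can be analysed on the left side of the common template space.
    The grid itself is unchanged.
    """
    if isinstance(vol, IntensityVolume):
        return IntensityVolume(vol.grid, _flip_array(vol.values))
    if isinstance(vol, LabelVolume):
        return LabelVolume(vol.grid, _flip_array(vol.labels), vol.label_map)
    if isinstance(vol, BinaryMask):
        return BinaryMask(vol.grid, _flip_array(vol.data))
    raise TypeError(f"cannot flip object of type {type(vol)!r}")


def resample_mask_affine(
    mask: BinaryMask, transform: np.ndarray, target: VoxelGrid
) -> BinaryMask:
    """Resample a mask through a world-to-world affine, nearest neighbor.

    ``transform`` maps source-world mm to target-world mm.  Each target voxel
    takes the membership of the source voxel whose center is nearest to the
    inverse-mapped target voxel center; a pure translation by an integer
    multiple of the spacing is therefore exact.  Masks stay hard labels — no
    partial-volume weighting.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise ValueError("transform must be a 4x4 affine")
    if abs(np.linalg.det(transform[:3, :3])) < 1e-12:
        raise ValueError("singular transform")
    inv = np.linalg.inv(transform)
    result = np.zeros(target.dims, dtype=bool)

    member = mask.indices()
    if len(member) == 0:
        return BinaryMask(target, result)

    # only target voxels inside the forward-mapped source bounding box can
    # be members; restrict the (expensive) inverse mapping to that box
    src_lo = member.min(axis=0)
    src_hi = member.max(axis=0)
    corners_idx = np.array(
        [
            (i, j, k)
            for i in (src_lo[0], src_hi[0])
            for j in (src_lo[1], src_hi[1])
            for k in (src_lo[2], src_hi[2])
        ]
    )
    corners_world = mask.grid.index_to_world(corners_idx)
    mapped = corners_world @ transform[:3, :3].T + transform[:3, 3]
    # half a source voxel can still round inward under NN; pad by that
    # half-voxel pushed through the transform plus one target voxel
    pad = float(
        np.max(np.abs(transform[:3, :3]) @ (np.asarray(mask.grid.spacing) / 2.0))
    ) + float(np.max(target.spacing))
    tgt_lo = np.maximum(
        np.floor(target.world_to_index(mapped.min(axis=0) - pad)).astype(int), 0
    )
    tgt_hi = np.minimum(
        np.ceil(target.world_to_index(mapped.max(axis=0) + pad)).astype(int) + 1,
        np.asarray(target.dims),
    )
    if np.any(tgt_lo >= tgt_hi):
        return BinaryMask(target, result)

    ranges = [np.arange(tgt_lo[a], tgt_hi[a]) for a in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    tgt_idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    tgt_world = target.index_to_world(tgt_idx)
    src_world = tgt_world @ inv[:3, :3].T + inv[:3, 3]
    src_idx = np.rint(mask.grid.world_to_index(src_world)).astype(np.int64)

    dims = np.asarray(mask.grid.dims)
    inside = np.all((src_idx >= 0) & (src_idx < dims), axis=1)
    vals = np.zeros(len(tgt_idx), dtype=bool)
    si = src_idx[inside]
    vals[inside] = mask.data[si[:, 0], si[:, 1], si[:, 2]]
    result[tgt_idx[:, 0], tgt_idx[:, 1], tgt_idx[:, 2]] = vals
    return BinaryMask(target, result)


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile (q in [0, 100]) of a nonempty list.

    q = 50 is the median, q = 100 the maximum; interpolation is linear
    between closest ranks (the common scientific default).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("percentile of an empty list")
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"q must be in [0, 100], got {q}")
    return float(np.percentile(values, q, method="linear"))
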