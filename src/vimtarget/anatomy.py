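"""Stereotactic anatomy operations.

The Vim (ventral intermediate nucleus) cannot be separated from the dorsal
part of VLp by a visible boundary, so it is defined operationally as the
ventral half of the segmented VLp.  The standard stereotactic initial target
is placed from the AC-PC landmark frame: a fixed lateral offset from the
third-ventricle wall, a fixed fraction of the AC-PC length anterior to PC,
on the AC-PC plane.  This module also builds equal-volume sphere targets,
landmark-distance reports, and majority-vote fusion of nucleus labelings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .grids import BinaryMask, LabelVolume, VoxelGrid

__all__ = [
    "StereotacticLandmarks",
    "StereotacticRule",
    "split_vlp",
    "standard_target",
    "LandmarkDistances",
    "target_landmark_distances",
    "sphere_target",
    "majority_vote",
]


@dataclass(frozen=True)
class StereotacticLandmarks:
    """AC-PC frame landmarks for one patient (world mm, RAS).

    ``third_ventricle_wall_x`` is the signed x of the third-ventricle wall on
    the treated side; ``acpc_plane_z`` the z of the AC-PC plane.
    """

    AC: tuple[float, float, float]
    PC: tuple[float, float, float]
    third_ventricle_wall_x: float
    treated_side: str
    midline_x: float = 0.0
    acpc_plane_z: float = 0.0

    def __post_init__(self) -> None:
        if self.treated_side not in ("left", "right"):
            raise ValueError(f"treated_side must be left/right, got {self.treated_side!r}")
        if not self.AC[1] > self.PC[1]:
            raise ValueError("AC must be anterior to PC (AC_y > PC_y)")

    def mirrored(self) -> "StereotacticLandmarks":
        """Landmarks after a left-right flip about the midline."""
        mx = self.midline_x

        def refl(p):
            return (2 * mx - p[0], p[1], p[2])

        return StereotacticLandmarks(
            AC=refl(self.AC),
            PC=refl(self.PC),
            third_ventricle_wall_x=2 * mx - self.third_ventricle_wall_x,
            treated_side="left" if self.treated_side == "right" else "right",
            midline_x=mx,
            acpc_plane_z=self.acpc_plane_z,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "AC": list(self.AC),
            "PC": list(self.PC),
            "wall_x": self.third_ventricle_wall_x,
            "midline_x": self.midline_x,
            "acpc_z": self.acpc_plane_z,
            "side": self.treated_side,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StereotacticLandmarks":
        d = json.loads(Path(path).read_text())
        return cls(
            AC=tuple(d["AC"]),
            PC=tuple(d["PC"]),
            third_ventricle_wall_x=float(d["wall_x"]),
            treated_side=d["side"],
            midline_x=float(d.get("midline_x", 0.0)),
            acpc_plane_z=float(d.get("acpc_z", 0.0)),
        )


@dataclass(frozen=True)
class StereotacticRule:
    """Standard initial-target rule: 11 mm lateral to the third-ventricle
    wall, 0.25 x AC-PC length anterior to PC, on the AC-PC plane."""

    lateral_offset: float = 11.0
    acpc_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.lateral_offset <= 0:
            raise ValueError("lateral_offset must be > 0")
        if not 0.0 < self.acpc_fraction < 1.0:
            raise ValueError("acpc_fraction must lie in (0, 1)")


def split_vlp(vlp: BinaryMask) -> tuple[BinaryMask, BinaryMask]:
    """Split VLp into (dorsal, vim) halves by a transaxial midplane.

    The cutting plane lies midway (in mm) between the two transaxial planes
    bounding VLp.  Voxels whose center z is below the midplane form the Vim
    (ventral half); voxels exactly on the midplane are assigned ventral, so
    the two halves always partition VLp.
    """
    idx = vlp.indices()
    if len(idx) == 0:
        raise ValueError("empty VLp mask")
    z_centers = vlp.grid.index_to_world(idx)[:, 2]
    z_min, z_max = z_centers.min(), z_centers.max()
    if np.isclose(z_min, z_max):
        raise ValueError("VLp spans a single transaxial slice; cannot split")
    z_star = (z_min + z_max) / 2.0

    kk = np.arange(vlp.grid.dims[2])
    slice_z = vlp.grid.origin[2] + kk * vlp.grid.spacing[2]
    ventral_slices = slice_z <= z_star + 1e-9

    vim_data = vlp.data & ventral_slices[None, None, :]
    dorsal_data = vlp.data & ~ventral_slices[None, None, :]
    return BinaryMask(vlp.grid, dorsal_data), BinaryMask(vlp.grid, vim_data)


def standard_target(
    landmarks: StereotacticLandmarks, rule: StereotacticRule = StereotacticRule()
) -> np.ndarray:
    """Standard stereotactic initial target point (world mm).

    Lateral means away from the midline into the treated hemisphere: the
    offset is subtracted from the wall x for a left-treated patient (RAS,
    −x = left) and added for a right-treated one.
    """
    sign = -1.0 if landmarks.treated_side == "left" else 1.0
    x = landmarks.third_ventricle_wall_x + sign * rule.lateral_offset
    y = landmarks.PC[1] + rule.acpc_fraction * (landmarks.AC[1] - landmarks.PC[1])
    z = landmarks.acpc_plane_z
    return np.array([x, y, z], dtype=float)


@dataclass(frozen=True)
class LandmarkDistances:
    """Distances from a target point to the stereotactic landmarks.

    ``acpc_percent`` is the signed position along PC->AC as a percentage of
    the AC-PC length; ``acpc_plane_dist_z`` is signed (negative = below the
    AC-PC plane).
    """

    midline_dist: float
    pc_dist_y: float
    acpc_percent: float
    acpc_plane_dist_z: float

    def as_dict(self) -> dict:
        return asdict(self)


def target_landmark_distances(
    p: Sequence[float], landmarks: StereotacticLandmarks
) -> LandmarkDistances:
    """Report a target's distances to midline, PC, %AC-PC, and AC-PC plane."""
    p = np.asarray(p, dtype=float)
    acpc_len = landmarks.AC[1] - landmarks.PC[1]
    if np.isclose(acpc_len, 0.0):
        raise ValueError("degenerate landmarks: AC_y equals PC_y")
    return LandmarkDistances(
        midline_dist=float(abs(p[0] - landmarks.midline_x)),
        pc_dist_y=float(abs(p[1] - landmarks.PC[1])),
        acpc_percent=float(100.0 * (p[1] - landmarks.PC[1]) / acpc_len),
        acpc_plane_dist_z=float(p[2] - landmarks.acpc_plane_z),
    )


def sphere_target(
    center: Sequence[float], volume_mm3: float, grid: VoxelGrid
) -> BinaryMask:
    """Rasterize a sphere of *exactly* the requested volume around a point.

    Voxels are ranked by (distance of voxel center to ``center``, then
    lexicographic index) and the first round(volume / voxel volume) are
    taken.  This guarantees an exact volume match — a plain radius cutoff
    cannot — and is deterministic regardless of enumeration order.
    """
    center = np.asarray(center, dtype=float)
    vox = grid.voxel_volume_mm3
    n = int(round(volume_mm3 / vox))
    if n < 1:
        raise ValueError(f"requested volume {volume_mm3} mm3 is below one voxel")
    if n > int(np.prod(grid.dims)):
        raise ValueError("requested volume exceeds the grid")

    # candidate bounding box around the equivalent-volume radius; grown if
    # the ranking ever reaches the box edge (degenerate thin grids)
    r = (3.0 * n * vox / (4.0 * math.pi)) ** (1.0 / 3.0)
    spacing = np.asarray(grid.spacing)
    dims = np.asarray(grid.dims)
    c_idx = grid.world_to_index(center)
    half = np.ceil(r / spacing).astype(int) + 2
    while True:
        lo = np.maximum(np.floor(c_idx).astype(int) - half, 0)
        hi = np.minimum(np.floor(c_idx).astype(int) + half + 1, dims)
        ranges = [np.arange(lo[a], hi[a]) for a in range(3)]
        ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
        cand = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        full_grid = bool(np.all(lo == 0) and np.all(hi == dims))
        if len(cand) >= n:
            world = grid.index_to_world(cand)
            d = np.linalg.norm(world - center, axis=1)
            order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], d))
            chosen = cand[order[:n]]
            # safe if no voxel outside the box could rank among the first n:
            # every outside voxel is at least the box inradius away
            box_inradius = float(
                np.min(
                    np.minimum(c_idx - lo + 0.5, hi - 0.5 - c_idx).clip(min=0) * spacing
                )
            )
            if full_grid or d[order[n - 1]] < box_inradius:
                break
        elif full_grid:
            raise ValueError("requested volume exceeds the grid")
        half = half + 2

    data = np.zeros(grid.dims, dtype=bool)
    data[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    return BinaryMask(grid, data)


def majority_vote(labelings: Sequence[LabelVolume]) -> LabelVolume:
    """Voxelwise plurality fusion of several nucleus labelings.

    Ties (including a tie with background) are assigned background (0):
    anatomy is never invented where raters disagree evenly.
    """
    if len(labelings) == 0:
        raise ValueError("majority_vote of an empty list")
    grid = labelings[0].grid
    if any(lv.grid != grid for lv in labelings):
        raise ValueError("labelings are on different grids")

    stack = np.stack([lv.labels for lv in labelings])
    codes = np.unique(stack)
    best_count = np.zeros(grid.dims, dtype=np.int32)
    best_label = np.zeros(grid.dims, dtype=np.int32)
    tied = np.zeros(grid.dims, dtype=bool)
    for code in codes:
        count = (stack == code).sum(axis=0).astype(np.int32)
        wins = count > best_count
        tied = np.where(wins, False, tied | (count == best_count))
        best_label = np.where(wins, np.int32(code), best_label)
        best_count = np.maximum(best_count, count)
    fused = np.where(tied, np.int32(0), best_label)

    merged_map: dict[int, str] = {}
    for lv in labelings:
        merged_map.update(lv.label_map)
    present = set(np.unique(fused).tolist()) - {0}
    return LabelVolume(grid, fused, {c: n for c, n in merged_map.items() if c in present} or {})
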