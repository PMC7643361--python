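"""Probabilistic target construction from cohort ablation masks.

The efficacious-target hypothesis: since every treated patient improved at
least somewhat, the thalamic region ablated in *all* patients is a good
candidate for the optimal target.  The construction intersects every
patient's whole-ablation mask in the common template space and erodes the
intersection with a full 3x3x3 cube kernel down to a stopping volume of
20 mm^3 — the cohort-average ablation-core volume — yielding a compact,
roughly spherical target that can be warped back into any patient's space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, VoxelGrid, resample_mask_affine

__all__ = [
    "TargetParams",
    "TargetRegion",
    "cohort_intersection",
    "erode_to_volume",
    "build_probabilistic_target",
    "warp_target_to_patient",
    "CUBE_KERNEL",
]

# full 3x3x3 cube (26-connectivity) — deliberately distinct from the
# connectivity-1 cross used for core closing
CUBE_KERNEL = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class TargetParams:
    """Stopping volume (mm^3) for the cube-kernel erosion."""

    stop_volume_mm3: float = 20.0

    def __post_init__(self) -> None:
        if self.stop_volume_mm3 <= 0:
            raise ValueError("stop_volume_mm3 must be > 0")


@dataclass
class TargetRegion:
    """A constructed target mask with its construction provenance."""

    mask: BinaryMask
    count_map: np.ndarray
    erosion_iterations: int
    final_volume_mm3: float
    n_patients: int


def cohort_intersection(
    masks: Sequence[BinaryMask],
) -> tuple[BinaryMask, np.ndarray]:
    """Intersection of all masks plus the per-voxel coverage count map."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to intersect")
    grid = masks[0].grid
    if any(m.grid != grid for m in masks):
        raise ValueError("masks are on different grids")
    count_map = np.zeros(grid.dims, dtype=np.int32)
    for m in masks:
        count_map += m.data
    intersection = BinaryMask(grid, count_map == len(masks))
    return intersection, count_map


def _boundary(data: np.ndarray) -> np.ndarray:
    # 26-connectivity boundary: member voxels with any neighbor outside
    return data & ~ndimage.binary_erosion(data, structure=CUBE_KERNEL)


def erode_to_volume(
    mask: BinaryMask, params: TargetParams = TargetParams()
) -> tuple[BinaryMask, int]:
    """Erode a mask with the 3x3x3 cube down to the stopping volume.

    Full erosion steps are applied while the result stays at or above the
    stopping volume.  Erosion is quantized, so the step that would
    undershoot is replaced by a deterministic peel: boundary voxels are
    removed one at a time, farthest from the current centroid first
    (lexicographic index breaking ties), until the voxel count equals
    round(stop_volume / voxel volume) exactly.  The result keeps the
    roughly spherical character intended by the construction while making
    "eroded down to 20 mm^3" an exact, reproducible statement.
    """
    grid = mask.grid
    stop_count = int(round(params.stop_volume_mm3 / grid.voxel_volume_mm3))
    if mask.count < stop_count:
        raise ValueError(
            f"mask volume {mask.volume_mm3:.1f} mm3 is below the stopping "
            f"volume {params.stop_volume_mm3:.1f} mm3"
        )
    current = mask.data.copy()
    iterations = 0
    while True:
        nxt = ndimage.binary_erosion(current, structure=CUBE_KERNEL)
        if int(nxt.sum()) >= stop_count:
            current = nxt
            iterations += 1
        else:
            break

    while int(current.sum()) > stop_count:
        idx = np.argwhere(_boundary(current))
        if len(idx) == 0:  # no interior left: every voxel is boundary
            idx = np.argwhere(current)
        world = grid.index_to_world(idx)
        centroid = grid.index_to_world(np.argwhere(current)).mean(axis=0)
        d = np.linalg.norm(world - centroid, axis=1)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -d))
        i, j, k = idx[order[0]]
        current[i, j, k] = False

    return BinaryMask(grid, current), iterations


def build_probabilistic_target(
    whole_ablation_masks: Sequence[BinaryMask],
    params: TargetParams = TargetParams(),
    min_fraction: float = 1.0,
) -> TargetRegion:
    """Build the probabilistic target from cohort whole-ablation masks.

    All masks must already live on the common template grid, with
    right-treated patients' masks flipped to the left.  ``min_fraction``
    generalizes the 100 %-overlap requirement (default keeps it: the region
    must be covered by *every* patient); lowering it is an extension for
    cohorts whose full intersection is empty.
    """
    intersection, count_map = cohort_intersection(whole_ablation_masks)
    n = len(whole_ablation_masks)
    if min_fraction < 1.0:
        need = int(np.ceil(min_fraction * n))
        intersection = BinaryMask(intersection.grid, count_map >= need)
    if intersection.count == 0:
        raise ValueError("cohort ablation masks have an empty intersection")
    if intersection.volume_mm3 < params.stop_volume_mm3:
        raise ValueError(
            f"cohort intersection ({intersection.volume_mm3:.1f} mm3) is below "
            f"the stopping volume {params.stop_volume_mm3:.1f} mm3"
        )
    mask, iterations = erode_to_volume(intersection, params)
    return TargetRegion(
        mask=mask,
        count_map=count_map,
        erosion_iterations=iterations,
        final_volume_mm3=mask.volume_mm3,
        n_patients=n,
    )


def warp_target_to_patient(
    target: TargetRegion, to_template: np.ndarray, patient_grid: VoxelGrid
) -> BinaryMask:
    """Transfer the template-space target into a patient's space.

    ``to_template`` maps patient world mm to template world mm; its inverse
    is applied with nearest-neighbor resampling.
    """
    to_template = np.asarray(to_template, dtype=float)
    if abs(np.linalg.det(to_template[:3, :3])) < 1e-12:
        raise ValueError("singular transform")
    return resample_mask_affine(target.mask, np.linalg.inv(to_template), patient_grid)
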