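"""Semi-automatic ablation-core segmentation from post-treatment imaging.

The penumbra's outer boundary (the whole ablation) is an input — in the
clinical workflow it is traced manually.  The core is then recovered
automatically: intensities inside the whole ablation are re-scaled against
the normal-appearing thalamus (0 at its median, 1 at its 99th percentile),
voxels above a fixed scaled threshold (default 1.25) form the core, and a
binary closing with a connectivity-1 kernel (the 3D cross) fills the small
central hypointensity seen in many cores.

Two re-scaling modes exist because "0 at the median and 1 at the 99th
percentile" pins down ``(x − median)/(p99 − median)`` (``anchored``, the
default), while the alternative ``literal`` mode divides by the p99 value
itself, ``(x − median)/p99``.  Anchored mode is invariant to affine
intensity changes of the scanner; literal mode is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, IntensityVolume, percentile

__all__ = [
    "AblationSegParams",
    "AblationSegmentation",
    "normal_thalamus_stats",
    "rescale_ablation_intensity",
    "segment_core",
    "CROSS_KERNEL",
]

# connectivity-1 structuring element: 7-voxel 3D cross ("jack")
CROSS_KERNEL = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class AblationSegParams:
    """Parameters of the core segmentation.

    core_threshold
        Scaled-intensity cutoff; voxels strictly above it are core.
    rescale_mode
        ``anchored`` -> (x − median)/(p99 − median); ``literal`` ->
        (x − median)/p99.
    p_high
        Upper reference percentile; 99 rather than the maximum so a few
        stray ventricle voxels in the thalamus mask cannot poison the scale.
    """

    core_threshold: float = 1.25
    rescale_mode: str = "anchored"
    p_high: float = 99.0

    def __post_init__(self) -> None:
        if self.core_threshold <= 0:
            raise ValueError("core_threshold must be > 0")
        if not 50.0 < self.p_high <= 100.0:
            raise ValueError("p_high must lie in (50, 100]")
        if self.rescale_mode not in ("anchored", "literal"):
            raise ValueError(f"unknown rescale_mode {self.rescale_mode!r}")


@dataclass
class AblationSegmentation:
    """Whole-ablation mask, derived core mask, and the statistics used."""

    whole: BinaryMask
    core: BinaryMask
    thalamus_median: float
    thalamus_p99: float


def normal_thalamus_stats(
    post: IntensityVolume,
    thalamus: BinaryMask,
    whole_ablation: BinaryMask,
    p_high: float = 99.0,
) -> tuple[float, float]:
    """Median and high-percentile intensity of the normal-appearing thalamus.

    Computed over thalamus voxels *excluding* the whole-ablation region, so
    the lesion hyperintensity cannot inflate the reference statistics.
    """
    if post.grid != thalamus.grid or post.grid != whole_ablation.grid:
        raise ValueError("volumes are on different grids")
    normal = thalamus.data & ~whole_ablation.data
    if not normal.any():
        raise ValueError("normal-appearing thalamus is empty")
    vals = post.values[normal]
    return percentile(vals, 50.0), percentile(vals, p_high)


def rescale_ablation_intensity(
    x, median: float, p99: float, mode: str = "anchored"
):
    """Re-scale intensity x against normal-thalamus statistics.

    anchored: (x − median)/(p99 − median)  — 0 at the median, 1 at the p99.
    literal:  (x − median)/p99.
    """
    x = np.asarray(x, dtype=float)
    if mode == "anchored":
        denom = p99 - median
        if denom <= 0:
            raise ValueError("degenerate statistics: p99 <= median")
    elif mode == "literal":
        denom = p99
        if denom == 0:
            raise ValueError("degenerate statistics: p99 == 0")
    else:
        raise ValueError(f"unknown rescale mode {mode!r}")
    out = (x - median) / denom
    return float(out) if out.ndim == 0 else out


def segment_core(
    post: IntensityVolume,
    whole: BinaryMask,
    thalamus: BinaryMask,
    params: AblationSegParams = AblationSegParams(),
) -> AblationSegmentation:
    """Segment the ablation core inside the traced whole-ablation boundary.

    Steps: re-scale intensities within ``whole`` against the
    normal-appearing thalamus, threshold at ``params.core_threshold``
    (strict >), close with the connectivity-1 cross kernel to fill the
    central hypointensity, and clip back to ``whole`` so the core can never
    escape the traced penumbra boundary.
    """
    if whole.count == 0:
        raise ValueError("whole-ablation mask is empty")
    med, p99 = normal_thalamus_stats(post, thalamus, whole, params.p_high)
    scaled = rescale_ablation_intensity(post.values, med, p99, params.rescale_mode)
    raw_core = (scaled > params.core_threshold) & whole.data
    closed = ndimage.binary_closing(raw_core, structure=CROSS_KERNEL)
    core = BinaryMask(whole.grid, (closed | raw_core) & whole.data)
    return AblationSegmentation(whole=whole, core=core, thalamus_median=med, thalamus_p99=p99)
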