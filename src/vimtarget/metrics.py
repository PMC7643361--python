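"""Scalar segmentation and targeting metrics.

Volumes, Dice and volume-similarity overlap scores, coverage fractions and
center-of-mass distances — the per-patient quantities that are later
correlated with clinical outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import BinaryMask

__all__ = [
    "volume_mm3",
    "dice",
    "vsi",
    "overlap_fraction",
    "center_of_mass",
    "com_distance",
    "MetricsRow",
    "metrics_table",
    "METRIC_COLUMNS",
]


def volume_mm3(mask: BinaryMask) -> float:
    """Mask volume in mm³ (member-voxel count times voxel volume)."""
    return mask.volume_mm3


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.grid != b.grid:
        raise ValueError("masks are on different grids")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A| + |B|)."""
    _check_same_grid(a, b)
    na, nb = a.count, b.count
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def vsi(a: BinaryMask, b: BinaryMask) -> float:
    """Volume similarity index 1 − ||A| − |B|| / (|A| + |B|).

    Agreement of segmentation volumes regardless of position; equals 1 iff
    the two masks have equal volume.  Always >= Dice.
    """
    _check_same_grid(a, b)
    na, nb = a.count, b.count
    if na + nb == 0:
        raise ValueError("VSI undefined for two empty masks")
    return 1.0 - abs(na - nb) / (na + nb)


def overlap_fraction(core: BinaryMask, target: BinaryMask) -> float:
    """Fraction of ``target`` covered by ``core``: |core ∩ target| / |target|."""
    _check_same_grid(core, target)
    nt = target.count
    if nt == 0:
        raise ValueError("overlap fraction undefined for an empty target")
    return int((core.data & target.data).sum()) / nt


def center_of_mass(mask: BinaryMask) -> np.ndarray:
    """Unweighted mean of member-voxel centers, in world mm."""
    idx = mask.indices()
    if len(idx) == 0:
        raise ValueError("center of mass of an empty mask")
    return mask.grid.index_to_world(idx).mean(axis=0)


def com_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Euclidean distance (mm) between two masks' centers of mass."""
    return float(np.linalg.norm(center_of_mass(a) - center_of_mass(b)))


METRIC_COLUMNS = [
    "core_volume_mm3",
    "whole_volume_mm3",
    "frac_vim_covered_by_core",
    "frac_vim_covered_by_whole",
    "com_dist_core_vim_mm",
    "com_dist_core_standard_target_mm",
    "frac_prob_target_covered_by_core",
    "frac_standard_sphere_covered_by_core",
]


@dataclass
class MetricsRow:
    """Per-patient scalar metrics joined to the patient's outcome scores."""

    patient_id: str
    core_volume_mm3: float
    whole_volume_mm3: float
    frac_vim_covered_by_core: float
    frac_vim_covered_by_whole: float
    com_dist_core_vim_mm: float
    com_dist_core_standard_target_mm: float
    frac_prob_target_covered_by_core: float
    frac_standard_sphere_covered_by_core: float
    crst_baseline: int
    crst_1month: int


def metrics_table(
    patient_ids,
    cores,
    wholes,
    vims,
    standard_targets,
    prob_targets,
    standard_spheres,
    baselines,
    one_months,
) -> pd.DataFrame:
    """Assemble the per-patient metrics table.

    All sequence arguments are aligned per patient; ``cores``/``wholes``/
    ``vims``/``prob_targets``/``standard_spheres`` are :class:`BinaryMask`
    in the same (patient) space, ``standard_targets`` are mm points.
    Returns a DataFrame with one row per patient (TSV-ready).
    """
    seqs = [cores, wholes, vims, standard_targets, prob_targets, standard_spheres,
            baselines, one_months]
    if any(len(s) != len(patient_ids) for s in seqs):
        raise ValueError("per-patient inputs have mismatched lengths")
    rows = []
    for pid, core, whole, vim, tgt_pt, prob, sphere, base, month in zip(
        patient_ids, cores, wholes, vims, standard_targets, prob_targets,
        standard_spheres, baselines, one_months,
    ):
        com_core = center_of_mass(core)
        rows.append(
            MetricsRow(
                patient_id=str(pid),
                core_volume_mm3=volume_mm3(core),
                whole_volume_mm3=volume_mm3(whole),
                frac_vim_covered_by_core=overlap_fraction(core, vim),
                frac_vim_covered_by_whole=overlap_fraction(whole, vim),
                com_dist_core_vim_mm=com_distance(core, vim),
                com_dist_core_standard_target_mm=float(
                    np.linalg.norm(com_core - np.asarray(tgt_pt, dtype=float))
                ),
                frac_prob_target_covered_by_core=overlap_fraction(core, prob),
                frac_standard_sphere_covered_by_core=overlap_fraction(core, sphere),
                crst_baseline=int(base),
                crst_1month=int(month),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
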