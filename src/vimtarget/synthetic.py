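"""Synthetic thalamic phantom cohorts with planted FUS ablations.

Every downstream stage of the analysis (core segmentation, Vim splitting,
probabilistic-target construction, outcome correlation) is exercised on
phantoms generated here, so the whole pipeline is testable without any
patient imaging.  A phantom emulates the features the analysis actually
consumes from white-matter-nulled MPRAGE imaging:

* dark white matter and a brighter thalamus composed of ellipsoidal nuclei
  (including VLp, whose ventral half defines the Vim), mirrored into both
  hemispheres;
* a planted ablation with the three observed zones — a diffusely
  hyperintense penumbra, a strongly hyperintense core, and a small central
  hypointensity inside the core;
* AC/PC stereotactic landmarks on the midline;
* integer CRST A+B outcome scores (0-32) whose improvement rises linearly
  with the overlap between the patient's true ablation core and a hidden
  efficacious region, plus Gaussian noise.

Ablation centers scatter around the hidden efficacious center with a
per-axis Gaussian jitter, emulating targeting variability across patients;
a few patients are right-treated and their anatomy is mirrored.  All
generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .anatomy import StereotacticLandmarks, sphere_target
from .grids import (
    BinaryMask,
    IntensityVolume,
    LabelVolume,
    VoxelGrid,
    percentile,
    write_volume,
)

__all__ = [
    "PhantomSpec",
    "AblationSpec",
    "OutcomeModel",
    "CohortRecord",
    "generate_phantom",
    "plant_ablation",
    "generate_outcomes",
    "generate_cohort",
    "draw_ablation_centers",
    "true_overlap_fractions",
    "write_cohort",
    "load_cohort",
    "NUCLEUS_CODES",
]

# label codes; VLp is rasterized last so its voxelization is exactly the
# analytic ellipsoid even where neighboring ellipsoids would overlap it
NUCLEUS_CODES: dict[str, int] = {
    "VA": 1, "VLa": 2, "VPL": 3, "MD": 4, "CM": 5, "Pul": 6, "VLp": 7,
}
_RASTER_ORDER = ["VA", "VLa", "VPL", "MD", "CM", "Pul", "VLp"]

# left-hemisphere nucleus ellipsoids: name -> (center mm, semi-axes mm)
_DEFAULT_NUCLEI: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "VA": ((-11.0, 0.0, 2.0), (2.5, 2.0, 3.0)),
    "VLa": ((-12.0, -3.5, 2.0), (2.5, 1.5, 3.0)),
    "VLp": ((-13.5, -7.0, 1.5), (4.5, 4.0, 5.0)),
    "VPL": ((-15.5, -11.5, 0.0), (2.5, 2.0, 3.0)),
    "MD": ((-6.0, -8.0, 2.0), (3.0, 4.0, 3.5)),
    "CM": ((-8.5, -12.0, -0.5), (2.0, 2.0, 2.0)),
    "Pul": ((-10.0, -17.0, 1.0), (4.0, 3.5, 4.0)),
}

# WMn-like contrast offsets (arbitrary MR units) around the thalamic mean
_DEFAULT_OFFSETS: dict[str, float] = {
    "VA": -80.0, "VLa": -60.0, "VLp": 0.0, "VPL": -40.0,
    "MD": 120.0, "CM": -30.0, "Pul": 60.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one thalamic phantom.

    The grid is centered on the world origin so lateral flips mirror
    exactly about the midsagittal plane x = 0.  The hidden efficacious
    center sits in the ventral half of the left VLp (the Vim), close to the
    stereotactic standard target; its small volume makes the core-overlap
    fraction vary steeply with targeting error, which is what gives the
    outcome model a detectable effect at realistic noise levels.
    """

    dims: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nuclei: Mapping[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=lambda: dict(_DEFAULT_NUCLEI)
    )
    nucleus_offsets: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_OFFSETS))
    wm_mean: float = 400.0
    wm_sd: float = 30.0
    thalamus_mean: float = 1000.0
    thalamus_sd: float = 30.0
    ac: tuple[float, float, float] = (0.0, 12.0, 0.0)
    pc: tuple[float, float, float] = (0.0, -12.0, 0.0)
    third_ventricle_wall_x: float = -2.5  # left-hemisphere wall; mirrored for right
    acpc_plane_z: float = 0.0
    efficacious_center: tuple[float, float, float] = (-14.5, -7.5, -1.0)
    efficacious_volume_mm3: float = 4.0

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid.centered(self.dims, self.spacing)

    def __post_init__(self) -> None:
        grid = self.grid
        half_extent = [
            (d - 1) / 2.0 * s for d, s in zip(self.dims, self.spacing)
        ]
        for name, (center, axes) in self.nuclei.items():
            for a in range(3):
                if abs(center[a]) + axes[a] > half_extent[a]:
                    raise ValueError(f"nucleus {name} ellipsoid exceeds the grid")
        vlp = self.nuclei.get("VLp")
        if vlp is None:
            raise ValueError("spec must define a VLp nucleus")
        if 2 * vlp[1][2] < 4 * self.spacing[2]:
            raise ValueError("VLp must span at least 4 transaxial slices")

    def shifted(self, t: Sequence[float]) -> "PhantomSpec":
        """Spec with all anatomy translated by ``t`` mm (patient spaces)."""
        t = np.asarray(t, dtype=float)
        nuc = {
            n: (tuple(np.asarray(c) + t), a) for n, (c, a) in self.nuclei.items()
        }
        return replace(
            self,
            nuclei=nuc,
            ac=tuple(np.asarray(self.ac) + t),
            pc=tuple(np.asarray(self.pc) + t),
            third_ventricle_wall_x=self.third_ventricle_wall_x + t[0],
            acpc_plane_z=self.acpc_plane_z + t[2],
            efficacious_center=tuple(np.asarray(self.efficacious_center) + t),
        )

    def mirrored(self) -> "PhantomSpec":
        """Spec mirrored about the midsagittal plane x = 0."""

        def m(p):
            return (-p[0], p[1], p[2])

        nuc = {n: (m(c), a) for n, (c, a) in self.nuclei.items()}
        return replace(
            self,
            nuclei=nuc,
            ac=m(self.ac),
            pc=m(self.pc),
            third_ventricle_wall_x=-self.third_ventricle_wall_x,
            efficacious_center=m(self.efficacious_center),
        )

    def point_in_thalamus(self, p: Sequence[float]) -> bool:
        """Analytic test: does p lie inside any nucleus ellipsoid (either
        hemisphere)?"""
        p = np.asarray(p, dtype=float)
        for center, axes in self.nuclei.values():
            for c in (np.asarray(center), np.asarray(center) * (-1, 1, 1)):
                if np.sum(((p - c) / np.asarray(axes)) ** 2) <= 1.0:
                    return True
        return False


@dataclass(frozen=True)
class AblationSpec:
    """Geometry and contrast of one planted ablation.

    Radii in mm; zone intensities in scaled units of the normal-thalamus
    distribution (0 at its median, 1 at its 99th percentile).  Each zone's
    tissue is *set* to its level plus a mild texture — ablated tissue loses
    the underlying nucleus contrast and looks smoother than normal thalamus
    — so the core (level 1.5) always clears the 1.25 segmentation threshold
    while the penumbra (0.6) never does.  A zone with level exactly 0 is
    left untouched, so a zero-contrast ablation leaves the image unchanged.
    ``min_core_scaled`` additionally floors non-hypointense core voxels,
    making core recoverability hold by construction even under extreme
    texture draws.
    """

    center: tuple[float, float, float]
    penumbra_radius: float = 6.0
    core_radius: float = 1.7
    hypointense_radius: float = 0.6
    penumbra_boost: float = 0.6
    core_boost: float = 1.5
    hypointense_offset: float = -1.0
    texture_sd: float = 0.05
    min_core_scaled: float = 1.3

    def __post_init__(self) -> None:
        if not (self.hypointense_radius <= self.core_radius <= self.penumbra_radius):
            raise ValueError("need hypointense ⊆ core ⊆ penumbra radii")


@dataclass(frozen=True)
class OutcomeModel:
    """Linear-in-overlap CRST A+B outcome model with integer clipping.

    one_month = clip(round(baseline − α − β·overlap − ε), 0, 32) with
    ε ~ N(0, σ²); baseline ~ clip(round(N(baseline_mean, baseline_sd))).
    Defaults are calibrated to the treated cohort's printed moments
    (baseline 20 ± 3.78; ≈12-point mean improvement).
    """

    baseline_mean: float = 20.0
    baseline_sd: float = 3.78
    improvement_intercept: float = 8.0
    improvement_slope: float = 10.0
    noise_sd: float = 2.0
    score_min: int = 0
    score_max: int = 32

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class CohortRecord:
    """One synthetic patient: volumes, masks, landmarks, transform, scores.

    ``true_core``, ``true_overlap`` and ``ablation_center_template`` are
    generator ground truth, available for testing only — the analysis
    pipeline never reads them.
    """

    patient_id: str
    treated_side: str
    pre_volume: IntensityVolume
    post_volume: IntensityVolume
    nuclei: LabelVolume
    whole_ablation: BinaryMask
    landmarks: StereotacticLandmarks
    to_template: np.ndarray
    crst_baseline: int
    crst_1month: int
    true_core: BinaryMask
    true_overlap: float
    ablation_center_template: tuple[float, float, float]


def _rasterize_ellipsoid(
    grid: VoxelGrid, center: np.ndarray, axes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices (n, 3) whose centers lie inside the ellipsoid."""
    lo = np.maximum(np.floor(grid.world_to_index(center - axes)).astype(int), 0)
    hi = np.minimum(
        np.ceil(grid.world_to_index(center + axes)).astype(int) + 1,
        np.asarray(grid.dims),
    )
    ranges = [np.arange(lo[a], hi[a]) for a in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = grid.index_to_world(idx)
    inside = np.sum(((world - center) / axes) ** 2, axis=1) <= 1.0
    return idx[inside], world[inside]


def generate_phantom(
    spec: PhantomSpec, rng_seed: int, treated_side: str = "left"
) -> tuple[IntensityVolume, LabelVolume, StereotacticLandmarks]:
    """Generate one WMn-like phantom: intensities, nucleus labels, landmarks.

    Nuclei are rasterized into both hemispheres (mirrored about the
    midline); thalamic gray is brighter than white matter, with per-nucleus
    contrast offsets.  Deterministic for a fixed seed.  For a right-treated
    patient the whole spec is mirrored about the midsagittal plane, which
    lateralizes the landmarks (the nucleus rasterization already covers
    both hemispheres and is unaffected).
    """
    if treated_side not in ("left", "right"):
        raise ValueError("treated_side must be left/right")
    if treated_side == "right":
        spec = spec.mirrored()
    grid = spec.grid
    labels = np.zeros(grid.dims, dtype=np.int32)
    mean_field = np.full(grid.dims, spec.wm_mean)
    sd_field = np.full(grid.dims, spec.wm_sd)

    for name in _RASTER_ORDER:
        if name not in spec.nuclei:
            continue
        center, axes = spec.nuclei[name]
        code = NUCLEUS_CODES[name]
        for c in (np.asarray(center, float), np.asarray(center, float) * (-1, 1, 1)):
            idx, _ = _rasterize_ellipsoid(grid, c, np.asarray(axes, float))
            labels[idx[:, 0], idx[:, 1], idx[:, 2]] = code
            mean_field[idx[:, 0], idx[:, 1], idx[:, 2]] = (
                spec.thalamus_mean + spec.nucleus_offsets.get(name, 0.0)
            )
            sd_field[idx[:, 0], idx[:, 1], idx[:, 2]] = spec.thalamus_sd

    rng = np.random.default_rng(rng_seed)
    values = mean_field + sd_field * rng.standard_normal(grid.dims)

    landmarks = StereotacticLandmarks(
        AC=spec.ac,
        PC=spec.pc,
        third_ventricle_wall_x=spec.third_ventricle_wall_x,
        treated_side=treated_side,
        midline_x=0.0,
        acpc_plane_z=spec.acpc_plane_z,
    )
    label_map = {code: name for name, code in NUCLEUS_CODES.items() if name in spec.nuclei}
    return (
        IntensityVolume(grid, values),
        LabelVolume(grid, labels, label_map),
        landmarks,
    )


def plant_ablation(
    pre: IntensityVolume,
    spec: AblationSpec,
    thalamus: BinaryMask,
    rng_seed: int,
) -> tuple[IntensityVolume, BinaryMask, BinaryMask]:
    """Plant a three-zone ablation into a pre-treatment volume.

    Returns (post volume, true core mask, whole-ablation mask).  The post
    volume equals the pre volume outside the penumbra.  Within each zone
    the intensity is set to the zone's scaled level (penumbra
    ``penumbra_boost``, core ``core_boost``, central hypointensity
    ``core_boost + hypointense_offset``) plus seeded texture noise, in
    units of the thalamus intensity distribution; zones at level 0 are
    left untouched.  The central hypointensity stays sub-threshold — it is
    the hole the closing step of the segmentation is there to fill — but
    remains part of the true core extent.
    """
    grid = pre.grid
    center = np.asarray(spec.center, dtype=float)
    c_idx = grid.world_to_index(center)
    if np.any(c_idx < 0) or np.any(c_idx > np.asarray(grid.dims) - 1):
        raise ValueError("ablation center lies outside the grid")

    tvals = pre.values[thalamus.data]
    med = percentile(tvals, 50.0)
    p99 = percentile(tvals, 99.0)
    den = p99 - med
    if den <= 0:
        raise ValueError("degenerate thalamus intensity distribution")

    r = np.asarray([spec.penumbra_radius] * 3)
    idx, world = _rasterize_ellipsoid(grid, center, r)
    d = np.linalg.norm(world - center, axis=1)
    pen_sel = d <= spec.penumbra_radius
    core_sel = d <= spec.core_radius
    hypo_sel = d <= spec.hypointense_radius

    post = pre.values.copy()
    ii, jj, kk = idx[:, 0], idx[:, 1], idx[:, 2]
    level = np.where(core_sel, spec.core_boost, spec.penumbra_boost)
    level = np.where(hypo_sel, spec.core_boost + spec.hypointense_offset, level)
    rng = np.random.default_rng(rng_seed)
    texture = spec.texture_sd * rng.standard_normal(len(idx))
    touched = level != 0.0  # level-0 zones are invisible: image unchanged
    sel = (ii[touched], jj[touched], kk[touched])
    post[sel] = med + (level[touched] + texture[touched]) * den

    if spec.core_boost > 0:
        floor_sel = core_sel & ~hypo_sel
        floor_val = med + spec.min_core_scaled * den
        fi, fj, fk = ii[floor_sel], jj[floor_sel], kk[floor_sel]
        post[fi, fj, fk] = np.maximum(post[fi, fj, fk], floor_val)

    whole = np.zeros(grid.dims, dtype=bool)
    whole[ii[pen_sel], jj[pen_sel], kk[pen_sel]] = True
    core = np.zeros(grid.dims, dtype=bool)
    core[ii[core_sel], jj[core_sel], kk[core_sel]] = True
    return (
        IntensityVolume(grid, post),
        BinaryMask(grid, core),
        BinaryMask(grid, whole),
    )


def generate_outcomes(
    overlap_fractions: Sequence[float],
    model: OutcomeModel = OutcomeModel(),
    rng_seed: int = 0,
) -> list[tuple[int, int]]:
    """Integer (baseline, one-month) CRST pairs from overlap fractions."""
    ov = np.asarray(overlap_fractions, dtype=float)
    if np.any((ov < 0) | (ov > 1)):
        raise ValueError("overlap fractions must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    lo, hi = model.score_min, model.score_max
    baseline = np.clip(
        np.rint(rng.normal(model.baseline_mean, model.baseline_sd, size=len(ov))), lo, hi
    ).astype(int)
    eps = rng.normal(0.0, model.noise_sd, size=len(ov)) if model.noise_sd > 0 else np.zeros(len(ov))
    one_month = np.clip(
        np.rint(
            baseline
            - model.improvement_intercept
            - model.improvement_slope * ov
            - eps
        ),
        lo,
        hi,
    ).astype(int)
    return list(zip(baseline.tolist(), one_month.tolist()))


def true_overlap_fractions(
    centers: np.ndarray, spec: PhantomSpec
) -> np.ndarray:
    """Template-space overlap of core spheres at ``centers`` with the hidden
    efficacious region, as the fraction of the efficacious region covered.

    The efficacious region is the exact-volume sphere at the hidden center;
    a core covers those of its voxels whose centers lie within the core
    radius of the ablation center.
    """
    grid = spec.grid
    eff = sphere_target(spec.efficacious_center, spec.efficacious_volume_mm3, grid)
    eff_world = grid.index_to_world(eff.indices())
    core_r = AblationSpec(center=(0, 0, 0)).core_radius
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    d = np.linalg.norm(eff_world[None, :, :] - centers[:, None, :], axis=2)
    return (d <= core_r).mean(axis=1)


def draw_ablation_centers(
    n_patients: int,
    phantom: PhantomSpec,
    ablation_jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Template-space ablation centers: hidden center + per-axis Gaussian
    jitter, re-drawn until inside the thalamus (canonical left hemisphere)."""
    hidden = np.asarray(phantom.efficacious_center, dtype=float)
    centers = np.empty((n_patients, 3))
    for i in range(n_patients):
        for _ in range(1000):
            c = hidden + rng.normal(0.0, ablation_jitter, size=3)
            if phantom.point_in_thalamus(c):
                centers[i] = c
                break
        else:
            raise RuntimeError("could not draw an ablation center inside the thalamus")
    return centers


def _default_right_treated(n: int) -> list[int]:
    # 3 of 14 default patients right-treated (indices of B, D, L)
    return [i for i in (1, 3, 11) if i < n]


def _patient_ids(n: int) -> list[str]:
    if n <= 26:
        return [chr(ord("A") + i) for i in range(n)]
    return [f"P{i + 1:03d}" for i in range(n)]


def generate_cohort(
    n_patients: int = 14,
    phantom: PhantomSpec = PhantomSpec(),
    ablation_jitter: float = 1.5,
    model: OutcomeModel = OutcomeModel(),
    right_treated_ids: Sequence[int] | None = None,
    rng_seed: int = 0,
    ablation: AblationSpec | None = None,
) -> list[CohortRecord]:
    """Generate a full synthetic patient cohort.

    Each patient's ablation center is the hidden efficacious center plus
    per-axis Gaussian jitter (re-drawn until it lies inside the thalamus,
    honoring the planting precondition); right-treated patients get fully
    mirrored anatomy and a right-hemisphere ablation.  Each patient space
    relates to the template by a small random whole-millimetre translation
    (``to_template`` maps patient mm to template mm); integer offsets keep
    nearest-neighbor mask transport between the spaces exact, so no
    resampling artifact is layered on top of the targeting variability.
    Outcomes are driven by the overlap of the true core with the hidden
    efficacious region.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    right_ids = (
        _default_right_treated(n_patients)
        if right_treated_ids is None
        else list(right_treated_ids)
    )
    if any(i < 0 or i >= n_patients for i in right_ids):
        raise ValueError("right_treated_ids outside cohort range")

    root = np.random.SeedSequence(rng_seed)
    seeds = root.spawn(n_patients)
    ids = _patient_ids(n_patients)
    base_ablation = ablation or AblationSpec(center=tuple(phantom.efficacious_center))

    # template-space ablation centers (canonical left hemisphere)
    center_rng = np.random.default_rng(root.spawn(1)[0])
    centers = draw_ablation_centers(n_patients, phantom, ablation_jitter, center_rng)

    overlaps = true_overlap_fractions(centers, phantom)
    outcome_seed = int(np.random.default_rng(root.spawn(1)[0]).integers(2**31))
    outcomes = generate_outcomes(overlaps, model, outcome_seed)

    records: list[CohortRecord] = []
    for i in range(n_patients):
        child = np.random.default_rng(seeds[i])
        side = "right" if i in right_ids else "left"
        # patient -> template translation; whole millimetres so that
        # nearest-neighbor mask transport between spaces is exact
        t = child.integers(-2, 3, size=3).astype(float)
        patient_spec = phantom.shifted(-t)
        phantom_seed = int(child.integers(2**31))
        pre, nuclei, landmarks = generate_phantom(patient_spec, phantom_seed, side)

        center_patient = centers[i] - t
        if side == "right":
            center_patient = center_patient * (-1, 1, 1)
        ab_spec = replace(base_ablation, center=tuple(center_patient))
        thalamus = BinaryMask(nuclei.grid, nuclei.labels > 0)
        ablation_seed = int(child.integers(2**31))
        post, true_core, whole = plant_ablation(pre, ab_spec, thalamus, ablation_seed)

        to_template = np.eye(4)
        to_template[:3, 3] = t
        base_score, month_score = outcomes[i]
        records.append(
            CohortRecord(
                patient_id=ids[i],
                treated_side=side,
                pre_volume=pre,
                post_volume=post,
                nuclei=nuclei,
                whole_ablation=whole,
                landmarks=landmarks,
                to_template=to_template,
                crst_baseline=base_score,
                crst_1month=month_score,
                true_core=true_core,
                true_overlap=float(overlaps[i]),
                ablation_center_template=tuple(centers[i]),
            )
        )
    return records


def write_cohort(records: Sequence[CohortRecord], outdir: str | Path) -> None:
    """Write a cohort to disk: one directory per patient with NIfTI volumes
    and a landmarks JSON, a cohort outcomes TSV, and a ground-truth JSON
    (testing only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth: dict[str, dict] = {}
    for rec in records:
        pdir = outdir / rec.patient_id
        pdir.mkdir(exist_ok=True)
        write_volume(rec.pre_volume, pdir / "pre.nii.gz")
        write_volume(rec.post_volume, pdir / "post.nii.gz")
        write_volume(rec.nuclei, pdir / "nuclei.nii.gz")
        write_volume(rec.whole_ablation, pdir / "whole_ablation.nii.gz")
        write_volume(rec.true_core, pdir / "true_core.nii.gz")
        rec.landmarks.to_json(pdir / "landmarks.json")
        np.savetxt(pdir / "to_template.txt", rec.to_template)
        rows.append(
            f"{rec.patient_id}\t{rec.treated_side}\t{rec.crst_baseline}\t{rec.crst_1month}"
        )
        truth[rec.patient_id] = {
            "true_overlap": rec.true_overlap,
            "ablation_center_template": list(rec.ablation_center_template),
        }
    header = "patient_id\ttreated_side\tcrst_baseline\tcrst_1month"
    (outdir / "outcomes.tsv").write_text("\n".join([header, *rows]) + "\n")
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))


def load_cohort(outdir: str | Path) -> list[CohortRecord]:
    """Read back a cohort directory written by :func:`write_cohort`."""
    from .grids import read_volume

    outdir = Path(outdir)
    label_map = {code: name for name, code in NUCLEUS_CODES.items()}
    truth = json.loads((outdir / "ground_truth.json").read_text())
    records = []
    for line in (outdir / "outcomes.tsv").read_text().strip().splitlines()[1:]:
        pid, side, base, month = line.split("\t")
        pdir = outdir / pid
        records.append(
            CohortRecord(
                patient_id=pid,
                treated_side=side,
                pre_volume=read_volume(pdir / "pre.nii.gz", "intensity"),
                post_volume=read_volume(pdir / "post.nii.gz", "intensity"),
                nuclei=read_volume(pdir / "nuclei.nii.gz", "label", label_map),
                whole_ablation=read_volume(pdir / "whole_ablation.nii.gz", "mask"),
                landmarks=StereotacticLandmarks.from_json(pdir / "landmarks.json"),
                to_template=np.loadtxt(pdir / "to_template.txt"),
                crst_baseline=int(base),
                crst_1month=int(month),
                true_core=read_volume(pdir / "true_core.nii.gz", "mask"),
                true_overlap=float(truth[pid]["true_overlap"]),
                ablation_center_template=tuple(truth[pid]["ablation_center_template"]),
            )
        )
    return records
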