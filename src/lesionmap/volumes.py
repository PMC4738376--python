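"""Standard-space volume and cohort handling.

Volumes are 3-D lattices with a NIfTI-style affine mapping 0-based voxel
indices to world millimetres (x increasing to the anatomical right, the
mid-sagittal plane at x = 0 mm).  "Slice z" always means the set of voxels
sharing the third index.  Lesion masks are binary; a cohort is the aligned
set of masks plus one behavioural record per subject.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("lesionmap")

#: behavioural table columns that must be present in a cohort CSV
REQUIRED_COLUMNS = (
    "subject_id", "side",
    "walk_baseline", "walk_outcome",
    "fac_baseline", "fac_outcome",
    "mrmi_baseline", "mrmi_outcome",
    "age", "fazekas", "time_days",
)

MEASURES = ("walk", "fac", "mrmi")


class CohortError(ValueError):
    """Inconsistent cohort inputs (grid mismatch, duplicate ids, ...)."""


class OrientationError(ValueError):
    """Affine not axis-aligned the way an operation requires."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar lattice plus its voxel-to-mm affine.

    ``data`` semantics depend on use: binary mask, t value, or integer
    label.  ``affine`` is the usual 4x4 homogeneous map from 0-based voxel
    indices to mm coordinates.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def voxels_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (n,3) array of voxel indices to mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data=data, affine=self.affine)


def centered_affine(shape: Sequence[int], voxel_mm: float) -> np.ndarray:
    """Isotropic affine placing the grid centre at the world origin.

    The mid-sagittal plane x = 0 mm then sits midway along the first index
    axis, which is what hemisphere flipping assumes.
    """
    shape = tuple(int(s) for s in shape)
    aff = np.eye(4)
    aff[:3, :3] *= voxel_mm
    aff[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    return aff


def as_mask(grid: VolumeGrid, warn: bool = True) -> VolumeGrid:
    """Binarize at > 0; delineation tools emit 0/1 or 0/255 interchangeably."""
    vals = np.unique(grid.data)
    if not np.isin(vals, (0, 1)).all():
        if warn:
            logger.warning("mask values %s binarized at >0", vals[:6])
        return grid.with_data((grid.data > 0).astype(np.uint8))
    return grid.with_data(grid.data.astype(np.uint8))


def read_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D volume, got shape {data.shape}")
    return VolumeGrid(data=data, affine=np.asarray(img.affine, dtype=float))


def read_mask(path: str | Path, reference: VolumeGrid | None = None) -> VolumeGrid:
    """Read a binary lesion mask; any nonzero voxel becomes 1.

    If ``reference`` is given the mask must share its dimensions and affine.
    """
    grid = as_mask(read_volume(path))
    if reference is not None and not grid.same_grid(reference):
        raise CohortError(
            f"{path}: dims/affine do not match the reference grid "
            f"({grid.shape} vs {reference.shape})"
        )
    return grid


def write_volume(grid: VolumeGrid, path: str | Path, dtype=None) -> None:
    data = grid.data if dtype is None else grid.data.astype(dtype)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


def _check_x_aligned(grid: VolumeGrid) -> None:
    aff = grid.affine
    if np.any(np.abs(aff[0, 1:3]) > 1e-6) or np.any(np.abs(aff[1:3, 0]) > 1e-6):
        raise OrientationError(
            "affine x-axis is not aligned with the first index axis; "
            "oblique volumes are rejected rather than resampled"
        )


def flip_to_left(mask: VolumeGrid, side: str) -> VolumeGrid:
    """Mirror a right-sided lesion about the mid-sagittal plane x = 0 mm.

    Left-sided masks are returned unchanged.  The flip is a pure index
    reversal along the first axis, valid only when that axis carries x and
    the grid is symmetric about x = 0 (so the reversal is exact, with no
    resampling).  Lesion voxel count is preserved exactly.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if side == "left":
        return mask
    _check_x_aligned(mask)
    n = mask.shape[0]
    x_first = mask.voxels_to_mm([[0, 0, 0]])[0, 0]
    x_last = mask.voxels_to_mm([[n - 1, 0, 0]])[0, 0]
    if abs(x_first + x_last) > 1e-4:
        raise OrientationError(
            "grid is not symmetric about x = 0 mm; index-reversal flipping "
            f"would shift the mask (x spans [{x_first:.2f}, {x_last:.2f}])"
        )
    return mask.with_data(mask.data[::-1, :, :].copy())


def voxels_to_ml(n_voxels: int | float, grid: VolumeGrid) -> float:
    """Convert a voxel count on ``grid`` to millilitres."""
    if n_voxels < 0:
        raise ValueError("n_voxels must be >= 0")
    return float(n_voxels) * grid.voxel_volume_mm3 / 1000.0


@dataclass
class SubjectRecord:
    """One subject's behavioural row.

    ``change`` is outcome minus baseline per measure — the response to the
    6-week course of therapy, the quantity every downstream model predicts.
    """

    subject_id: str
    side: str
    baseline: dict[str, float]
    outcome: dict[str, float]
    age: float
    fazekas: int
    time_days: float
    lesion_volume_cm3: float | None = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.fazekas not in (0, 1, 2, 3):
            raise ValueError(f"fazekas must be in 0..3, got {self.fazekas}")
        if self.time_days < 0:
            raise ValueError("time_to_baseline must be >= 0")
        for m in MEASURES:
            for d in (self.baseline, self.outcome):
                if m not in d:
                    raise ValueError(f"missing measure {m!r}")
        for d in (self.baseline, self.outcome):
            if not (0 <= d["fac"] <= 5 and float(d["fac"]).is_integer()):
                raise ValueError(f"FAC must be integer in 0..5, got {d['fac']}")
            if not (0 <= d["mrmi"] <= 40 and float(d["mrmi"]).is_integer()):
                raise ValueError(f"MRMI must be integer in 0..40, got {d['mrmi']}")
            if d["walk"] < 0:
                raise ValueError("walk speed must be >= 0")

    @property
    def change(self) -> dict[str, float]:
        return {m: self.outcome[m] - self.baseline[m] for m in MEASURES}


@dataclass
class LesionCohort:
    """Aligned lesion masks (all flipped onto the left hemisphere) plus
    behavioural records, index-matched one-to-one."""

    masks: list[VolumeGrid]
    records: list[SubjectRecord]
    exclusions: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.masks) != len(self.records):
            raise CohortError("masks and records differ in length")
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate subject_id in cohort")
        if self.masks:
            ref = self.masks[0]
            for m, r in zip(self.masks, self.records):
                if not m.same_grid(ref):
                    raise CohortError(
                        f"mask for {r.subject_id} is on a different grid"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def grid(self) -> VolumeGrid:
        if not self.masks:
            raise CohortError("empty cohort has no grid")
        return self.masks[0]

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def stacked_masks(self) -> np.ndarray:
        """(n_subjects, nx, ny, nz) uint8 stack of the masks."""
        return np.stack([m.data for m in self.masks]).astype(np.uint8)

    def table(self) -> pd.DataFrame:
        """Behavioural table with per-measure change columns."""
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id, "side": r.side,
                "age": r.age, "fazekas": r.fazekas, "time_days": r.time_days,
                "lesion_volume_cm3": r.lesion_volume_cm3,
            }
            for m in MEASURES:
                row[f"{m}_baseline"] = r.baseline[m]
                row[f"{m}_outcome"] = r.outcome[m]
                row[f"{m}_change"] = r.outcome[m] - r.baseline[m]
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, keep: Iterable[int]) -> "LesionCohort":
        keep = list(keep)
        return LesionCohort(
            masks=[self.masks[i] for i in keep],
            records=[self.records[i] for i in keep],
            exclusions=list(self.exclusions),
        )


def record_from_row(row: pd.Series, lesion_volume_cm3: float | None = None) -> SubjectRecord:
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        side=str(row["side"]),
        baseline={m: float(row[f"{m}_baseline"]) for m in MEASURES},
        outcome={m: float(row[f"{m}_outcome"]) for m in MEASURES},
        age=float(row["age"]),
        fazekas=int(row["fazekas"]),
        time_days=float(row["time_days"]),
        lesion_volume_cm3=lesion_volume_cm3,
    )


def load_cohort(mask_dir: str | Path, behaviour_table: str | Path) -> LesionCohort:
    """Join the behavioural CSV against ``mask_dir`` and flip right-sided
    lesions onto the left hemisphere.

    Mask files are matched by ``<subject_id>.nii`` / ``.nii.gz``.  Rows with
    a missing mask or missing outcome are excluded with a logged warning and
    kept in the provenance list; duplicated subject ids are an error.
    """
    mask_dir = Path(mask_dir)
    df = pd.read_csv(behaviour_table)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"behaviour table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise CohortError("duplicate subject_id in behaviour table")

    masks: list[VolumeGrid] = []
    records: list[SubjectRecord] = []
    exclusions: list[str] = []
    reference: VolumeGrid | None = None
    matched: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        path = None
        for ext in (".nii.gz", ".nii"):
            cand = mask_dir / f"{sid}{ext}"
            if cand.exists():
                path = cand
                break
        if path is None:
            exclusions.append(f"{sid}: no mask file")
            logger.warning("excluding %s: no mask file", sid)
            continue
        outcome_cols = [f"{m}_outcome" for m in MEASURES]
        if row[outcome_cols].isna().any():
            exclusions.append(f"{sid}: missing outcome score")
            logger.warning("excluding %s: missing outcome score", sid)
            continue
        mask = read_mask(path, reference)
        if reference is None:
            reference = mask
        mask = flip_to_left(mask, str(row["side"]))
        vol = voxels_to_ml(int(mask.data.sum()), mask)  # mL == cm^3
        masks.append(mask)
        records.append(record_from_row(row, lesion_volume_cm3=vol))
        matched.add(sid)

    stems = {p.name.removesuffix(".nii.gz").removesuffix(".nii")
             for p in mask_dir.iterdir() if p.name.endswith((".nii", ".nii.gz"))}
    for orphan in sorted(stems - set(df["subject_id"].astype(str))):
        exclusions.append(f"{orphan}: mask without behavioural row")
        logger.warning("mask %s has no behavioural row", orphan)

    return LesionCohort(masks=masks, records=records, exclusions=exclusions)
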