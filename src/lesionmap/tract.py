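"""Weighted tract lesion load (wCST-LL).

The load of a lesion against a canonical corticospinal tract is the
lesion-tract overlap summed over axial slices, with each slice's overlap
weighted by A_max / A(z) — the ratio of the tract's maximum cross-sectional
area to its area on that slice.  The weighting compensates for the
narrowing of the tract as it descends from the motor cortex into the
posterior limb of the internal capsule, so a small capsular lesion that
transects the tract scores as heavily as a large lesion higher up.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import LesionCohort, VolumeGrid, as_mask


@dataclass(frozen=True)
class TractMap:
    """A binary canonical tract with its per-slice area profile.

    ``slice_area[z]`` is the tract cross-section on slice z in mm²,
    recomputable as voxel count x in-plane voxel area.  ``z_support`` is the
    inclusive slice range where the tract exists.
    """

    mask: VolumeGrid
    slice_area: np.ndarray
    max_area: float
    z_support: tuple[int, int]

    @classmethod
    def from_mask(cls, mask: VolumeGrid) -> "TractMap":
        mask = as_mask(mask, warn=False)
        if mask.data.sum() == 0:
            raise ValueError("empty tract mask")
        sx, sy, _ = mask.voxel_sizes_mm
        in_plane = float(sx * sy)
        counts = mask.data.sum(axis=(0, 1))
        areas = counts.astype(float) * in_plane
        nz = np.nonzero(counts)[0]
        return cls(
            mask=mask,
            slice_area=areas,
            max_area=float(areas.max()),
            z_support=(int(nz[0]), int(nz[-1])),
        )


@dataclass
class LoadResult:
    """wCST-LL for one lesion: total load plus the per-slice breakdown."""

    wcst_ll_cm3: float | None
    per_slice: pd.DataFrame
    status: str  # "ok" | "outside_tract_support"


def weighted_tract_load(lesion: VolumeGrid, tract: TractMap) -> LoadResult:
    """Slice-weighted overlap of ``lesion`` with the canonical tract.

    For each slice z where the tract has area A(z) > 0, the overlap volume
    o(z) (mm³) contributes o(z) * A_max / A(z); the load is the sum over
    slices divided by 1000 (cm³).  A lesion with no voxel in any slice of
    the tract's z-support — e.g. a medullary lesion below a supratentorial
    canonical tract — is flagged ``outside_tract_support`` and its load
    reported as missing rather than zero.
    """
    if not lesion.same_grid(tract.mask):
        raise ValueError("lesion and tract are on different grids")
    lesion = as_mask(lesion, warn=False)
    z0, z1 = tract.z_support
    lesion_per_slice = lesion.data.sum(axis=(0, 1))
    if lesion.data.sum() > 0 and lesion_per_slice[z0:z1 + 1].sum() == 0:
        return LoadResult(wcst_ll_cm3=None, per_slice=pd.DataFrame(), status="outside_tract_support")

    vox_mm3 = lesion.voxel_volume_mm3
    overlap_counts = (lesion.data.astype(bool) & tract.mask.data.astype(bool)).sum(axis=(0, 1))
    rows = []
    total_mm3 = 0.0
    for z in range(z0, z1 + 1):
        area = tract.slice_area[z]
        if area <= 0:  # gap inside support: tract absent, overlap necessarily 0
            continue
        o_mm3 = float(overlap_counts[z]) * vox_mm3
        weight = tract.max_area / area
        contrib = o_mm3 * weight
        total_mm3 += contrib
        rows.append({
            "z": z, "overlap_mm3": o_mm3, "area_mm2": area,
            "weight": weight, "weighted_mm3": contrib,
        })
    return LoadResult(
        wcst_ll_cm3=total_mm3 / 1000.0,
        per_slice=pd.DataFrame(rows),
        status="ok",
    )


def cohort_loads(cohort: LesionCohort, tract: TractMap) -> pd.DataFrame:
    """wCST-LL per subject.

    Subjects whose lesion lies entirely outside the tract's z-support are
    flagged (status ``outside_tract_support``, load NaN) so downstream
    regressions can drop them instead of treating the load as zero.
    """
    rows = []
    for mask, rec in zip(cohort.masks, cohort.records):
        res = weighted_tract_load(mask, tract)
        rows.append({
            "subject_id": rec.subject_id,
            "wcst_ll_cm3": np.nan if res.wcst_ll_cm3 is None else res.wcst_ll_cm3,
            "status": res.status,
        })
    return pd.DataFrame(rows)
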