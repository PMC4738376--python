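"""Synthetic lesion cohorts with known ground truth.

Real lesion-mapping cohorts cannot be redistributed, so every downstream
stage is exercised on simulated ones: blob-like lesions drawn around a
striatocapsular hotspot (a single spatial mode of per-voxel overlap, with
peak overlap around half the cohort), a canonical descending tract whose
cross-section narrows mid-course, a rectangular label atlas, and
behavioural change scores generated as a linear function of the lesion's
overlap with a designated effect region plus covariate effects and noise.
The generating coefficients are returned as ground truth so recovery is
testable exactly.

All randomness flows from one integer seed through per-subject substreams
(``SeedSequence.spawn``), so extending the cohort never perturbs earlier
subjects.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import LabelAtlas, write_atlas
from .tract import TractMap
from .volumes import (
    LesionCohort, SubjectRecord, VolumeGrid, centered_affine, flip_to_left,
    write_volume,
)

# Latent-scale coefficients for the ordinal scales.  The latent response is
# latent = l0 + l_eff*effect_beta*overlap_mL + l_base*baseline
#          + l_age*(age-65) + l_time*(time-16) + Logistic(0, 1)
# and the observed score counts the cutpoints below it, which is exactly a
# proportional-odds model — so ordinal-regression recovery is testable by
# construction.
_FAC_LATENT = dict(l0=2.0, l_eff=4.0, l_base=0.5, l_age=-0.04, l_time=-0.03)
_MRMI_LATENT = dict(l0=18.0, l_eff=30.0, l_base=0.6, l_age=-0.08, l_time=-0.06)


def _default_effect_region() -> tuple:
    # 4x4x4 voxel box inside the hotspot, straddling the atlas j=16 boundary
    return ((8, 12), (14, 18), (12, 16))


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of the synthetic cohort.

    ``effect_beta`` is in score units (m/s for walk speed) per mL of
    lesion overlap with the effect region; it is <= 0 so that damage hurts.
    ``effect_region`` is an axis-aligned voxel box given as ((i0,i1),
    (j0,j1), (k0,k1)) half-open bounds.
    """

    grid_dims: tuple[int, int, int] = (32, 32, 32)
    voxel_mm: float = 2.0
    n_subjects: int = 50
    hotspot_centre: tuple[int, int, int] = (10, 16, 16)
    hotspot_sd: float = 6.0                      # mm
    lesion_radius_range: tuple[float, float] = (4.0, 12.0)  # mm
    effect_region: tuple = field(default_factory=_default_effect_region)
    effect_beta: float = -0.8                    # m/s per mL of overlap
    intercept: float = 0.70                      # m/s
    baseline_beta: float = -0.5
    age_beta: float = -0.002                     # per year
    time_beta: float = -0.005                    # per day
    noise_sd: float = 0.08                       # m/s
    fac_cutpoints: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 3.0)
    mrmi_cutpoints: tuple[float, ...] = tuple(np.linspace(0.5, 39.5, 40))
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must be positive")
        for cuts in (self.fac_cutpoints, self.mrmi_cutpoints):
            if not np.all(np.diff(cuts) > 0):
                raise ValueError("cutpoint lists must be strictly increasing")
        for (a, b), dim in zip(self.effect_region, self.grid_dims):
            if not (0 <= a < b <= dim):
                raise ValueError("effect_region must lie inside grid_dims")

    @property
    def affine(self) -> np.ndarray:
        return centered_affine(self.grid_dims, self.voxel_mm)

    def effect_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_dims, dtype=bool)
        (i0, i1), (j0, j1), (k0, k1) = self.effect_region
        m[i0:i1, j0:j1, k0:k1] = True
        return m

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mrmi_cutpoints"] = [float(c) for c in d["mrmi_cutpoints"]]
        return d


@dataclass
class GroundTruth:
    """What the simulator actually implanted."""

    overlap_ml: np.ndarray            # per-subject effect-region overlap, mL
    coefficients: dict[str, float]    # generating walk-change model
    effect_centre_mm: np.ndarray      # effect-region centre of mass
    effect_centre_vox: np.ndarray


def make_tract(config: SimulationConfig) -> TractMap:
    """A vertical tube spanning the full z-range, wide at the top and
    narrow mid-course, so the slice weighting A_max/A(z) is non-trivial
    (weights up to ~5 at the waist, like a descending tract entering the
    internal capsule)."""
    nx, ny, nz = config.grid_dims
    cx, cy = config.hotspot_centre[0], config.hotspot_centre[1]
    z = np.arange(nz)
    # radius profile in voxels: wide at top (high z), pinched at mid-course
    top, bottom, waist = 3.4, 2.4, 1.2
    zw = nz * 0.45
    width = nz * 0.18
    base = bottom + (top - bottom) * z / (nz - 1)
    radius = waist + (base - waist) * (1 - np.exp(-((z - zw) ** 2) / (2 * width**2)))
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dist2 = (ii - cx) ** 2 + (jj - cy) ** 2
    data = (dist2[:, :, None] <= radius[None, None, :] ** 2).astype(np.uint8)
    return TractMap.from_mask(VolumeGrid(data=data, affine=config.affine))


def make_label_atlas(config: SimulationConfig) -> LabelAtlas:
    """Partition the grid into 8 named octants (split at the midpoint of
    each axis) so the default effect region straddles exactly two labels."""
    nx, ny, nz = config.grid_dims
    hx, hy, hz = nx // 2, ny // 2, nz // 2
    labels = np.zeros(config.grid_dims, dtype=np.int16)
    names: dict[int, str] = {}
    lid = 0
    for xi, xname in ((0, "left"), (1, "right")):
        for yi, yname in ((0, "posterior"), (1, "anterior")):
            for zi, zname in ((0, "inferior"), (1, "superior")):
                lid += 1
                sl = (slice(0, hx) if xi == 0 else slice(hx, nx),
                      slice(0, hy) if yi == 0 else slice(hy, ny),
                      slice(0, hz) if zi == 0 else slice(hz, nz))
                labels[sl] = lid
                names[lid] = f"{xname}-{yname}-{zname}"
    return LabelAtlas(
        labels=VolumeGrid(data=labels, affine=config.affine),
        names=names, atlas_name="synthetic-octants",
    )


def _subject_lesion(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """A voxelized sphere with jittered boundary around a hotspot draw."""
    dims = np.array(config.grid_dims)
    centre_vox = np.array(config.hotspot_centre, dtype=float)
    centre_vox = centre_vox + rng.normal(0.0, config.hotspot_sd / config.voxel_mm, 3)
    radius = rng.uniform(*config.lesion_radius_range)
    idx = np.indices(config.grid_dims).reshape(3, -1).T.astype(float)
    dist = np.linalg.norm((idx - centre_vox) * config.voxel_mm, axis=1)
    jitter = rng.uniform(-0.6, 0.6, dist.shape) * config.voxel_mm
    mask = (dist + jitter) <= radius
    mask = mask.reshape(config.grid_dims)
    if not mask.any():
        nearest = np.clip(np.rint(centre_vox).astype(int), 0, dims - 1)
        mask[tuple(nearest)] = True
    return mask.astype(np.uint8)


def _ordinal_from_latent(eta: float, cutpoints, rng: np.random.Generator) -> int:
    latent = eta + rng.logistic(0.0, 1.0)
    return int(np.sum(latent > np.asarray(cutpoints)))


def make_cohort(config: SimulationConfig) -> tuple[LesionCohort, GroundTruth]:
    """Draw the full cohort: lesions, covariates, and change scores with
    the implanted lesion-location effect.

    Walk-speed change is
    ``intercept + effect_beta*overlap_mL + baseline_beta*baseline
    + age_beta*age + time_beta*time + N(0, noise_sd)``, truncated so the
    outcome stays >= 0.  FAC/MRMI outcomes come from a latent logistic
    response thresholded at the configured cutpoints (bounds 0-5 and 0-40
    hold by construction).  Identical seed implies a bit-identical cohort.
    """
    effect = config.effect_mask()
    if not effect.any():
        raise ValueError("empty effect region")
    vox_ml = config.voxel_mm**3 / 1000.0
    affine = config.affine

    substreams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    masks: list[VolumeGrid] = []
    records: list[SubjectRecord] = []
    overlaps = np.empty(config.n_subjects)
    for i, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        lesion = _subject_lesion(config, rng)
        overlap_ml = float(np.logical_and(lesion, effect).sum()) * vox_ml
        overlaps[i] = overlap_ml

        age = float(rng.uniform(30.0, 92.0))
        fazekas = int(rng.choice(4, p=[0.15, 0.35, 0.35, 0.15]))
        time_days = float(rng.uniform(3.0, 42.0))
        walk_base = float(rng.uniform(0.0, 0.5))
        fac_base = int(rng.choice(6, p=[0.25, 0.30, 0.25, 0.10, 0.06, 0.04]))
        mrmi_base = int(rng.integers(5, 36))

        change = (config.intercept
                  + config.effect_beta * overlap_ml
                  + config.baseline_beta * walk_base
                  + config.age_beta * age
                  + config.time_beta * time_days
                  + rng.normal(0.0, config.noise_sd))
        walk_out = max(0.0, walk_base + change)

        eff = config.effect_beta * overlap_ml
        eta_fac = (_FAC_LATENT["l0"] + _FAC_LATENT["l_eff"] * eff
                   + _FAC_LATENT["l_base"] * fac_base
                   + _FAC_LATENT["l_age"] * (age - 65.0)
                   + _FAC_LATENT["l_time"] * (time_days - 16.0))
        fac_out = _ordinal_from_latent(eta_fac, config.fac_cutpoints, rng)
        eta_mrmi = (_MRMI_LATENT["l0"] + _MRMI_LATENT["l_eff"] * eff
                    + _MRMI_LATENT["l_base"] * mrmi_base
                    + _MRMI_LATENT["l_age"] * (age - 65.0)
                    + _MRMI_LATENT["l_time"] * (time_days - 16.0))
        mrmi_out = _ordinal_from_latent(eta_mrmi, config.mrmi_cutpoints, rng)

        side = "left" if i % 2 == 0 else "right"
        masks.append(VolumeGrid(data=lesion, affine=affine))
        records.append(SubjectRecord(
            subject_id=f"sub-{i:03d}", side=side,
            baseline={"walk": walk_base, "fac": fac_base, "mrmi": mrmi_base},
            outcome={"walk": walk_out, "fac": fac_out, "mrmi": mrmi_out},
            age=age, fazekas=fazekas, time_days=time_days,
            lesion_volume_cm3=float(lesion.sum()) * vox_ml,
        ))

    if overlaps.max() == 0:
        import warnings
        warnings.warn("effect region has zero overlap with every lesion; "
                      "the implanted effect is unidentifiable", stacklevel=2)

    centre_vox = np.argwhere(effect).mean(axis=0)
    grid0 = masks[0]
    truth = GroundTruth(
        overlap_ml=overlaps,
        coefficients={
            "intercept": config.intercept,
            "effect_beta": config.effect_beta,
            "baseline_beta": config.baseline_beta,
            "age_beta": config.age_beta,
            "time_beta": config.time_beta,
            "noise_sd": config.noise_sd,
        },
        effect_centre_mm=grid0.voxels_to_mm(centre_vox)[0],
        effect_centre_vox=centre_vox,
    )
    return LesionCohort(masks=masks, records=records), truth


def make_null_cohort(config: SimulationConfig) -> LesionCohort:
    """Same lesion geometry, scores independent of lesion location
    (the implanted effect forced to zero) — the FWER calibration null."""
    cohort, _ = make_cohort(dataclasses.replace(config, effect_beta=0.0))
    return cohort


def make_proportional_odds_data(
    n: int, coefficients: dict[str, float], cutpoints, seed: int,
    predictor_sd: float = 1.0,
) -> pd.DataFrame:
    """Standalone proportional-odds draws for ordinal-regression checks.

    Predictors are independent N(0, predictor_sd); the response counts the
    cutpoints below ``x @ beta + Logistic(0, 1)``.
    """
    rng = np.random.default_rng(seed)
    names = list(coefficients)
    X = rng.normal(0.0, predictor_sd, size=(n, len(names)))
    eta = X @ np.array([coefficients[k] for k in names])
    latent = eta + rng.logistic(0.0, 1.0, n)
    y = (latent[:, None] > np.asarray(cutpoints)[None, :]).sum(axis=1)
    df = pd.DataFrame(X, columns=names)
    df["response"] = y
    return df


def write_fixture(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a complete on-disk fixture: masks (right-sided subjects
    mirrored back onto the right hemisphere, so loading exercises the
    flip), tract, atlas, behaviour table, ground truth and config."""
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    cohort, truth = make_cohort(config)

    for mask, rec in zip(cohort.masks, cohort.records):
        on_disk = flip_to_left(mask, rec.side)  # mirroring is an involution
        write_volume(on_disk, out / "masks" / f"{rec.subject_id}.nii.gz",
                     dtype=np.uint8)

    tract = make_tract(config)
    write_volume(tract.mask, out / "tract.nii.gz", dtype=np.uint8)
    write_atlas(make_label_atlas(config), out / "atlas.nii.gz",
                out / "atlas_names.tsv")

    tbl = cohort.table().drop(columns=[c for c in ("walk_change", "fac_change",
                                                   "mrmi_change")])
    tbl.to_csv(out / "behaviour.csv", index=False)

    with open(out / "truth.json", "w") as fh:
        json.dump({
            "overlap_ml": truth.overlap_ml.tolist(),
            "coefficients": truth.coefficients,
            "effect_centre_mm": truth.effect_centre_mm.tolist(),
            "effect_centre_vox": truth.effect_centre_vox.tolist(),
        }, fh, indent=2)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    return out
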