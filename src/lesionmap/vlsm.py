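"""Voxel-based lesion-symptom mapping with permutation FWE correction.

At every voxel lesioned in enough subjects, the behavioural change score is
compared between lesioned and non-lesioned subjects by the t statistic of
the lesion indicator in a linear model with nuisance covariates (age,
white-matter hyperintensity score, days from stroke to baseline, and the
measure's baseline score).  Supra-threshold voxels (uncorrected p < 0.005
by default) form connected clusters, and cluster peak t values are referred
to the permutation distribution of the search-volume maximum t obtained by
reshuffling behavioural rows against lesion masks — the max-statistic
family-wise-error correction.

The voxelwise fits are vectorised over voxels and permutations through the
Frisch-Waugh decomposition: with Z the covariate block (intercept
included), residualising the score and each lesion column on Z reduces the
per-voxel t to closed form, so one matrix product per permutation batch
replaces millions of model fits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import LesionCohort, VolumeGrid, voxels_to_ml

logger = logging.getLogger("lesionmap")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}
DEFAULT_COVARIATES = ("age", "fazekas", "time_days", "baseline")


@dataclass(frozen=True)
class VlsmConfig:
    min_lesioned: int = 6
    p_uncorrected: float = 0.005
    n_permutations: int = 5000
    alpha_corrected: float = 0.05
    connectivity: int = 26
    direction: str = "damage_lowers_score"   # or "two_sided"
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    freedman_lane: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_uncorrected < 1):
            raise ValueError("p_uncorrected must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.direction not in ("damage_lowers_score", "two_sided"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.min_lesioned < 2:
            raise ValueError("min_lesioned must be >= 2")


@dataclass
class TMap:
    """Voxelwise t map (damage-direction sign: positive t means lesioned
    subjects have lower adjusted scores), defined only on the search
    volume."""

    t: VolumeGrid
    df: int
    search: VolumeGrid
    n_inestimable: int = 0


@dataclass
class ClusterResult:
    voxels: np.ndarray                   # (n, 3) voxel indices
    size_voxels: int
    size_ml: float
    peak_t: float
    peak_coord_vox: np.ndarray
    peak_coord_mm: np.ndarray
    centre_of_mass_vox: np.ndarray
    centre_of_mass_mm: np.ndarray
    p_corrected: float | None = None
    significant: bool | None = None


@dataclass
class VlsmReport:
    measure: str
    config: VlsmConfig
    overlap_count: VolumeGrid
    tmap: TMap | None
    clusters: list[ClusterResult]
    t_threshold: float | None
    perm_max_t: np.ndarray | None
    log: list[str] = field(default_factory=list)

    @property
    def significant_clusters(self) -> list[ClusterResult]:
        return [c for c in self.clusters if c.significant]

    def clusters_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters, start=1):
            rows.append({
                "cluster": i, "size_voxels": c.size_voxels, "size_ml": c.size_ml,
                "peak_t": c.peak_t,
                "peak_x_mm": c.peak_coord_mm[0], "peak_y_mm": c.peak_coord_mm[1],
                "peak_z_mm": c.peak_coord_mm[2],
                "com_x_mm": c.centre_of_mass_mm[0], "com_y_mm": c.centre_of_mass_mm[1],
                "com_z_mm": c.centre_of_mass_mm[2],
                "p_corrected": c.p_corrected, "significant": c.significant,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# search volume


def build_search_volume(cohort: LesionCohort, min_lesioned: int
                        ) -> tuple[VolumeGrid, VolumeGrid]:
    """Voxels lesioned in >= ``min_lesioned`` subjects (and spared in at
    least two, so a comparison group exists), plus the raw overlap-count
    map."""
    n = len(cohort)
    if not (2 <= min_lesioned <= n - 2):
        raise ValueError(f"min_lesioned must be in [2, {n - 2}]")
    counts = cohort.stacked_masks().sum(axis=0).astype(np.int32)
    search = (counts >= min_lesioned) & (n - counts >= 2)
    grid = cohort.grid
    return grid.with_data(search), grid.with_data(counts)


# ---------------------------------------------------------------------------
# voxelwise GLM kernel


def _t_kernel(num: np.ndarray, den: np.ndarray, yy: float | np.ndarray,
              df: int) -> np.ndarray:
    """Closed-form lesion-coefficient t from residualised cross-products.

    num = e_L . e_y, den = e_L . e_L, yy = e_y . e_y, per voxel.  Sign is
    flipped so positive t means damage lowers the score.  Returns NaN where
    the model is inestimable (den ~ 0 or zero residual variance).
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_scaled = den * yy - num**2
        t = -num * np.sqrt(df) / np.sqrt(rss_scaled)
    bad = (den <= 1e-10) | (rss_scaled <= 1e-12 * np.maximum(den * yy, 1e-300))
    t = np.where(bad, np.nan, t)
    return t


def _design(cohort: LesionCohort, measure: str,
            covariate_names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Response vector (change score) and covariate block Z = [1, C]."""
    tbl = cohort.table()
    y = tbl[f"{measure}_change"].to_numpy(dtype=float)
    cols = [np.ones(len(tbl))]
    for name in covariate_names:
        col = f"{measure}_baseline" if name == "baseline" else name
        cols.append(tbl[col].to_numpy(dtype=float))
    Z = np.column_stack(cols)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("covariate design is rank deficient")
    return y, Z


def voxel_t(scores: np.ndarray, lesion_status: np.ndarray,
            covariates: np.ndarray | None = None) -> tuple[float, int]:
    """t statistic of the lesion indicator at a single voxel.

    Fits score = b0 + bL*lesion + C @ bc + e by least squares and returns
    (t, df) with t = -bL/SE(bL), so positive t means lesioned subjects have
    lower adjusted scores.  With no covariates this equals (minus) the
    pooled-variance two-sample t.  Rank deficiency or zero residual
    variance yields t = NaN (inestimable).
    """
    y = np.asarray(scores, dtype=float)
    L = np.asarray(lesion_status, dtype=float).reshape(-1, 1)
    n = len(y)
    if L.sum() < 2 or (n - L.sum()) < 2:
        raise ValueError("need at least two subjects in each lesion group")
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        Z = np.column_stack([np.ones(n), C])
    df = n - Z.shape[1] - 1
    coef, *_ = np.linalg.lstsq(Z, np.column_stack([y, L]), rcond=None)
    resid = np.column_stack([y, L]) - Z @ coef
    e_y, e_L = resid[:, 0], resid[:, 1]
    t = _t_kernel(e_L @ e_y, e_L @ e_L, e_y @ e_y, df)
    return float(t), df


def _lesion_matrix(cohort: LesionCohort, search: np.ndarray) -> np.ndarray:
    """(n_subjects, n_search_voxels) float lesion-status matrix."""
    stacked = cohort.stacked_masks()
    return stacked.reshape(len(cohort), -1)[:, search.ravel()].astype(float)


def _tmap_values(L: np.ndarray, y: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, int]:
    """Observed t at each column of L (vectorised over voxels)."""
    n, p = Z.shape
    df = n - p - 1
    G = np.linalg.inv(Z.T @ Z)
    e_y = y - Z @ (G @ (Z.T @ y))
    yy = float(e_y @ e_y)
    A = Z.T @ L                              # (p, V)
    den = L.sum(axis=0) - np.einsum("pv,pq,qv->v", A, G, A)
    num = L.T @ e_y
    return _t_kernel(num, den, yy, df), df


def compute_tmap(cohort: LesionCohort, measure: str, config: VlsmConfig) -> TMap:
    """Covariate-adjusted voxelwise t over the search volume.

    Ordinal FAC/MRMI change scores enter as numeric responses here, as in
    the mass-univariate VLSM framework; inestimable voxels are removed from
    the search volume with a log entry.
    """
    search_grid, _ = build_search_volume(cohort, config.min_lesioned)
    search = search_grid.data.astype(bool)
    grid = cohort.grid
    tvol = np.full(grid.shape, np.nan)
    if not search.any():
        return TMap(t=grid.with_data(tvol), df=0, search=grid.with_data(search))
    y, Z = _design(cohort, measure, config.covariate_names)
    L = _lesion_matrix(cohort, search)
    tvals, df = _tmap_values(L, y, Z)
    bad = ~np.isfinite(tvals)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("%d inestimable voxels removed from the search volume", n_bad)
        idx = np.flatnonzero(search.ravel())[bad]
        search_flat = search.ravel().copy()
        search_flat[idx] = False
        search = search_flat.reshape(search.shape)
        tvals = tvals[~bad]
    tvol.ravel()[np.flatnonzero(search.ravel())] = tvals
    return TMap(t=grid.with_data(tvol), df=df,
                search=grid.with_data(search), n_inestimable=n_bad)


# ---------------------------------------------------------------------------
# clusters


def t_threshold(config: VlsmConfig, df: int) -> float:
    """Cluster-forming t cutoff from the uncorrected p threshold."""
    if config.direction == "two_sided":
        return float(stats.t.ppf(1 - config.p_uncorrected / 2, df))
    return float(stats.t.ppf(1 - config.p_uncorrected, df))


def form_clusters(tmap: TMap, config: VlsmConfig) -> list[ClusterResult]:
    """Connected supra-threshold components of the t map.

    Thresholds one-sidedly in the damage direction (or on |t| when
    two-sided), labels components at the configured neighbourhood, and
    reports each with size, peak t and (unweighted) centre of mass.
    """
    if tmap.df <= 0:
        return []
    thr = t_threshold(config, tmap.df)
    tdata = tmap.t.data
    with np.errstate(invalid="ignore"):
        if config.direction == "two_sided":
            supra = np.abs(tdata) >= thr
        else:
            supra = tdata >= thr
    supra &= tmap.search.data.astype(bool)
    if not supra.any():
        return []
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[config.connectivity])
    labels, n_comp = ndimage.label(supra, structure=structure)
    grid = tmap.t
    clusters: list[ClusterResult] = []
    for comp in range(1, n_comp + 1):
        vox = np.argwhere(labels == comp)
        vals = tdata[vox[:, 0], vox[:, 1], vox[:, 2]]
        mag = np.abs(vals) if config.direction == "two_sided" else vals
        peak_idx = int(np.argmax(mag))
        com_vox = vox.mean(axis=0)
        clusters.append(ClusterResult(
            voxels=vox,
            size_voxels=len(vox),
            size_ml=voxels_to_ml(len(vox), grid),
            peak_t=float(vals[peak_idx]),
            peak_coord_vox=vox[peak_idx],
            peak_coord_mm=grid.voxels_to_mm(vox[peak_idx])[0],
            centre_of_mass_vox=com_vox,
            centre_of_mass_mm=grid.voxels_to_mm(com_vox)[0],
        ))
    clusters.sort(key=lambda c: -abs(c.peak_t))
    return clusters


# ---------------------------------------------------------------------------
# permutation correction


def _perm_max_stats(L: np.ndarray, y: np.ndarray, Z: np.ndarray,
                    config: VlsmConfig, rng: np.random.Generator,
                    batch: int = 100) -> np.ndarray:
    """Max t over the search volume for each permutation.

    Default scheme: behavioural rows (score and covariates together) are
    reshuffled against the fixed lesion masks.  Because a joint row
    permutation leaves Z'Z and the residual norm unchanged, each
    permutation costs two matrix products.  The Freedman-Lane variant
    permutes reduced-model residuals instead, keeping covariates attached
    to their masks.
    """
    n, p = Z.shape
    df = n - p - 1
    G = np.linalg.inv(Z.T @ Z)
    e_y = y - Z @ (G @ (Z.T @ y))
    yy = float(e_y @ e_y)
    colsum = L.sum(axis=0)
    B = config.n_permutations
    out = np.empty(B)
    two_sided = config.direction == "two_sided"

    if config.freedman_lane:
        A0 = Z.T @ L
        den = colsum - np.einsum("pv,pq,qv->v", A0, G, A0)
        AG = G @ A0                                       # (p, V)
    for start in range(0, B, batch):
        b = min(batch, B - start)
        perms = np.stack([rng.permutation(n) for _ in range(b)])
        if config.freedman_lane:
            E = e_y[perms].T                              # (n, b) permuted residuals
            ZE = Z.T @ E                                  # (p, b)
            num = L.T @ E - A0.T @ (G @ ZE)               # (V, b)
            yy_b = (E**2).sum(axis=0) - np.einsum("pb,pq,qb->b", ZE, G, ZE)
            tb = _t_kernel(num, den[:, None], yy_b[None, :], df)
        else:
            E = e_y[perms].T                              # (n, b)
            num = L.T @ E                                 # (V, b)
            Zb = Z[perms]                                 # (b, n, p)
            A = np.einsum("bnp,nv->bpv", Zb, L)
            den_b = colsum[None, :] - np.einsum("bpv,pq,bqv->bv", A, G, A)
            tb = _t_kernel(num, den_b.T, yy, df)
        with np.errstate(invalid="ignore"):
            stat = np.abs(tb) if two_sided else tb
        out[start:start + b] = np.nanmax(stat, axis=0)
    return out


def permutation_correct(cohort: LesionCohort, measure: str, config: VlsmConfig,
                        clusters: list[ClusterResult],
                        tmap: TMap | None = None) -> tuple[list[ClusterResult], np.ndarray]:
    """Max-statistic FWE correction of candidate cluster peaks.

    For each of B permutations the behavioural rows are reshuffled against
    the masks, the t map recomputed on the fixed search volume, and its
    maximum recorded.  A cluster with observed peak t* gets
    p = (1 + #{perm max >= t*}) / (B + 1), significant when p < alpha.
    Returns the annotated clusters and the permutation max-t sample.
    """
    if tmap is None:
        tmap = compute_tmap(cohort, measure, config)
    y, Z = _design(cohort, measure, config.covariate_names)
    L = _lesion_matrix(cohort, tmap.search.data.astype(bool))
    rng = np.random.default_rng(config.seed)
    max_t = _perm_max_stats(L, y, Z, config, rng)
    B = len(max_t)
    for c in clusters:
        peak = abs(c.peak_t) if config.direction == "two_sided" else c.peak_t
        c.p_corrected = (1 + int(np.sum(max_t >= peak))) / (B + 1)
        c.significant = c.p_corrected < config.alpha_corrected
    return clusters, max_t


# ---------------------------------------------------------------------------
# orchestration


def run_vlsm(cohort: LesionCohort, measure: str, config: VlsmConfig) -> VlsmReport:
    """Full VLSM for one measure: search volume, t map, clusters,
    permutation correction.  Identical seed and inputs reproduce the
    report exactly."""
    search, counts = build_search_volume(cohort, config.min_lesioned)
    log: list[str] = list(cohort.exclusions)
    if not search.data.any():
        log.append("empty search volume: no voxel lesioned in enough subjects")
        return VlsmReport(measure=measure, config=config, overlap_count=counts,
                          tmap=None, clusters=[], t_threshold=None,
                          perm_max_t=None, log=log)
    tmap = compute_tmap(cohort, measure, config)
    if tmap.n_inestimable:
        log.append(f"{tmap.n_inestimable} inestimable voxels removed")
    clusters = form_clusters(tmap, config)
    perm_max = None
    if clusters:
        clusters, perm_max = permutation_correct(cohort, measure, config,
                                                 clusters, tmap=tmap)
    return VlsmReport(
        measure=measure, config=config, overlap_count=counts, tmap=tmap,
        clusters=clusters, t_threshold=t_threshold(config, tmap.df),
        perm_max_t=perm_max, log=log,
    )


def loo_stability(cohort: LesionCohort, measure: str, config: VlsmConfig,
                  tolerance_mm: float = 1.4,
                  reference: VlsmReport | None = None) -> pd.DataFrame:
    """Leave-one-out stability of the main cluster's centre of mass.

    Reruns the analysis dropping one subject at a time and reports, per
    fold, the displacement of the significant cluster nearest (by centre
    of mass) to the whole-group cluster.  Folds with no significant
    cluster are reported with NaN displacement, not zero.
    """
    if reference is None:
        reference = run_vlsm(cohort, measure, config)
    ref_sig = reference.significant_clusters
    if not ref_sig:
        raise ValueError("no significant whole-group cluster to track")
    ref_com = ref_sig[0].centre_of_mass_mm
    rows = []
    for i in range(len(cohort)):
        sub = cohort.subset([j for j in range(len(cohort)) if j != i])
        rep = run_vlsm(sub, measure, config)
        sig = rep.significant_clusters
        if sig:
            coms = np.stack([c.centre_of_mass_mm for c in sig])
            disp = float(np.linalg.norm(coms - ref_com, axis=1).min())
        else:
            disp = np.nan
        rows.append({"fold": i, "dropped": cohort.records[i].subject_id,
                     "displacement_mm": disp,
                     "within_tolerance": bool(disp <= tolerance_mm) if np.isfinite(disp) else False})
    return pd.DataFrame(rows)


def sensitivity_configs(config: VlsmConfig) -> dict[str, VlsmConfig]:
    """The standard sensitivity reruns: stricter overlap threshold and
    stricter cluster-forming p, singly and combined."""
    return {
        "min_lesioned_10": replace(config, min_lesioned=10),
        "p_unc_0.001": replace(config, p_uncorrected=0.001),
        "min10_p0.001": replace(config, min_lesioned=10, p_uncorrected=0.001),
    }
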