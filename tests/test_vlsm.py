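"""VLSM engine: search volume, voxelwise GLM, clustering, permutation."""
import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats as sps

import lesionmap as lm
from lesionmap.vlsm import _design

from conftest import mask_grid


def normal_equations_t(y, lesion, covariates):
    """Independent full-rank least-squares oracle for the lesion t."""
    n = len(y)
    X = np.column_stack([np.ones(n), lesion] +
                        ([covariates] if covariates is not None else []))
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    return -beta[1] / se, df


def tiny_cohort(lesion_columns, scores, covars=None, voxel_mm=2.0):
    """Cohort on a small grid with prescribed per-voxel lesion patterns.

    ``lesion_columns``: (n_subjects, nx, ny, nz) binary array.
    """
    lesions = np.asarray(lesion_columns, dtype=np.uint8)
    n = lesions.shape[0]
    covars = covars if covars is not None else {}
    base = float(max(0.0, -np.min(scores))) + 1.0
    masks, records = [], []
    for i in range(n):
        masks.append(mask_grid(lesions[i], voxel_mm))
        # walk change is outcome - baseline, so the score rides on outcome
        records.append(lm.SubjectRecord(
            subject_id=f"s{i}", side="left",
            baseline={"walk": base, "fac": 0, "mrmi": 0},
            outcome={"walk": base + float(scores[i]), "fac": 0, "mrmi": 0},
            age=float(covars.get("age", np.zeros(n))[i] + 60),
            fazekas=int(covars.get("fazekas", np.zeros(n))[i]),
            time_days=float(covars.get("time_days", np.zeros(n))[i] + 10),
        ))
    return lm.LesionCohort(masks=masks, records=records)


class TestSearchVolume:
    def test_threshold_and_comparison_group(self):
        # voxel A lesioned in 5/10 subjects, voxel B in 6/10, voxel C in all
        lesions = np.zeros((10, 3, 1, 1), dtype=np.uint8)
        lesions[:5, 0] = 1
        lesions[:6, 1] = 1
        lesions[:, 2] = 1
        cohort = tiny_cohort(lesions, np.arange(10.0))
        search, counts = lm.build_search_volume(cohort, min_lesioned=6)
        assert not search.data[0, 0, 0]      # below threshold
        assert search.data[1, 0, 0]
        assert not search.data[2, 0, 0]      # no comparison group
        np.testing.assert_array_equal(counts.data.ravel(), [5, 6, 10])

    def test_counts_match_brute_force(self, effect_cohort):
        cohort, _ = effect_cohort
        _, counts = lm.build_search_volume(cohort, 6)
        brute = np.zeros(cohort.grid.shape, dtype=int)
        for m in cohort.masks:
            brute += m.data
        np.testing.assert_array_equal(counts.data, brute)

    def test_empty_search_volume_is_explicit_empty_report(self):
        lesions = np.zeros((8, 2, 2, 2), dtype=np.uint8)
        lesions[0, 0, 0, 0] = 1   # max count 1 < min_lesioned
        cohort = tiny_cohort(lesions, np.arange(8.0))
        report = lm.run_vlsm(cohort, "walk",
                             lm.VlsmConfig(min_lesioned=2, n_permutations=100,
                                           covariate_names=()))
        assert report.clusters == []
        assert report.tmap is None

    def test_removing_subject_never_raises_counts(self, effect_cohort):
        cohort, _ = effect_cohort
        _, full = lm.build_search_volume(cohort, 6)
        sub = cohort.subset(range(len(cohort) - 1))
        _, reduced = lm.build_search_volume(sub, 6)
        assert (reduced.data <= full.data).all()


class TestVoxelT:
    def test_equal_group_means_give_zero_t(self):
        scores = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        lesion = np.array([1, 1, 1, 0, 0, 0])
        t, df = lm.voxel_t(scores, lesion)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert df == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_no_covariates_equals_pooled_two_sample_t(self, seed):
        rng = np.random.default_rng(seed)
        lesion = np.array([1] * 6 + [0] * 8)
        scores = rng.normal(size=14)
        t, df = lm.voxel_t(scores, lesion)
        ref = sps.ttest_ind(scores[lesion == 0], scores[lesion == 1],
                            equal_var=True)
        # positive t == lesioned group scores lower
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert df == 12

    @pytest.mark.parametrize("seed", range(5))
    def test_with_covariates_matches_normal_equations(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 25
        lesion = (rng.random(n) < 0.4).astype(float)
        lesion[:2], lesion[-2:] = 1, 0
        C = rng.normal(size=(n, 3))
        y = rng.normal(size=n) + C @ [0.5, -1.0, 0.2]
        t, df = lm.voxel_t(y, lesion, C)
        t_ref, df_ref = normal_equations_t(y, lesion, C)
        assert t == pytest.approx(t_ref, abs=1e-8)
        assert df == df_ref

    def test_inestimable_flagged_as_nan(self):
        # lesion identical to a covariate: rank-deficient full design
        lesion = np.array([1.0, 1, 0, 0, 1, 0])
        t, _ = lm.voxel_t(np.arange(6.0), lesion, lesion.reshape(-1, 1))
        assert np.isnan(t)

    def test_group_size_precondition(self):
        with pytest.raises(ValueError):
            lm.voxel_t(np.arange(5.0), np.array([1, 0, 0, 0, 0]))


class TestComputeTmap:
    def test_matches_per_voxel_fit(self, effect_cohort):
        cohort, _ = effect_cohort
        config = lm.VlsmConfig()
        tmap = lm.compute_tmap(cohort, "walk", config)
        y, Z = _design(cohort, "walk", config.covariate_names)
        C = Z[:, 1:]
        stacked = cohort.stacked_masks()
        vox = np.argwhere(tmap.search.data)[::29]  # spot-check a spread
        for i, j, k in vox:
            lesion = stacked[:, i, j, k].astype(float)
            t_ref, df_ref = normal_equations_t(y, lesion, C)
            assert tmap.t.data[i, j, k] == pytest.approx(t_ref, abs=1e-8)
            assert tmap.df == df_ref

    def test_subject_order_invariance(self, effect_cohort):
        cohort, _ = effect_cohort
        config = lm.VlsmConfig()
        tmap = lm.compute_tmap(cohort, "walk", config)
        perm = np.random.default_rng(0).permutation(len(cohort))
        shuffled = cohort.subset(perm)
        tmap2 = lm.compute_tmap(shuffled, "walk", config)
        np.testing.assert_allclose(tmap.t.data, tmap2.t.data, equal_nan=True,
                                   atol=1e-10)

    def test_max_t_lands_in_effect_region(self, effect_cohort, default_config):
        cohort, truth = effect_cohort
        tmap = lm.compute_tmap(cohort, "walk", lm.VlsmConfig())
        flat = np.nanargmax(np.where(tmap.search.data, tmap.t.data, -np.inf))
        peak = np.array(np.unravel_index(flat, tmap.t.shape))
        assert default_config.effect_mask()[tuple(peak)]


class TestFormClusters:
    def _tmap_from_array(self, t, df=30):
        grid = mask_grid(np.zeros(t.shape))
        return lm.TMap(t=grid.with_data(t.astype(float)), df=df,
                       search=grid.with_data(np.ones(t.shape, dtype=bool)))

    def test_no_suprathreshold_voxels_gives_empty_list(self):
        t = np.zeros((4, 4, 4))
        assert lm.form_clusters(self._tmap_from_array(t), lm.VlsmConfig()) == []

    def test_corner_touching_voxels_connectivity(self):
        t = np.zeros((4, 4, 4))
        t[0, 0, 0] = t[1, 1, 1] = 10.0
        tmap = self._tmap_from_array(t)
        c26 = lm.form_clusters(tmap, lm.VlsmConfig(connectivity=26))
        c6 = lm.form_clusters(tmap, lm.VlsmConfig(connectivity=6))
        assert len(c26) == 1 and len(c6) == 2

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(4)
        t = rng.normal(loc=1.5, size=(6, 6, 6))
        config = lm.VlsmConfig(connectivity=6)
        tmap = self._tmap_from_array(t)
        clusters = lm.form_clusters(tmap, config)
        thr = lm.vlsm.t_threshold(config, tmap.df)
        supra = t >= thr
        seen = np.zeros_like(supra, dtype=bool)
        comps = []
        for start in map(tuple, np.argwhere(supra)):
            if seen[start]:
                continue
            stack, comp = [start], set()
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.add(v)
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                          (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    w = tuple(np.add(v, d))
                    if all(0 <= w[i] < 6 for i in range(3)) and supra[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
            comps.append(comp)
        assert sorted(len(c) for c in comps) == sorted(c.size_voxels for c in clusters)
        oracle_sets = {frozenset(c) for c in comps}
        ours = {frozenset(map(tuple, c.voxels)) for c in clusters}
        assert ours == oracle_sets

    def test_centre_of_mass_is_unweighted_mean(self):
        t = np.zeros((5, 5, 5))
        t[1, 1, 1] = 5.0
        t[2, 1, 1] = 9.0
        clusters = lm.form_clusters(self._tmap_from_array(t), lm.VlsmConfig())
        com = clusters[0].centre_of_mass_vox
        np.testing.assert_allclose(com, [1.5, 1, 1])
        np.testing.assert_allclose(clusters[0].peak_coord_vox, [2, 1, 1])


class TestPermutationCorrect:
    def test_floor_of_corrected_p(self):
        """An observed peak exceeding every permutation max gets
        p = 1/(B+1)."""
        rng = np.random.default_rng(0)
        lesions = np.zeros((12, 1, 1, 1), dtype=np.uint8)
        lesions[:6, 0, 0, 0] = 1
        scores = np.where(np.arange(12) < 6, -10.0, 10.0) + rng.normal(size=12) * .01
        cohort = tiny_cohort(lesions, scores)
        config = lm.VlsmConfig(min_lesioned=2, n_permutations=500,
                               covariate_names=(), seed=5)
        report = lm.run_vlsm(cohort, "walk", config)
        assert len(report.clusters) == 1
        # only 924 group assignments exist; the observed split is the most
        # extreme, so permutation maxima rarely reach it but can tie
        assert report.clusters[0].p_corrected >= 1 / 501
        assert report.clusters[0].p_corrected < 0.05

    def test_matches_exhaustive_enumeration_single_voxel(self):
        """n = 6 single-voxel cohort: corrected p within Monte-Carlo error
        of the exact value over all 720 assignment permutations."""
        lesions = np.zeros((6, 1, 1, 1), dtype=np.uint8)
        lesions[:3, 0, 0, 0] = 1
        scores = np.array([0.1, 0.4, 0.9, 1.1, 1.7, 2.3])
        cohort = tiny_cohort(lesions, scores)
        config = lm.VlsmConfig(min_lesioned=2, n_permutations=2000,
                               p_uncorrected=0.4, covariate_names=(), seed=2)
        report = lm.run_vlsm(cohort, "walk", config)
        assert len(report.clusters) == 1
        observed = report.clusters[0].peak_t

        lesion = lesions[:, 0, 0, 0].astype(float)
        count = 0
        for perm in itertools.permutations(range(6)):
            t, _ = lm.voxel_t(scores[list(perm)], lesion)
            if t >= observed - 1e-12:
                count += 1
        exact = count / 720
        mc = report.clusters[0].p_corrected
        se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(mc - exact) <= 3 * se + 1 / 2001

    def test_corrected_p_monotone_in_peak_and_bounded(self, effect_cohort):
        cohort, _ = effect_cohort
        config = lm.VlsmConfig(n_permutations=300, p_uncorrected=0.2,
                               connectivity=6, seed=8)
        report = lm.run_vlsm(cohort, "walk", config)
        assert len(report.clusters) >= 2
        peaks = [c.peak_t for c in report.clusters]
        ps = [c.p_corrected for c in report.clusters]
        order = np.argsort(peaks)[::-1]
        assert all(ps[order[i]] <= ps[order[i + 1]] + 1e-12
                   for i in range(len(order) - 1))
        assert all(1 / 301 <= p <= 1 for p in ps)


class TestRunVlsm:
    def test_seed_determinism(self, effect_cohort):
        cohort, _ = effect_cohort
        config = lm.VlsmConfig(n_permutations=200, seed=13)
        a = lm.run_vlsm(cohort, "walk", config)
        b = lm.run_vlsm(cohort, "walk", config)
        assert a.clusters_frame().equals(b.clusters_frame())
        np.testing.assert_array_equal(a.perm_max_t, b.perm_max_t)

    def test_recovers_implanted_region(self, effect_cohort, default_config):
        cohort, truth = effect_cohort
        report = lm.run_vlsm(cohort, "walk",
                             lm.VlsmConfig(n_permutations=500, seed=3))
        sig = report.significant_clusters
        assert len(sig) >= 1
        com_err = np.linalg.norm(sig[0].centre_of_mass_vox
                                 - truth.effect_centre_vox)
        assert com_err <= 2.0

    def test_freedman_lane_variant_also_recovers(self, effect_cohort):
        cohort, _ = effect_cohort
        report = lm.run_vlsm(cohort, "walk",
                             lm.VlsmConfig(n_permutations=300, seed=3,
                                           freedman_lane=True))
        assert len(report.significant_clusters) >= 1

    def test_shrinking_search_volume_only_removes_clusters(self, effect_cohort):
        cohort, _ = effect_cohort
        t6 = lm.compute_tmap(cohort, "walk", lm.VlsmConfig(min_lesioned=6))
        t10 = lm.compute_tmap(cohort, "walk", lm.VlsmConfig(min_lesioned=10))
        assert (t10.search.data <= t6.search.data).all()
        c6 = lm.form_clusters(t6, lm.VlsmConfig(min_lesioned=6))
        c10 = lm.form_clusters(t10, lm.VlsmConfig(min_lesioned=10))
        vox6 = set().union(*[set(map(tuple, c.voxels)) for c in c6]) if c6 else set()
        vox10 = set().union(*[set(map(tuple, c.voxels)) for c in c10]) if c10 else set()
        assert vox10 <= vox6


class TestLooStability:
    def test_duplicate_subject_and_fold_count(self):
        cfg = lm.SimulationConfig(n_subjects=16, seed=6, noise_sd=0.02)
        cohort, _ = lm.make_cohort(cfg)
        # duplicate subject 0 so dropping one copy changes nothing
        dup = lm.LesionCohort(
            masks=cohort.masks + [cohort.masks[0]],
            records=cohort.records + [dataclasses.replace(
                cohort.records[0], subject_id="sub-dup")])
        config = lm.VlsmConfig(min_lesioned=4, n_permutations=200, seed=1)
        ref = lm.run_vlsm(dup, "walk", config)
        if not ref.significant_clusters:
            pytest.skip("no significant cluster on this tiny fixture")
        folds = lm.loo_stability(dup, "walk", config, reference=ref)
        assert len(folds) == len(dup)
        d0 = folds.loc[folds["dropped"] == "sub-000", "displacement_mm"]
        ddup = folds.loc[folds["dropped"] == "sub-dup", "displacement_mm"]
        assert np.allclose(d0.values, ddup.values, equal_nan=True)

    def test_requires_significant_reference(self, effect_cohort):
        cohort, _ = effect_cohort
        config = lm.VlsmConfig(n_permutations=200, seed=1)
        empty = lm.VlsmReport(measure="walk", config=config,
                              overlap_count=cohort.grid, tmap=None,
                              clusters=[], t_threshold=None, perm_max_t=None)
        with pytest.raises(ValueError):
            lm.loo_stability(cohort, "walk", config, reference=empty)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(p_uncorrected=0.0), dict(n_permutations=50),
        dict(connectivity=7), dict(direction="sideways"),
        dict(min_lesioned=1)])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            lm.VlsmConfig(**kwargs)
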