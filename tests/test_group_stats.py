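import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gfcpipe import (
    StatMap,
    apply_fdr,
    bh_adjusted_p,
    build_design,
    fdr_bh,
    fit_voxel_ancova,
    label_clusters,
    posthoc_t,
    voxel_to_world,
)
from gfcpipe.group_stats import DesignError

from conftest import random_gfc_stack


def make_table(n_per_group, rng, groups=("S1", "S0", "HC")):
    rows = []
    for g, n in zip(groups, n_per_group):
        for _ in range(n):
            rows.append({
                "group": g,
                "age": rng.integers(18, 55),
                "gender": rng.integers(0, 2),
                "education_years": rng.integers(6, 20),
                "mean_fd": rng.uniform(0.02, 0.3),
            })
    return pd.DataFrame(rows)


class TestDesign:
    def test_columns_and_rank(self, rng):
        table = make_table((6, 6, 6), rng)
        design = build_design(table)
        assert design.matrix.shape == (18, 7)
        assert design.labels[0] == "intercept"
        assert len(design.group_cols) == 2

    def test_covariate_centering_does_not_change_f(self, rng):
        table = make_table((8, 8, 8), rng)
        maps, mask3d = random_gfc_stack(rng, 24)
        centered = build_design(table)
        raw_cols = centered.matrix.copy()
        for j, lab in enumerate(centered.labels):
            if lab not in ("intercept",) and not lab.startswith("group"):
                raw_cols[:, j] += 11.0  # undo centering by an arbitrary shift
        from gfcpipe.group_stats import DesignMatrix

        shifted = DesignMatrix(raw_cols, centered.labels, centered.group_cols)
        f1 = fit_voxel_ancova(maps, centered, mask3d)
        f2 = fit_voxel_ancova(maps, shifted, mask3d)
        np.testing.assert_allclose(f1.stat, f2.stat, atol=1e-8)

    def test_rank_deficiency_is_an_error(self, rng):
        table = make_table((5, 5, 5), rng)
        table["age"] = 30  # constant covariate duplicates the intercept
        with pytest.raises(DesignError):
            build_design(table)


class TestVoxelAncova:
    def test_matches_oneway_anova_without_covariates(self, rng):
        table = make_table((7, 5, 6), rng)
        maps, mask3d = random_gfc_stack(rng, 18)
        design = build_design(table, covariates=())
        fmap = fit_voxel_ancova(maps, design, mask3d)
        y = np.stack([m.values[mask3d] for m in maps])
        labels = table["group"].to_numpy()
        for v in range(y.shape[1]):
            f_ref, p_ref = stats.f_oneway(*(y[labels == g, v] for g in ("S1", "S0", "HC")))
            assert fmap.stat[v] == pytest.approx(f_ref, abs=1e-8)
            assert fmap.p[v] == pytest.approx(p_ref, abs=1e-8)

    def test_null_rejection_rate_calibrated(self, rng):
        # iid normal maps, random covariates: per-voxel p should be uniform
        table = make_table((10, 10, 10), rng)
        maps, mask3d = random_gfc_stack(rng, 30, mask_shape=(10, 10, 10), n_mask=800)
        design = build_design(table)
        fmap = fit_voxel_ancova(maps, design, mask3d)
        rate = (fmap.p < 0.05).mean()
        # binomial 99% band around 0.05 at m = 800
        band = 2.58 * np.sqrt(0.05 * 0.95 / 800)
        assert abs(rate - 0.05) < band + 1e-12

    def test_identical_maps_flagged_not_significant(self, rng):
        table = make_table((5, 5, 5), rng)
        maps, mask3d = random_gfc_stack(rng, 15)
        for m in maps[1:]:
            m.values = maps[0].values.copy()
        design = build_design(table, covariates=())
        fmap = fit_voxel_ancova(maps, design, mask3d)
        assert np.isnan(fmap.stat).all()
        reject, _ = fdr_bh(fmap.p, 0.05)
        assert not reject.any()


class TestPosthocT:
    def test_reduces_to_pooled_t_without_covariates(self, rng):
        table = make_table((8, 9), rng, groups=("S1", "HC"))
        maps, mask3d = random_gfc_stack(rng, 17)
        design = build_design(table, covariates=(), reference_group="HC")
        tmap = posthoc_t(maps, design, mask3d)
        y = np.stack([m.values[mask3d] for m in maps])
        labels = table["group"].to_numpy()
        t_ref, p_ref = stats.ttest_ind(y[labels == "S1"], y[labels == "HC"])
        np.testing.assert_allclose(tmap.stat, t_ref, atol=1e-8)
        np.testing.assert_allclose(tmap.p, p_ref, atol=1e-8)

    def test_sign_flips_with_group_coding(self, rng):
        table = make_table((8, 9), rng, groups=("S1", "HC"))
        maps, mask3d = random_gfc_stack(rng, 17)
        d1 = build_design(table, covariates=("age",), reference_group="HC")
        d2 = build_design(table, covariates=("age",), reference_group="S1")
        t1 = posthoc_t(maps, d1, mask3d)
        t2 = posthoc_t(maps, d2, mask3d)
        np.testing.assert_allclose(t1.stat, -t2.stat, atol=1e-10)


class TestFdrBh:
    def test_hand_applied_step_up(self):
        reject, threshold = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()           # p_(4) = 0.04 <= 4 * 0.0125
        assert threshold == 0.04

    def test_all_ones_rejects_nothing(self):
        reject, threshold = fdr_bh(np.ones(10), q=0.05)
        assert not reject.any() and np.isnan(threshold)

    def test_single_test_reduces_to_alpha(self):
        reject, _ = fdr_bh(np.array([0.049]), q=0.05)
        assert reject.all()
        reject, _ = fdr_bh(np.array([0.051]), q=0.05)
        assert not reject.any()

    def test_monotone_in_q(self, rng):
        p = rng.random(200) ** 2
        r1, _ = fdr_bh(p, 0.01)
        r5, _ = fdr_bh(p, 0.05)
        assert (r5 | ~r1).all()  # rejections at 0.01 are a subset of those at 0.05

    def test_order_invariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        r, _ = fdr_bh(p, 0.05)
        r_perm, _ = fdr_bh(p[perm], 0.05)
        np.testing.assert_array_equal(r[perm], r_perm)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.random(100) ** 3
        reject, _ = fdr_bh(p, 0.05)
        adj = bh_adjusted_p(p)
        ref_reject, ref_adj, *_ = sm.multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, ref_reject)
        np.testing.assert_allclose(adj, ref_adj, atol=1e-12)

    def test_empty_input(self):
        reject, threshold = fdr_bh(np.array([]), 0.05)
        assert reject.size == 0 and np.isnan(threshold)


def stat_map_from_volume(vol, mask3d, affine=None, kind="t"):
    affine = np.eye(4) if affine is None else affine
    stat = vol[mask3d]
    p = np.full(stat.shape, 1.0)
    sm = StatMap(stat, p, 10.0, kind, mask3d, affine)
    sm.fdr_mask = ~np.isnan(stat) & (np.abs(stat) > 0)
    return sm


class TestClusters:
    def test_single_voxel_cluster(self):
        vol = np.zeros((4, 4, 4))
        mask3d = np.ones((4, 4, 4), bool)
        vol[1, 2, 3] = 5.0
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        sm = stat_map_from_volume(vol, mask3d, affine)
        clusters = label_clusters(sm)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.size == 1 and c.peak_voxel == (1, 2, 3)
        assert c.peak_mni == (3.0, 6.0, 9.0)
        assert c.peak_stat == 5.0

    def test_corner_touching_voxels_connectivity_semantics(self):
        vol = np.zeros((4, 4, 4))
        mask3d = np.ones((4, 4, 4), bool)
        vol[0, 0, 0] = vol[1, 1, 1] = 2.0  # share only a corner
        sm = stat_map_from_volume(vol, mask3d)
        assert len(label_clusters(sm, connectivity=26)) == 1
        sm = stat_map_from_volume(vol, mask3d)
        assert len(label_clusters(sm, connectivity=6)) == 2

    def test_affine_offset_maps_origin_voxel(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = (-90, -126, -72)
        assert voxel_to_world(affine, (0, 0, 0)) == (-90.0, -126.0, -72.0)

    def test_sign_split_and_peak_invariant(self, rng):
        vol = np.full((6, 6, 6), np.nan)
        mask3d = np.ones((6, 6, 6), bool)
        vol[:] = 0.0
        vol[1:3, 1:3, 1] = 3.0 + rng.random((2, 2))
        vol[1:3, 1:3, 2] = -(3.0 + rng.random((2, 2)))  # adjacent negative block
        sm = stat_map_from_volume(vol, mask3d)
        clusters = label_clusters(sm, connectivity=26)
        assert len(clusters) == 2
        assert {c.sign for c in clusters} == {1, -1}
        for c in clusters:
            member_vals = vol[tuple(c.voxels.T)]
            assert np.abs(member_vals).max() == pytest.approx(abs(c.peak_stat))
        # sorted by size descending
        sizes = [c.size for c in clusters]
        assert sizes == sorted(sizes, reverse=True)

    def test_min_extent_filters_small_clusters(self):
        vol = np.zeros((5, 5, 5))
        mask3d = np.ones((5, 5, 5), bool)
        vol[0, 0, 0] = 1.0                # singleton
        vol[2:4, 2:4, 2:4] = 1.0          # 8-voxel block
        sm = stat_map_from_volume(vol, mask3d)
        clusters = label_clusters(sm, min_extent=2)
        assert len(clusters) == 1 and clusters[0].size == 8

    def test_requires_fdr_first(self, rng):
        sm = StatMap(rng.normal(size=10), rng.random(10), 5.0, "t",
                     np.ones((10, 1, 1), bool), np.eye(4))
        with pytest.raises(DesignError):
            label_clusters(sm)


class TestApplyFdrOnMaps:
    def test_null_maps_rarely_survive(self, rng):
        maps, mask3d = random_gfc_stack(rng, 21, mask_shape=(8, 8, 8), n_mask=300)
        table = make_table((7, 7, 7), rng)
        design = build_design(table, covariates=())
        fmap = apply_fdr(fit_voxel_ancova(maps, design, mask3d), q=0.05)
        assert fmap.fdr_mask.sum() <= 0.05 * 300  # overwhelmingly empty under null
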