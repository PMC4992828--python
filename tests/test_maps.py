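"""PLS, cluster-mass permutation, and sphere-feature extraction."""

import numpy as np
import pytest
from scipy import ndimage, stats

from alphaconvert import maps, synthgen
from alphaconvert.exceptions import DesignError, LabelError
from alphaconvert.maps import Cluster, SourceStatMap


class TestTaskPLS:
    def test_svd_energy_identity(self, rng):
        X = rng.standard_normal((20, 30))
        groups = np.repeat(["a", "b", "c", "d"], 5)
        res = maps.task_pls(X, groups, n_perm=20, n_boot=0, seed=0)
        M = np.stack([X[groups == g].mean(axis=0) for g in res.group_order])
        M = M - M.mean(axis=0)
        assert np.sum(res.singular_values**2) == pytest.approx(np.sum(M**2), rel=1e-10)
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    def test_mirrored_groups_give_antisymmetric_design_saliences(self, rng):
        pattern = rng.standard_normal(40)
        X = np.vstack([
            pattern + 0.01 * rng.standard_normal((10, 40)),
            -pattern + 0.01 * rng.standard_normal((10, 40)),
        ])
        groups = np.repeat(["plus", "minus"], 10)
        res = maps.task_pls(X, groups, n_perm=20, n_boot=0, seed=0)
        u = res.design_saliences[:, 0]
        assert u[0] == pytest.approx(-u[1], rel=1e-6)

    def test_recovers_planted_rank1_pattern(self, rng):
        pattern = rng.standard_normal(60)
        X = rng.standard_normal((24, 60))
        groups = np.repeat(["a", "b"], 12)
        X[groups == "a"] += pattern
        res = maps.task_pls(X, groups, n_perm=50, n_boot=50, seed=0)
        r = np.corrcoef(res.element_saliences[:, 0], pattern)[0, 1]
        assert abs(r) > 0.9
        assert res.perm_p[0] < 0.05

    def test_null_first_lv_rarely_significant(self):
        # two groups from one distribution: LV1 p > 0.05 in >= 90% of replicates
        hits = 0
        n_rep = 30
        for k in range(n_rep):
            rng = np.random.default_rng(100 + k)
            X = rng.standard_normal((20, 15))
            groups = np.repeat(["a", "b"], 10)
            res = maps.task_pls(X, groups, n_perm=99, n_boot=0, seed=k)
            hits += res.perm_p[0] > 0.05
        assert hits >= 0.9 * n_rep

    def test_degenerate_inputs_raise(self, rng):
        with pytest.raises(DesignError):
            maps.task_pls(rng.standard_normal((4, 5)), np.array(["a"] * 4))


class TestBehaviorPLS:
    def test_perfect_element_dominates_saliences(self, rng):
        y = rng.standard_normal(25)
        X = rng.standard_normal((25, 8)) * 0.3
        X[:, 3] = y
        res = maps.behavior_pls(X, y, n_perm=30, n_boot=0, seed=0)
        v = np.abs(res.element_saliences[:, 0])
        assert np.argmax(v) == 3

    def test_uncorrelated_behavior_not_significant_mostly(self):
        hits = 0
        n_rep = 20
        for k in range(n_rep):
            rng = np.random.default_rng(200 + k)
            res = maps.behavior_pls(
                rng.standard_normal((22, 10)), rng.standard_normal(22), n_perm=99, seed=k
            )
            hits += res.perm_p[0] > 0.05
        assert hits >= 0.8 * n_rep


class TestClusterPermutation:
    def test_identical_groups_no_clusters(self):
        a = np.zeros((6, 5, 5, 5))
        b = np.zeros((6, 5, 5, 5))
        res = maps.cluster_permutation(a, b, n_perm=30, seed=0)
        assert res.clusters == []
        assert not res.sig_mask.any()

    def test_planted_difference_localizes(self, rng):
        shape = (8, 8, 8)
        a = rng.standard_normal((12,) + shape)
        b = rng.standard_normal((12,) + shape)
        a[:, 2:5, 2:5, 2:5] += 3.0
        res = maps.cluster_permutation(a, b, n_perm=99, seed=1)
        assert res.clusters
        best = res.clusters[0]
        assert best.p_cluster <= 0.05
        box = np.zeros(shape, bool)
        box[2:5, 2:5, 2:5] = True
        inside = box[tuple(best.voxels.T)].mean()
        assert inside > 0.5

    def test_cluster_mass_matches_enumeration(self, rng):
        a = rng.standard_normal((10, 6, 6, 6))
        b = rng.standard_normal((10, 6, 6, 6))
        a[:, 1:4, 1:4, 1:4] += 2.0
        res = maps.cluster_permutation(a, b, n_perm=20, seed=0)
        # brute-force: recompute the voxelwise t map and sum |t| over members
        t_oracle = np.empty((6, 6, 6))
        for i in np.ndindex(6, 6, 6):
            t_oracle[i] = stats.ttest_ind(a[(slice(None),) + i], b[(slice(None),) + i]).statistic
        for cl in res.clusters:
            mass = np.abs(t_oracle[tuple(cl.voxels.T)]).sum()
            assert cl.mass == pytest.approx(mass, rel=1e-8)
            # members all suprathreshold and face-connected
            assert (np.abs(res.t_values[tuple(cl.voxels.T)]) >= res.threshold).all()
            mask = np.zeros((6, 6, 6), bool)
            mask[tuple(cl.voxels.T)] = True
            _, n_comp = ndimage.label(mask, structure=maps.FACE_CONNECTIVITY)
            assert n_comp == 1

    def test_correlation_difference_mode_detects_group_specific_link(self, rng):
        shape = (6, 6, 6)
        na = nb = 16
        ya = rng.standard_normal(na)
        yb = rng.standard_normal(nb)
        a = rng.standard_normal((na,) + shape)
        b = rng.standard_normal((nb,) + shape)
        a[:, 1:4, 1:4, 1:4] += 2.0 * ya[:, None, None, None]  # link only in group a
        res = maps.cluster_permutation(
            a, b, behavior=(ya, yb), mode="correlation_difference", n_perm=99, seed=2
        )
        assert res.clusters and res.clusters[0].p_cluster <= 0.05

    def test_type_i_error_near_nominal(self):
        # under exchangeability the smallest p_cluster <= .05 in ~5% of null data
        rejections = 0
        n_rep = 60
        for k in range(n_rep):
            rng = np.random.default_rng(300 + k)
            a = rng.standard_normal((8, 5, 5, 5))
            b = rng.standard_normal((8, 5, 5, 5))
            res = maps.cluster_permutation(a, b, n_perm=79, seed=k)
            if res.clusters and res.clusters[0].p_cluster <= 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.15


def _stat_map(shape, tvals, sig, atlas):
    return SourceStatMap(
        t_values=tvals, threshold=2.0, sig_mask=sig, clusters=[], atlas=atlas
    )


class _ToyAtlas:
    def __init__(self, label_volume, names):
        self.label_volume = label_volume
        self.names = names


class TestSphereCluster:
    def test_isolated_voxel_becomes_its_own_feature(self):
        shape = (7, 7, 7)
        t = np.zeros(shape)
        sig = np.zeros(shape, bool)
        t[3, 3, 3] = 5.0
        sig[3, 3, 3] = True
        labels = np.ones(shape, np.int16)
        atlas = _ToyAtlas(labels, {1: "roi"})
        values = np.arange(2 * 7**3, dtype=float).reshape((2,) + shape)
        table, spheres = maps.sphere_cluster(_stat_map(shape, t, sig, atlas), values)
        assert len(spheres) == 1
        assert spheres[0].center == (3, 3, 3)
        assert len(spheres[0].members) == 1
        np.testing.assert_allclose(table["roi"].to_numpy(), values[:, 3, 3, 3])

    def test_two_maxima_one_region_average_of_sphere_means(self):
        shape = (7, 7, 7)
        t = np.zeros(shape)
        sig = np.zeros(shape, bool)
        t[1, 1, 1] = 5.0
        t[5, 5, 5] = 4.0
        sig[1, 1, 1] = sig[5, 5, 5] = True
        # one extra significant member near each center
        t[1, 1, 2] = 2.5
        sig[1, 1, 2] = True
        t[5, 5, 4] = 2.5
        sig[5, 5, 4] = True
        atlas = _ToyAtlas(np.ones(shape, np.int16), {1: "roi"})
        rng = np.random.default_rng(0)
        values = rng.standard_normal((3,) + shape)
        table, spheres = maps.sphere_cluster(_stat_map(shape, t, sig, atlas), values)
        assert len(spheres) == 2
        m1 = values[:, [1, 1], [1, 1], [1, 2]].mean(axis=1)
        m2 = values[:, [5, 5], [5, 5], [5, 4]].mean(axis=1)
        np.testing.assert_allclose(table["roi"].to_numpy(), (m1 + m2) / 2.0)

    def test_nonsignificant_voxel_inside_radius_excluded(self):
        shape = (7, 7, 7)
        t = np.full(shape, 3.0)  # suprathreshold everywhere, but only 2 significant
        sig = np.zeros(shape, bool)
        t[3, 3, 3] = 6.0
        sig[3, 3, 3] = True
        sig[3, 3, 4] = True
        atlas = _ToyAtlas(np.ones(shape, np.int16), {1: "roi"})
        values = np.random.default_rng(1).standard_normal((2,) + shape)
        table, spheres = maps.sphere_cluster(_stat_map(shape, t, sig, atlas), values)
        assert len(spheres) == 1
        assert len(spheres[0].members) == 2  # not the whole radius-3 ball

    def test_empty_mask_gives_empty_table(self):
        shape = (5, 5, 5)
        atlas = _ToyAtlas(np.ones(shape, np.int16), {1: "roi"})
        table, spheres = maps.sphere_cluster(
            _stat_map(shape, np.zeros(shape), np.zeros(shape, bool), atlas),
            np.zeros((2,) + shape),
        )
        assert spheres == []
        assert table.empty or table.shape[1] == 0

    def test_deterministic_and_members_within_radius(self, default_cohort):
        ms = default_cohort.maps[("alpha", "encoding")]
        stat = maps.cluster_permutation(
            ms, group_a="aMCI-s", group_b="aMCI-c", n_perm=60, seed=4
        )
        t1, s1 = maps.sphere_cluster(stat, ms)
        t2, s2 = maps.sphere_cluster(stat, ms)
        assert t1.equals(t2)
        for sp in s1:
            d = np.linalg.norm(sp.members - np.asarray(sp.center), axis=1)
            assert (d <= 3.0 + 1e-9).all()
            assert stat.sig_mask[tuple(np.asarray(sp.center))]


def test_group_difference_tmap_peaks_in_planted_region(default_cohort):
    """The s-vs-c alpha encoding t-map maximum falls inside the PCC parcels."""
    ms = default_cohort.maps[("alpha", "encoding")]
    stat = maps.cluster_permutation(ms, group_a="aMCI-s", group_b="aMCI-c", n_perm=30, seed=9)
    peak = np.unravel_index(np.argmax(np.abs(stat.t_values)), stat.t_values.shape)
    region = ms.atlas.names[int(ms.atlas.label_volume[peak])]
    assert region in {"l_pcc", "r_pcc", "l_inferior_parietal"}
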