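"""Pose RMSD, complete-linkage clustering and the hierarchical screen."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opsinscreen.consensus import (PoseSet, complete_linkage_cluster,
                                   consensus_of, hierarchical_screen,
                                   pose_rmsd, rmsd_matrix)
from opsinscreen.synthdata import (TEMPLATE_BONDS, TEMPLATE_COORDS,
                                   TEMPLATE_SYMBOLS, template_pose)

from conftest import benzene_coords, benzene_pose
from _oracles import (benzene_ring_permutations, naive_symmetric_rmsd,
                      partition_to_sets, scipy_complete_linkage)


class TestPoseRmsd:
    def test_identical_coordinates_give_zero(self):
        a = template_pose("L", "m1")
        b = template_pose("L", "m2")
        assert pose_rmsd(a, b) == 0.0

    def test_uniform_translation_gives_shift_norm(self):
        a = template_pose("L", "m1")
        b = template_pose("L", "m2", TEMPLATE_COORDS + np.array([2.0, 0, 0]))
        assert pose_rmsd(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(0)
        a = template_pose("L", "m1", TEMPLATE_COORDS + rng.normal(0, 1, (9, 3)))
        b = template_pose("L", "m2", TEMPLATE_COORDS + rng.normal(0, 1, (9, 3)))
        assert pose_rmsd(a, b) == pytest.approx(pose_rmsd(b, a), abs=1e-12)

    def test_mismatched_poses_are_rejected(self):
        a = template_pose("L", "m1")
        b = benzene_pose("m2", benzene_coords(), ligand_id="L")
        with pytest.raises(ValueError, match="not comparable"):
            pose_rmsd(a, b)

    def test_benzene_ring_relabeling_is_zero_only_with_symmetry(self):
        coords = benzene_coords()
        # 60-degree graph rotation: same geometry, shifted atom labels
        rotated = coords[[1, 2, 3, 4, 5, 0]]
        a = benzene_pose("m1", coords)
        b = benzene_pose("m2", rotated)
        assert pose_rmsd(a, b, symmetry=True) == pytest.approx(0.0, abs=1e-9)
        assert pose_rmsd(a, b, symmetry=False) > 1.0

    def test_benzene_rmsd_equals_explicit_permutation_minimum(self):
        rng = np.random.default_rng(5)
        perms = benzene_ring_permutations()
        for _ in range(20):
            ca = benzene_coords() + rng.normal(0, 0.5, (6, 3))
            cb = benzene_coords() + rng.normal(0, 0.5, (6, 3))
            got = pose_rmsd(benzene_pose("m1", ca), benzene_pose("m2", cb))
            want = naive_symmetric_rmsd(ca, cb, perms)
            assert got == pytest.approx(want, abs=1e-9)

    def test_symmetry_correction_never_increases_rmsd(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            ca = benzene_coords() + rng.normal(0, 2.0, (6, 3))
            cb = benzene_coords() + rng.normal(0, 2.0, (6, 3))
            a, b = benzene_pose("m1", ca), benzene_pose("m2", cb)
            assert pose_rmsd(a, b, symmetry=True) <= \
                pose_rmsd(a, b, symmetry=False) + 1e-12


class TestRmsdMatrix:
    def test_identical_poses_give_zero_matrix(self):
        ps = PoseSet("L", [template_pose("L", f"m{i}") for i in range(3)])
        assert np.allclose(rmsd_matrix(ps), 0.0)

    def test_translated_poses_give_translation_distances(self):
        shifts = [0.0, 3.0, 7.0]
        ps = PoseSet("L", [template_pose("L", f"m{i}",
                                         TEMPLATE_COORDS + np.array([s, 0, 0]))
                           for i, s in enumerate(shifts)])
        m = rmsd_matrix(ps)
        for i, j in itertools.combinations(range(3), 2):
            assert m[i, j] == pytest.approx(abs(shifts[i] - shifts[j]), abs=1e-9)

    def test_matrix_matches_per_pair_recomputation(self):
        rng = np.random.default_rng(23)
        poses = [template_pose("L", f"m{i}",
                               TEMPLATE_COORDS + rng.normal(0, 2, (9, 3)))
                 for i in range(5)]
        m = rmsd_matrix(PoseSet("L", poses))
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        for i, j in itertools.combinations(range(5), 2):
            d = poses[i].coords - poses[j].coords
            naive = np.sqrt(np.mean(np.sum(d * d, axis=1)))
            # template graph has no non-trivial automorphisms
            assert m[i, j] == pytest.approx(naive, abs=1e-12)

    def test_single_pose_is_rejected(self):
        with pytest.raises(ValueError):
            rmsd_matrix(PoseSet("L", [template_pose("L", "m1")]))


def _random_distance_matrix(rng, n):
    d = rng.uniform(0, 8, size=(n, n))
    d = np.triu(d, 1)
    return d + d.T


class TestCompleteLinkage:
    def test_two_well_separated_groups_give_two_clusters(self):
        m = np.zeros((5, 5))
        for i, j in itertools.combinations(range(5), 2):
            same = (i < 3) == (j < 3)
            m[i, j] = m[j, i] = 0.0 if same else 10.0
        parts = complete_linkage_cluster(m, threshold=2.0)
        assert partition_to_sets(parts) == {frozenset({0, 1, 2}),
                                            frozenset({3, 4})}

    def test_all_far_apart_gives_singletons(self):
        m = np.full((4, 4), 5.0)
        np.fill_diagonal(m, 0.0)
        parts = complete_linkage_cluster(m, threshold=2.0)
        assert parts == [[0], [1], [2], [3]]

    def test_every_cluster_diameter_is_below_threshold(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            m = _random_distance_matrix(rng, n)
            for cluster in complete_linkage_cluster(m, threshold=2.0):
                for i, j in itertools.combinations(cluster, 2):
                    assert m[i, j] < 2.0

    def test_agreement_with_scipy_reference(self):
        rng = np.random.default_rng(37)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            m = _random_distance_matrix(rng, n)
            got = partition_to_sets(complete_linkage_cluster(m, 2.0))
            want = scipy_complete_linkage(m, 2.0)
            assert got == want

    def test_partition_is_invariant_under_pose_order_permutation(self):
        rng = np.random.default_rng(41)
        n = 7
        m = _random_distance_matrix(rng, n)
        base = partition_to_sets(complete_linkage_cluster(m, 2.0))
        for _ in range(10):
            perm = rng.permutation(n)
            pm = m[np.ix_(perm, perm)]
            parts = complete_linkage_cluster(pm, 2.0)
            relabeled = {frozenset(int(perm[i]) for i in c) for c in parts}
            assert relabeled == base

    @given(st.integers(min_value=2, max_value=8), st.integers(0, 2**31 - 1),
           st.floats(min_value=0.5, max_value=6.0))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_cluster_diameters_stay_below_any_threshold(self, n, seed, thr):
        rng = np.random.default_rng(seed)
        m = _random_distance_matrix(rng, n)
        parts = complete_linkage_cluster(m, threshold=thr)
        assert sorted(i for c in parts for i in c) == list(range(n))
        for cluster in parts:
            for i, j in itertools.combinations(cluster, 2):
                assert m[i, j] < thr

    def test_invalid_matrices_are_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))
        m = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            complete_linkage_cluster(m)


class TestConsensus:
    def test_planted_four_of_six_gives_level_four(self):
        rng = np.random.default_rng(43)
        poses = [template_pose("L", f"m{i}",
                               TEMPLATE_COORDS + rng.normal(0, 0.2, (9, 3)))
                 for i in range(4)]
        poses.append(template_pose("L", "m4", TEMPLATE_COORDS + np.array([20.0, 0, 0])))
        poses.append(template_pose("L", "m5", TEMPLATE_COORDS + np.array([0, 20.0, 0])))
        res = consensus_of(PoseSet("L", poses), threshold=2.0)
        assert res.level == 4
        assert sorted(res.clusters, key=len)[-1] == [0, 1, 2, 3]

    def test_eleven_identical_poses_give_full_consensus_and_lowest_medoid(self):
        ps = PoseSet("L", [template_pose("L", f"m{i:02d}") for i in range(11)])
        res = consensus_of(ps, threshold=2.0)
        assert res.level == 11
        assert res.medoid_index == 0

    def test_medoid_minimizes_summed_rmsd_within_largest_cluster(self):
        rng = np.random.default_rng(47)
        poses = [template_pose("L", f"m{i}",
                               TEMPLATE_COORDS + rng.normal(0, 0.4, (9, 3)))
                 for i in range(6)]
        res = consensus_of(PoseSet("L", poses), threshold=5.0)
        m = res.matrix
        cluster = max(res.clusters, key=len)
        sums = {i: sum(m[i, j] for j in cluster if j != i) for i in cluster}
        assert res.medoid_index == min(sums, key=lambda i: (sums[i], i))


class TestHierarchicalScreen:
    @staticmethod
    def _stage_sets(k1, stage2_close, seed=0):
        """Stage-1 set with k1 close poses; 5 extras with stage2_close close."""
        rng = np.random.default_rng(seed)
        s1_methods = [f"a{i}" for i in range(6)]
        s2_methods = [f"b{i}" for i in range(5)]
        poses1, extra = [], []
        far = iter(range(1, 20))
        for i, m in enumerate(s1_methods):
            if i < k1:
                c = TEMPLATE_COORDS + rng.normal(0, 0.2, (9, 3))
            else:
                c = TEMPLATE_COORDS + np.array([12.0 * next(far), 0, 0])
            poses1.append(template_pose("L", m, c))
        for i, m in enumerate(s2_methods):
            if i < stage2_close:
                c = TEMPLATE_COORDS + rng.normal(0, 0.2, (9, 3))
            else:
                c = TEMPLATE_COORDS + np.array([0, 12.0 * next(far), 0])
            extra.append(template_pose("L", m, c))
        return PoseSet("L", poses1), extra

    def test_low_stage1_level_fails_without_stage2(self):
        ps1, extra = self._stage_sets(k1=3, stage2_close=5)
        dec = hierarchical_screen(ps1, extra, min_level=4)
        assert dec.stage1_level == 3
        assert dec.stage2_level is None
        assert not dec.passed

    def test_full_agreement_across_eleven_poses_passes(self):
        ps1, extra = self._stage_sets(k1=6, stage2_close=5)
        dec = hierarchical_screen(ps1, extra, min_level=4)
        assert dec.stage1_level == 6
        assert dec.stage2_level == 11
        assert dec.passed

    def test_one_disagreeing_stage2_pose_fails_at_level_ten(self):
        ps1, extra = self._stage_sets(k1=6, stage2_close=4)
        dec = hierarchical_screen(ps1, extra, min_level=4)
        assert dec.stage2_level == 10
        assert not dec.passed

    def test_mixed_ligand_ids_are_rejected(self):
        ps1, extra = self._stage_sets(k1=6, stage2_close=5)
        bad = [template_pose("OTHER", "b9")]
        with pytest.raises(ValueError, match="mixed ligand"):
            hierarchical_screen(ps1, extra + bad)

    def test_raising_min_level_never_passes_more_ligands(self):
        cases = [self._stage_sets(k1=k, stage2_close=5, seed=k)
                 for k in range(1, 7)]
        passed_at = {}
        for lvl in range(1, 7):
            passed_at[lvl] = sum(
                hierarchical_screen(ps1, extra, min_level=lvl).stage1_level >= lvl
                for ps1, extra in cases)
        for lvl in range(2, 7):
            assert passed_at[lvl] <= passed_at[lvl - 1]
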