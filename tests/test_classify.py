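import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import projectome as pj
from projectome.classify import Decision, root_split
from projectome.errors import ValidationError


def matrix_from_array(arr):
    arr = np.asarray(arr)
    return pj.ProjectionMatrix(
        [f"n{i}" for i in range(arr.shape[0])],
        [pj.RegionLabel(f"R{j}") for j in range(arr.shape[1])],
        arr,
    )


class TestPairwiseAngles:
    def test_parallel_vectors_at_zero(self):
        dist = pj.pairwise_angles(matrix_from_array([[1, 0, 0], [2, 0, 0]]))
        assert dist.angles[0] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_vectors_at_ninety(self):
        dist = pj.pairwise_angles(matrix_from_array([[1, 0], [0, 1]]))
        assert dist.angles[0] == pytest.approx(90.0)

    def test_three_four_oracle(self):
        # arccos(24/25) computed independently at high precision
        expected = math.degrees(math.acos(24 / 25))
        dist = pj.pairwise_angles(matrix_from_array([[3, 4], [4, 3]]))
        assert dist.angles[0] == pytest.approx(expected, abs=1e-12)
        assert dist.angles[0] == pytest.approx(16.260204708312, abs=1e-9)

    def test_zero_row_names_the_neuron(self):
        with pytest.raises(ValidationError, match="n1"):
            pj.pairwise_angles(matrix_from_array([[1, 0], [0, 0]]))

    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=1, max_value=50))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_range_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 40, size=(5, 6))
        arr[:, 0] += 1  # no zero rows
        base = pj.pairwise_angles(matrix_from_array(arr)).angles
        scaled = pj.pairwise_angles(matrix_from_array(arr * scale)).angles
        assert np.all(base >= 0) and np.all(base <= 180)
        assert np.allclose(base, scaled, atol=1e-8)
        # symmetry: reversing row order permutes but preserves the multiset
        rev = pj.pairwise_angles(matrix_from_array(arr[::-1])).angles
        assert np.allclose(np.sort(base), np.sort(rev), atol=1e-8)


class TestLeveneGate:
    def test_identical_distributions_stop(self):
        values = np.array([10.0, 20.0, 30.0, 40.0])
        real = pj.DistanceDistribution(values, None)
        null = pj.DistanceDistribution(values.copy(), None)
        res = pj.levene_one_tailed(real, null)
        assert res.decision is Decision.STOP
        assert res.p_one_tailed is None  # equal variance is not the split direction

    def test_wider_real_distribution_splits(self):
        # real spread ~3x the null spread: the gate should open in nearly
        # every seeded draw (simulation oracle)
        splits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            real = pj.DistanceDistribution(
                np.clip(90 + 15 * rng.standard_normal(500), 0, 180), None)
            null = pj.DistanceDistribution(
                np.clip(90 + 5 * rng.standard_normal(500), 0, 180), None)
            if pj.levene_one_tailed(real, null).decision is Decision.SPLIT:
                splits += 1
        assert splits >= 38  # >= 95% of seeds

    def test_smaller_real_variance_gives_not_applicable_p(self):
        rng = np.random.default_rng(0)
        real = pj.DistanceDistribution(90 + 2 * rng.standard_normal(300), None)
        null = pj.DistanceDistribution(90 + 6 * rng.standard_normal(300), None)
        res = pj.levene_one_tailed(real, null)
        assert res.var_real < res.var_null
        assert res.p_one_tailed is None
        assert res.decision is Decision.STOP

    def test_statistic_matches_manual_levene_formula(self):
        # independent oracle: classical two-group Levene F on absolute
        # deviations from each group's mean
        rng = np.random.default_rng(7)
        x = 90 + 12 * rng.standard_normal(80)
        y = 90 + 5 * rng.standard_normal(90)
        zx = np.abs(x - x.mean())
        zy = np.abs(y - y.mean())
        grand = np.concatenate([zx, zy]).mean()
        nx, ny = len(zx), len(zy)
        between = nx * (zx.mean() - grand) ** 2 + ny * (zy.mean() - grand) ** 2
        within = ((zx - zx.mean()) ** 2).sum() + ((zy - zy.mean()) ** 2).sum()
        F = (nx + ny - 2) * between / within
        res = pj.levene_one_tailed(
            pj.DistanceDistribution(x, None), pj.DistanceDistribution(y, None))
        assert res.statistic == pytest.approx(F, rel=1e-10)

    def test_degenerate_constant_samples_stop_with_note(self):
        real = pj.DistanceDistribution(np.full(5, 10.0) + np.arange(5) * 1e-30, None)
        null = pj.DistanceDistribution(np.full(5, 10.0), None)
        res = pj.levene_one_tailed(real, null)
        assert res.decision is Decision.STOP


def brute_force_upgma(dmat):
    """Independent UPGMA: merge the closest pair of clusters, distance
    between clusters = mean of original pairwise distances."""
    n = dmat.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dmat[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestAverageLinkage:
    def test_two_items_single_merge(self):
        dist = pj.DistanceDistribution(np.array([42.0]), 2)
        Z = pj.average_linkage(dist)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(42.0)

    def test_forced_merge_order(self):
        # angles AB=10, AC=50, BC=50: A,B merge first, C joins at 50
        dist = pj.DistanceDistribution(np.array([10.0, 50.0, 50.0]), 3)
        Z = pj.average_linkage(dist)
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]
        assert Z[1, 2] == pytest.approx(50.0)
        left, right = root_split(Z, 3)
        assert sorted([left, right], key=len) == [[2], [0, 1]]

    def test_six_point_fixture_matches_brute_force(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(6, 4))
        dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        condensed = dmat[np.triu_indices(6, k=1)]
        Z = pj.average_linkage(pj.DistanceDistribution(
            np.clip(condensed, 0, 180), 6))
        expected = brute_force_upgma(dmat)
        assert np.allclose(sorted(Z[:, 2]), sorted(expected), atol=1e-10)

    def test_newick_has_all_labels_and_heights(self):
        dist = pj.DistanceDistribution(np.array([10.0, 50.0, 50.0]), 3)
        Z = pj.average_linkage(dist)
        nwk = pj.linkage_to_newick(Z, ["a", "b", "c"])
        assert nwk.endswith(";")
        for label in ("a", "b", "c"):
            assert label in nwk


class TestClassifyRecursive:
    def test_disjoint_two_class_matrix_recovered_exactly(self):
        cfg = pj.SyntheticConfig(
            seed=5, k_classes=2, neurons_per_class=20, n_regions=10,
            profiles=pj.default_profiles(2, 10, disjoint=True))
        mat, truth = pj.generate_matrix(cfg)
        tree, assignment = pj.classify_recursive(
            mat, pj.RandomizationConfig(seed=99))
        ari = adjusted_rand_score(
            [truth[n] for n in mat.neuron_ids],
            [assignment[n] for n in mat.neuron_ids])
        assert ari == pytest.approx(1.0)
        assert assignment.n_classes() == 2

    def test_labels_are_letter_plus_size_in_decreasing_size(self):
        cfg = pj.SyntheticConfig(
            seed=6, k_classes=2, neurons_per_class=[24, 16], n_regions=10,
            profiles=pj.default_profiles(2, 10, disjoint=True))
        mat, _ = pj.generate_matrix(cfg)
        _, assignment = pj.classify_recursive(mat, pj.RandomizationConfig(seed=1))
        labels = assignment.class_labels()
        assert labels == ["A24", "B16"]

    def test_partition_is_exact_and_exhaustive(self):
        cfg = pj.SyntheticConfig(seed=8, k_classes=3, neurons_per_class=15,
                                 n_regions=12)
        mat, _ = pj.generate_matrix(cfg)
        tree, assignment = pj.classify_recursive(mat, pj.RandomizationConfig(seed=2))
        leaves = tree.classes()
        all_members = [m for leaf in leaves for m in leaf.members]
        assert sorted(all_members) == sorted(mat.neuron_ids)  # no overlap, no loss
        assert set(assignment.as_dict()) == set(mat.neuron_ids)

    def test_determinism_same_seed_same_tree(self):
        cfg = pj.SyntheticConfig(seed=9, k_classes=2, neurons_per_class=15,
                                 n_regions=12)
        mat, _ = pj.generate_matrix(cfg)
        t1, a1 = pj.classify_recursive(mat, pj.RandomizationConfig(seed=77))
        t2, a2 = pj.classify_recursive(mat, pj.RandomizationConfig(seed=77))
        assert a1.as_dict() == a2.as_dict()
        assert t1.to_dict() == t2.to_dict()

    def test_min_testable_floor_enforced(self):
        cfg = pj.SyntheticConfig(seed=10, k_classes=1, neurons_per_class=10,
                                 n_regions=6)
        mat, _ = pj.generate_matrix(cfg)
        with pytest.raises(ValidationError, match="min_testable"):
            pj.classify_recursive(mat, pj.RandomizationConfig(seed=1),
                                  min_testable=3)

    def test_small_groups_terminate_untested(self):
        # 3 neurons are below the testable minimum: one terminal class
        cfg = pj.SyntheticConfig(seed=11, k_classes=1, neurons_per_class=3,
                                 n_regions=6)
        mat, _ = pj.generate_matrix(cfg)
        tree, assignment = pj.classify_recursive(mat, pj.RandomizationConfig(seed=1))
        assert assignment.n_classes() == 1
        assert tree.root.levene is None  # too small for the gate
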