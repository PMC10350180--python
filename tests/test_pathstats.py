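import itertools
import math

import numpy as np
import pytest

import projectome as pj
from projectome.errors import StructuralError, ValidationError
from projectome.matrix import RegionLabel, Side

from conftest import make_neuron


class TestPathDistance:
    def test_soma_distance_is_zero(self, chain_neuron):
        assert pj.path_distance(chain_neuron, 1) == 0.0

    def test_three_four_five_chain(self, chain_neuron):
        # cable length 3 + 4 = 7 while the Euclidean distance is 5
        assert pj.path_distance(chain_neuron, 3) == pytest.approx(7.0)
        euclid = math.dist(chain_neuron.node(3).xyz, chain_neuron.soma.xyz)
        assert euclid == pytest.approx(5.0)

    def test_branched_tree_matches_explicit_root_path_oracle(self, branched_neuron):
        # independent recomputation: walk parent pointers, sum segments
        for node in branched_neuron.nodes:
            expected, cur = 0.0, node
            while cur.parent_id is not None:
                parent = branched_neuron.node(cur.parent_id)
                expected += math.dist(cur.xyz, parent.xyz)
                cur = parent
            assert pj.path_distance(branched_neuron, node.node_id) == pytest.approx(
                expected)
            assert pj.path_distances_from_soma(branched_neuron)[
                node.node_id] == pytest.approx(expected)

    def test_path_distance_at_least_euclidean(self):
        rng = np.random.default_rng(2)
        specs, parent = [], 0
        for i in range(15):
            x, y, z = rng.normal(size=3) * 50
            specs.append((x, y, z, parent, "P"))
            parent = i + 1 if rng.random() < 0.7 else 0
        neuron = make_neuron("rand", (0, 0, 0), specs)
        for node in neuron.axon_nodes():
            assert pj.path_distance(neuron, node.node_id) >= math.dist(
                node.xyz, neuron.soma.xyz) - 1e-9

    def test_unknown_node_is_structural_error(self, chain_neuron):
        with pytest.raises(StructuralError):
            pj.path_distance(chain_neuron, 99)


class TestCollectMedians:
    def test_median_of_region_points(self):
        # points at path distances 1, 2, 9 along one chain in region P
        neuron = make_neuron("n", (0, 0, 0),
                             [(1, 0, 0, 0, "P"), (2, 0, 0, 1, "P"),
                              (9, 0, 0, 2, "P")])
        records = pj.collect_medians([neuron], {"n": "A1"})
        assert len(records) == 1
        assert records[0].median_distance == pytest.approx(2.0)

    def test_absent_region_has_no_record(self):
        neuron = make_neuron("n", (0, 0, 0), [(1, 0, 0, 0, "P")])
        records = pj.collect_medians([neuron], {"n": "A1"})
        assert {str(r.region) for r in records} == {"P"}

    def test_two_neuron_fixture_matches_hand_enumeration(self):
        n1 = make_neuron("n1", (0, 0, 0),
                         [(2, 0, 0, 0, "P"), (4, 0, 0, 1, "P"),
                          (0, 3, 0, 0, "Q")])
        n2 = make_neuron("n2", (0, 0, 0), [(0, 5, 0, 0, "Q")])
        records = pj.collect_medians([n1, n2], {"n1": "A", "n2": "B"})
        table = {(r.neuron_id, str(r.region)): r.median_distance for r in records}
        assert table == {
            ("n1", "P"): pytest.approx(3.0),  # median of {2, 4}
            ("n1", "Q"): pytest.approx(3.0),
            ("n2", "Q"): pytest.approx(5.0),
        }

    def test_hemisphere_separation(self):
        neuron = make_neuron("n", (0, 0, 2.0),
                             [(0, 0, 4.0, 0, "P"), (0, 0, 9.0, 0, "P")])
        records = pj.collect_medians([neuron], {"n": "A"}, midline=5.0,
                                     split_hemispheres=True)
        sides = {str(r.region) for r in records}
        assert sides == {"P:ipsi", "P:contra"}

    def test_unassigned_nodes_are_skipped(self):
        neuron = make_neuron("n", (0, 0, 0),
                             [(1, 0, 0, 0, "unassigned"), (2, 0, 0, 0, "P")])
        records = pj.collect_medians([neuron], {"n": "A"})
        assert [str(r.region) for r in records] == ["P"]


def bh_oracle(p):
    """Direct Benjamini–Hochberg definition: q_i = min over j >= rank(i)
    of p_(j) * m / j, computed by brute force."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert pj.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_closed_form_pair(self):
        q = pj.fdr_adjust([0.01, 0.04])
        assert q == pytest.approx([0.02, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_definition(self, seed):
        p = np.random.default_rng(seed).uniform(size=20)
        assert pj.fdr_adjust(p) == pytest.approx(bh_oracle(p))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            pj.fdr_adjust([0.5, 1.5])


def exact_ranksum_p(x, y):
    """Enumerate all assignments of ranks to group x (no ties assumed)."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    rx = ranks[: len(x)].sum()
    n, m = len(x), len(y)
    stats = [sum(c) for c in itertools.combinations(range(1, n + m + 1), n)]
    stats = np.array(stats)
    observed_tail = min((stats <= rx).mean(), (stats >= rx).mean())
    return min(1.0, 2 * observed_tail)


class TestRankTests:
    def test_identical_median_sets_not_significant(self):
        records = []
        for cls, vals in (("A", [1, 2, 3, 4, 5]), ("B", [1, 2, 3, 4, 5])):
            for i, v in enumerate(vals):
                records.append(pj.PathDistanceRecord(
                    f"{cls}{i}", cls, RegionLabel("T"), np.array([v]), float(v)))
        results, _ = pj.convergence_test(records, RegionLabel("T"))
        assert len(results) == 1
        assert not results[0].significant
        assert results[0].p_raw == pytest.approx(1.0, abs=0.05)

    def test_extreme_separation_significant_with_exact_p(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([101.0, 102, 103, 104, 105])
        records = [
            pj.PathDistanceRecord(f"a{i}", "C", RegionLabel("T1"),
                                  np.array([v]), float(v)) for i, v in enumerate(a)
        ] + [
            pj.PathDistanceRecord(f"b{i}", "C", RegionLabel("T2"),
                                  np.array([v]), float(v)) for i, v in enumerate(b)
        ]
        results, _ = pj.divergence_test(records, "C")
        assert len(results) == 1
        r = results[0]
        assert r.significant
        assert r.p_raw == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)
        assert "T1 shorter than T2" in r.direction

    def test_divergence_never_mixes_hemispheres(self):
        records = []
        for side, vals in ((Side.IPSI, [1, 2, 3]), (Side.CONTRA, [10, 20, 30])):
            for i, v in enumerate(vals):
                records.append(pj.PathDistanceRecord(
                    f"n{side.value}{i}", "C", RegionLabel("T", side),
                    np.array([v]), float(v)))
        results, _ = pj.divergence_test(records, "C")
        assert results == []  # same parcel on opposite sides is never a pair

    def test_single_class_target_yields_notice(self):
        records = [pj.PathDistanceRecord("n0", "A", RegionLabel("T"),
                                         np.array([1.0]), 1.0)]
        results, notices = pj.convergence_test(records, RegionLabel("T"))
        assert results == []
        assert any("only 1 class" in n for n in notices)

    def test_planted_shift_between_classes_detected(self):
        rng = np.random.default_rng(0)
        detected = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            records = []
            for cls, shift in (("A", 0.0), ("B", 0.25)):
                base = 1000 * (1 + shift)
                for i in range(12):
                    v = base * (1 + 0.08 * r.standard_normal())
                    records.append(pj.PathDistanceRecord(
                        f"{cls}{i}", cls, RegionLabel("T"), np.array([v]), v))
            results, _ = pj.convergence_test(records, RegionLabel("T"))
            if results and results[0].significant:
                assert "A shorter than B" in results[0].direction
                detected += 1
        assert detected >= 18

    def test_null_rejection_rate_controlled(self):
        # both classes drawn from one distribution: q < 0.05 rejections
        # should not exceed the nominal level by more than binomial noise
        rejections = 0
        n_rep = 500
        for rep in range(n_rep):
            r = np.random.default_rng(10_000 + rep)
            records = []
            for cls in ("A", "B"):
                for i in range(10):
                    v = float(1000 + 100 * r.standard_normal())
                    records.append(pj.PathDistanceRecord(
                        f"{cls}{i}", cls, RegionLabel("T"), np.array([v]), v))
            results, _ = pj.convergence_test(records, RegionLabel("T"))
            rejections += bool(results and results[0].significant)
        rate = rejections / n_rep
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)

    def test_direction_consistent_with_median_difference(self):
        rng = np.random.default_rng(4)
        records = []
        for cls in ("A", "B", "C"):
            for i in range(8):
                v = float(rng.uniform(500, 1500))
                records.append(pj.PathDistanceRecord(
                    f"{cls}{i}", cls, RegionLabel("T"), np.array([v]), v))
        results, _ = pj.convergence_test(records, RegionLabel("T"))
        medians = {cls: np.median([r.median_distance for r in records
                                   if r.class_label == cls])
                   for cls in ("A", "B", "C")}
        for res in results:
            if "shorter" in res.direction:
                shorter = res.direction.split(" shorter")[0]
                other = res.group_b if shorter == res.group_a else res.group_a
                assert medians[shorter] < medians[other]
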