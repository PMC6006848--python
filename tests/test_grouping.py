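"""Clustering, merging, the three cluster rules, weight calibration and
sample-set emission."""

import math

import numpy as np

from samselect.extraction import HFSubstring, dis_matrix
from samselect.grouping import (
    Cluster,
    GroupingConfig,
    _AmCache,
    apply_rule1,
    apply_rule2,
    apply_rule3,
    calibrate_am,
    cluster_ap,
    cluster_weight,
    emit_sample_sets,
    merge_clusters,
    similarity,
    similarity_matrix,
    trim_to_t_prime,
)
from samselect.seqdata import codes_to_seq


def mutate(rng, text: str, k: int) -> str:
    codes = np.frombuffer(text.encode(), dtype=np.uint8).copy()
    lookup = {65: 0, 67: 1, 71: 2, 84: 3}
    positions = rng.choice(len(text), size=k, replace=False)
    out = list(text)
    for p in positions:
        cur = lookup[codes[p]]
        out[p] = "ACGT"[(cur + int(rng.integers(1, 4))) % 4]
    return "".join(out)


class TestSimilarity:
    def test_zero_distance(self):
        assert similarity("ACGTACGTA", "ACGTACGTA", 9, 2) == 0.0

    def test_boundary_inclusive_in_first_branch(self):
        # construct a pair at exactly dis = 2d = 4
        a = "AAAAAAAAA"
        b = "TTTTAAAAA"[::-1]  # 4 mismatches in the lone 9-window
        assert similarity(a, b, 9, 2) == -4.0

    def test_penalty_branch(self):
        a, b = "AAAAAAAAA", "TTTTTAAAA"
        assert similarity(a, b, 9, 2) == -50.0

    def test_matrix_branches(self):
        D = np.array([[0, 4, 5], [4, 0, 2], [5, 2, 0]], dtype=np.uint8)
        S = similarity_matrix(D, 2)
        assert S[0, 1] == -4.0 and S[0, 2] == -50.0 and S[1, 2] == -2.0


class TestClusterAP:
    def test_two_planted_groups_recovered(self, rng):
        base1 = codes_to_seq(rng.integers(0, 4, 12))
        base2 = codes_to_seq(rng.integers(0, 4, 12))
        texts = [mutate(rng, base1, 1) for _ in range(10)]
        texts += [mutate(rng, base2, 1) for _ in range(10)]
        D = dis_matrix(texts, 9)
        clusters = cluster_ap(D, 2, GroupingConfig(seed=0))
        assert len(clusters) == 2
        sides = [sorted(c.members) for c in clusters]
        assert sorted(sides) == [list(range(10)), list(range(10, 20))]

    def test_partition_property(self, rng):
        texts = [codes_to_seq(rng.integers(0, 4, 12)) for _ in range(15)]
        D = dis_matrix(texts, 9)
        clusters = cluster_ap(D, 2, GroupingConfig(seed=1))
        members = sorted(m for c in clusters for m in c.members)
        assert members == list(range(15))
        for c in clusters:
            assert c.center in c.members

    def test_deterministic_under_seed(self, rng):
        texts = [codes_to_seq(rng.integers(0, 4, 12)) for _ in range(12)]
        D = dis_matrix(texts, 9)
        a = cluster_ap(D, 2, GroupingConfig(seed=7))
        b = cluster_ap(D, 2, GroupingConfig(seed=7))
        assert [(c.members, c.center) for c in a] == [
            (c.members, c.center) for c in b
        ]


class TestMergeClusters:
    def test_same_motif_clusters_merge(self, rng):
        base = codes_to_seq(rng.integers(0, 4, 12))
        texts = [mutate(rng, base, 1) for _ in range(12)]
        D = dis_matrix(texts, 9)
        clusters = [
            Cluster(list(range(6)), 0),
            Cluster(list(range(6, 12)), 6),
        ]
        merged = merge_clusters(clusters, D, 9, 2)
        assert len(merged) == 1
        assert sorted(merged[0].members) == list(range(12))

    def test_unrelated_clusters_stay_apart(self, rng):
        texts = [codes_to_seq(rng.integers(0, 4, 12)) for _ in range(12)]
        D = dis_matrix(texts, 9)
        # random 9-mer window distances are rarely <= d = 1
        clusters = [Cluster(list(range(6)), 0), Cluster(list(range(6, 12)), 6)]
        merged = merge_clusters(clusters, D, 9, 1)
        assert len(merged) == 2

    def test_membership_conserved(self, rng):
        base = codes_to_seq(rng.integers(0, 4, 12))
        texts = [mutate(rng, base, 1) for _ in range(9)]
        texts += [codes_to_seq(rng.integers(0, 4, 12)) for _ in range(6)]
        D = dis_matrix(texts, 9)
        clusters = [
            Cluster(list(range(5)), 0),
            Cluster(list(range(5, 9)), 5),
            Cluster(list(range(9, 15)), 9),
        ]
        merged = merge_clusters(clusters, D, 9, 2)
        members = sorted(m for c in merged for m in c.members)
        assert members == list(range(15))
        assert len(merged) <= 3


class TestTrim:
    def test_small_cluster_unchanged(self):
        D = np.zeros((4, 4), dtype=np.uint8)
        c = trim_to_t_prime(Cluster([0, 1, 2, 3], 0), D, 10)
        assert sorted(c.members) == [0, 1, 2, 3]

    def test_keeps_the_closest(self):
        n = 10
        D = np.zeros((n, n), dtype=np.uint8)
        D[0, :] = np.arange(n)
        D[:, 0] = np.arange(n)
        c = trim_to_t_prime(Cluster(list(range(n)), 0), D, 5)
        assert sorted(c.members) == [0, 1, 2, 3, 4]

    def test_center_survives_mass_ties(self):
        n = 8
        D = np.zeros((n, n), dtype=np.uint8)  # everything at distance 0
        c = trim_to_t_prime(Cluster(list(range(n)), 5), D, 3)
        assert 5 in c.members and len(c.members) == 3


class TestRules:
    def test_rule1_compliant_cluster_unchanged(self):
        D = np.full((5, 5), 3, dtype=np.uint8)
        np.fill_diagonal(D, 0)
        c = apply_rule1(Cluster(list(range(5)), 0), D, 2)
        assert sorted(c.members) == list(range(5))

    def test_rule1_removes_exactly_the_outlier(self):
        n = 6
        D = np.full((n, n), 2, dtype=np.uint8)
        np.fill_diagonal(D, 0)
        D[n - 1, :] = 9
        D[:, n - 1] = 9
        D[n - 1, n - 1] = 0
        c = apply_rule1(Cluster(list(range(n)), 0), D, 2)
        assert sorted(c.members) == list(range(n - 1))
        sub = D[np.ix_(c.members, c.members)]
        assert sub.max() <= 4

    def test_rule2_boundary_floor_3d_over_2(self):
        # d=4: members at distance 6 kept, 7 removed
        D = np.zeros((4, 4), dtype=np.uint8)
        D[0, 1] = D[1, 0] = 6
        D[0, 2] = D[2, 0] = 7
        c = apply_rule2(Cluster([0, 1, 2, 3], 0), D, 4)
        assert sorted(c.members) == [0, 1, 3]

    def test_rule2_center_never_removed(self):
        D = np.full((3, 3), 9, dtype=np.uint8)
        np.fill_diagonal(D, 0)
        c = apply_rule2(Cluster([0, 1, 2], 1), D, 2)
        assert c.members == [1]


class TestCalibration:
    def test_d0_gives_zero_threshold(self):
        am, mu, sigma = calibrate_am(10, 9, 0, calib_samples=50, seed=0)
        assert (am, mu, sigma) == (0.0, 0.0, 0.0)

    def test_grows_with_cluster_size(self):
        am10, _, _ = calibrate_am(10, 9, 2, calib_samples=300, seed=3)
        am40, _, _ = calibrate_am(40, 9, 2, calib_samples=300, seed=3)
        assert am40 > am10

    def test_mean_matches_pair_expectation(self):
        size, l, d, trials = 12, 9, 2, 2000
        _, mu, _ = calibrate_am(size, l, d, calib_samples=trials, seed=5)
        m = d / (2 * l)  # per-position mutation probability of the model
        e_pair = l * (2 * m - (4 / 3) * m * m)
        expected = math.comb(size, 2) * e_pair
        # SE of the mean of `trials` sample weights
        assert abs(mu - expected) / expected < 0.05

    def test_reproducible_under_seed(self):
        a = calibrate_am(15, 9, 2, calib_samples=100, seed=9)
        b = calibrate_am(15, 9, 2, calib_samples=100, seed=9)
        assert a == b


class TestRule3:
    def cfg(self, **kw):
        defaults = dict(min_cluster=3, removal_batch=2, calib_samples=100, seed=0)
        defaults.update(kw)
        return GroupingConfig(**defaults)

    def test_identical_members_accepted_immediately(self):
        D = np.zeros((6, 6), dtype=np.uint8)
        cache = _AmCache(9, 2, 100, 0)
        c = apply_rule3(Cluster(list(range(6)), 0), D, cache, self.cfg())
        assert c is not None and sorted(c.members) == list(range(6))

    def test_inflated_decoys_removed_in_batches(self):
        n = 9
        D = np.full((n, n), 4, dtype=np.uint8)
        np.fill_diagonal(D, 0)
        # members 0..4 mutually close; 5..8 inflate the weight
        close = np.ix_(range(5), range(5))
        D[close] = 0
        cache = _AmCache(9, 2, 100, 0)
        c = apply_rule3(Cluster(list(range(n)), 0), D, cache, self.cfg())
        assert c is not None
        assert len(c.members) < n  # at least one batch was removed
        assert cluster_weight(c, D) <= cache.get(len(c.members))
        # removal targets the heavy members: the tight core survives intact
        assert set(range(5)) <= set(c.members)

    def test_hopeless_cluster_discarded(self):
        n = 6
        D = np.full((n, n), 9, dtype=np.uint8)
        np.fill_diagonal(D, 0)
        cache = _AmCache(9, 1, 100, 0)
        c = apply_rule3(
            Cluster(list(range(n)), 0), D, cache, self.cfg(min_cluster=5)
        )
        assert c is None


class TestEmit:
    def test_distinct_sources_full_size(self):
        subs = [
            HFSubstring(f"s{i}", 0, 9, "ACGTACGTA") for i in range(4)
        ]
        D = np.zeros((4, 4), dtype=np.uint8)
        sets = emit_sample_sets(
            [Cluster(list(range(4)), 0)], subs, D, GroupingConfig()
        )
        assert sets[0].t_prime == 4
        assert sorted(sets[0].sequence_ids) == [f"s{i}" for i in range(4)]

    def test_duplicate_source_deduplicated(self):
        subs = [
            HFSubstring("s0", 0, 9, "ACGTACGTA"),
            HFSubstring("s0", 10, 19, "ACGTACGTT"),
            HFSubstring("s1", 0, 9, "ACGTACGTC"),
        ]
        D = np.array([[0, 1, 1], [1, 0, 2], [1, 2, 0]], dtype=np.uint8)
        sets = emit_sample_sets(
            [Cluster([0, 1, 2], 0)], subs, D, GroupingConfig()
        )
        assert sets[0].t_prime == 2
        assert sets[0].sequence_ids.count("s0") == 1

    def test_ranking_by_size(self):
        subs = [HFSubstring(f"s{i}", 0, 9, "ACGTACGTA") for i in range(12)]
        D = np.zeros((12, 12), dtype=np.uint8)
        big = Cluster(list(range(8)), 0)
        small = Cluster(list(range(8, 12)), 8)
        sets = emit_sample_sets([small, big], subs, D, GroupingConfig())
        assert [s.rank for s in sets] == [1, 2]
        assert sets[0].t_prime == 8 and sets[1].t_prime == 4
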