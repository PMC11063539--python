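import numpy as np
import pytest

from icluf import (
    SurvivalTable,
    adjusted_rand_index,
    cluster_subset_survival,
    evaluate,
    fowlkes_mallows,
    km_curves,
    logrank_test,
    silhouette_score,
)

from conftest import make_assignment, make_similarity
from helpers import ari_oracle, fm_oracle, km_oracle, logrank_oracle, silhouette_oracle


class TestPartitionAgreement:
    def test_identical_partitions_score_one(self):
        a = make_assignment([0, 1, 1, 2])
        b = make_assignment([2, 0, 0, 1], k=3)
        assert adjusted_rand_index(a, a) == 1.0
        assert fowlkes_mallows(a, a) == 1.0
        # label names do not matter
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_crossed_partitions_match_pair_counting(self):
        a = make_assignment([0, 0, 1, 1])
        b = make_assignment([0, 1, 0, 1])
        assert adjusted_rand_index(a, b) == pytest.approx(ari_oracle(a.labels, b.labels))
        assert fowlkes_mallows(a, b) == pytest.approx(fm_oracle(a.labels, b.labels))

    def test_singletons_vs_one_cluster(self):
        a = make_assignment([0, 1, 2, 3])
        b = make_assignment([0, 0, 0, 0], k=1)
        assert adjusted_rand_index(a, b) == pytest.approx(ari_oracle(a.labels, b.labels))
        assert abs(adjusted_rand_index(a, b)) < 1e-12

    def test_symmetric_and_permutation_invariant(self, rng):
        a = make_assignment(rng.integers(0, 3, 12), k=3)
        b = make_assignment(rng.integers(0, 4, 12), k=4)
        assert adjusted_rand_index(a, b) == adjusted_rand_index(b, a)
        assert fowlkes_mallows(a, b) == fowlkes_mallows(b, a)
        relabeled = make_assignment((b.labels + 1) % 4, k=4)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(a, relabeled))

    def test_mismatched_samples_rejected(self):
        a = make_assignment([0, 1], sample_ids=["A", "B"])
        b = make_assignment([0, 1], sample_ids=["B", "A"])
        with pytest.raises(ValueError, match="different samples"):
            adjusted_rand_index(a, b)

    def test_chance_level_fm_for_independent_partitions(self, rng):
        # mean FM over independent draws approaches the analytic chance level
        n, draws = 200, 100
        vals = []
        for _ in range(draws):
            a = make_assignment(rng.integers(0, 2, n), k=2)
            b = make_assignment(rng.integers(0, 2, n), k=2)
            vals.append(fowlkes_mallows(a, b))
        # for balanced random binary partitions both precision and recall
        # concentrate near 1/2, so FM concentrates near 1/2 as well
        assert np.mean(vals) == pytest.approx(0.5, abs=3 * np.std(vals) / np.sqrt(draws) + 0.01)


class TestSilhouette:
    def test_two_far_identical_blocks_approach_one(self):
        values = np.zeros((6, 6))
        values[:3, :3] = 1.0
        values[3:, 3:] = 1.0
        integ = make_similarity(values, role="integrated")
        ca = make_assignment([0, 0, 0, 1, 1, 1])
        assert silhouette_score(integ, ca) == pytest.approx(1.0, abs=1e-6)

    def test_matches_per_point_oracle(self, rng):
        x = rng.uniform(0, 1, size=(4, 4))
        values = (x + x.T) / 2
        integ = make_similarity(values, role="integrated")
        ca = make_assignment([0, 0, 1, 1])
        expected = silhouette_oracle(values, ca.labels)
        assert silhouette_score(integ, ca) == pytest.approx(expected, abs=1e-12)

    def test_range_invariant(self, rng):
        x = rng.uniform(0, 1, size=(10, 10))
        integ = make_similarity((x + x.T) / 2, role="integrated")
        ca = make_assignment(rng.integers(0, 3, 10), k=3)
        if len(np.unique(ca.labels)) < 2:
            pytest.skip("degenerate draw")
        assert -1.0 <= silhouette_score(integ, ca) <= 1.0

    def test_single_cluster_rejected(self, rng):
        x = rng.uniform(0, 1, size=(4, 4))
        integ = make_similarity((x + x.T) / 2, role="integrated")
        with pytest.raises(ValueError, match="two"):
            silhouette_score(integ, make_assignment([0, 0, 0, 0], k=1))

    def test_dissimilarity_space_variant(self, rng):
        x = rng.uniform(0, 1, size=(6, 6))
        integ = make_similarity((x + x.T) / 2, role="integrated")
        ca = make_assignment([0, 0, 0, 1, 1, 1])
        val = silhouette_score(integ, ca, space="dissimilarity")
        assert -1.0 <= val <= 1.0


class TestLogrank:
    def _surv(self, time, event, ids=None):
        ids = ids or [f"S{i}" for i in range(len(time))]
        return SurvivalTable(ids, time, event)

    def test_identical_groups_give_null_result(self):
        time = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        surv = self._surv(time, event)
        ca = make_assignment([0, 0, 0, 0, 1, 1, 1, 1])
        stat, df, p = logrank_test(surv, ca)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation_on_worked_example(self):
        # 10 subjects, two groups, mixed censoring and a tied event time
        time = [1.0, 2.0, 2.0, 4.0, 5.0, 1.5, 3.0, 4.0, 6.0, 7.0]
        event = [1, 1, 0, 1, 1, 1, 1, 0, 1, 0]
        labels = [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
        surv = self._surv(time, event)
        ca = make_assignment(labels)
        stat, df, p = logrank_test(surv, ca)
        stat_o, df_o, p_o = logrank_oracle(time, event, labels)
        assert stat == pytest.approx(stat_o, abs=1e-6)
        assert df == df_o
        assert p == pytest.approx(p_o, abs=1e-6)

    def test_three_group_example_matches_oracle(self, rng):
        n = 30
        time = rng.exponential(1.0, n)
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        labels = np.repeat([0, 1, 2], 10)
        stat, df, p = logrank_test(self._surv(time, event), make_assignment(labels))
        stat_o, df_o, p_o = logrank_oracle(time, event, labels)
        assert df == 2
        assert stat == pytest.approx(stat_o, rel=1e-6)
        assert p == pytest.approx(p_o, rel=1e-6)

    def test_invariant_to_time_rescaling(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        labels = [0, 0, 0, 1, 1, 1]
        s1 = logrank_test(self._surv(time, event), make_assignment(labels))
        s2 = logrank_test(self._surv(time * 37.5, event), make_assignment(labels))
        assert s1[0] == pytest.approx(s2[0], rel=1e-12)

    def test_single_group_rejected(self):
        surv = self._surv([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="two"):
            logrank_test(surv, make_assignment([0, 0], k=1))

    def test_zero_events_rejected(self):
        surv = self._surv([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="event"):
            logrank_test(surv, make_assignment([0, 1]))


class TestKaplanMeier:
    def test_product_limit_two_events(self):
        surv = SurvivalTable(["A", "B"], [1.0, 2.0], [1, 1])
        ca = make_assignment([0, 0], k=1, sample_ids=["A", "B"])
        table = km_curves(surv, ca)
        after = {row.time: row.survival for row in table.itertuples() if row.n_events}
        assert after[1.0] == pytest.approx(0.5)
        assert after[2.0] == pytest.approx(0.0)

    def test_matches_hand_product_limit(self, rng):
        n = 12
        time = rng.exponential(2.0, n).round(2)
        event = rng.integers(0, 2, n)
        event[0] = 1
        surv = SurvivalTable([f"S{i}" for i in range(n)], time, event)
        ca = make_assignment([0] * n, k=1)
        table = km_curves(surv, ca)
        for t, s in km_oracle(time, event):
            got = table[(table.time == t) & (table.n_events > 0)].survival.iloc[0]
            assert got == pytest.approx(s, abs=1e-12)

    def test_all_censored_constant_one(self):
        surv = SurvivalTable(["A", "B", "C"], [1.0, 2.0, 3.0], [0, 0, 0])
        ca = make_assignment([0, 0, 0], k=1, sample_ids=["A", "B", "C"])
        table = km_curves(surv, ca)
        assert (table.survival == 1.0).all()

    def test_invariant_to_within_group_order(self):
        surv1 = SurvivalTable(["A", "B", "C"], [3.0, 1.0, 2.0], [1, 1, 0])
        ca1 = make_assignment([0, 0, 0], k=1, sample_ids=["A", "B", "C"])
        surv2 = SurvivalTable(["B", "C", "A"], [1.0, 2.0, 3.0], [1, 0, 1])
        ca2 = make_assignment([0, 0, 0], k=1, sample_ids=["B", "C", "A"])
        t1 = km_curves(surv1, ca1)
        t2 = km_curves(surv2, ca2)
        assert t1.drop(columns=[]).equals(t2)


class TestClusterSubsets:
    def _five_cluster_setup(self, rng):
        n = 50
        labels = np.repeat(np.arange(5), 10)
        time = rng.exponential(1.0, n)
        event = np.ones(n, dtype=int)
        ids = [f"S{i}" for i in range(n)]
        return SurvivalTable(ids, time, event), make_assignment(labels, sample_ids=ids)

    @pytest.mark.parametrize("size,count", [(2, 10), (3, 10), (4, 5)])
    def test_combination_counts(self, rng, size, count):
        surv, ca = self._five_cluster_setup(rng)
        out = cluster_subset_survival(surv, ca, [size])
        assert len(out) == count
        assert all(0.0 <= p <= 1.0 for p in out.values())

    def test_subset_size_equal_to_k_rejected(self, rng):
        surv, ca = self._five_cluster_setup(rng)
        with pytest.raises(ValueError, match="size"):
            cluster_subset_survival(surv, ca, [5])

    def test_k3_size3_rejected(self, rng):
        ids = [f"S{i}" for i in range(9)]
        surv = SurvivalTable(ids, rng.exponential(1.0, 9), np.ones(9, dtype=int))
        ca = make_assignment(np.repeat([0, 1, 2], 3), sample_ids=ids)
        with pytest.raises(ValueError, match="size"):
            cluster_subset_survival(surv, ca, [3])


class TestEvaluateBundle:
    def test_report_fields_follow_inputs(self, rng):
        x = rng.uniform(0, 1, size=(6, 6))
        integ = make_similarity((x + x.T) / 2, role="integrated")
        ca = make_assignment([0, 0, 0, 1, 1, 1])
        truth = make_assignment([0, 0, 1, 1, 1, 0])
        surv = SurvivalTable(ca.sample_ids, rng.exponential(1.0, 6), np.ones(6, dtype=int))
        rep = evaluate(ca, integrated=integ, truth=truth, surv=surv)
        d = rep.to_dict()
        assert d["ari"] is not None and d["fm"] is not None
        assert d["silhouette"] is not None
        assert 0.0 <= d["logrank_p"] <= 1.0
        rep2 = evaluate(ca, truth=truth)
        assert rep2.silhouette is None and rep2.logrank_p is None
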