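"""Clustering algorithms, label alignment, consensus and PC-score rules."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabotyper.cluster import (
    ALGORITHMS,
    Partition,
    align_labels,
    final_consensus,
    pc_score_clusters,
    run_algorithm,
    select_k,
    _fuzzy_cmeans,
)
from metabotyper.synthetic import truth_recovery_score

from conftest import three_blobs, two_blobs
from oracles import adjusted_rand, best_alignment_exhaustive


class TestAlgorithms:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_recovers_two_separated_blobs(self, algorithm):
        x, truth = two_blobs(n_per=20, sep=5.0, sd=0.1)
        part = run_algorithm(x, algorithm, 2, seed=0)
        assert truth_recovery_score(truth, part) == 1.0

    def test_k_out_of_range_errors(self):
        x, _ = two_blobs(n_per=5)
        with pytest.raises(ValueError, match="out of range"):
            run_algorithm(x, "kmeans", len(x), seed=0)
        with pytest.raises(ValueError, match="out of range"):
            run_algorithm(x, "kmeans", 1, seed=0)

    def test_unknown_algorithm_errors(self):
        x, _ = two_blobs()
        with pytest.raises(ValueError, match="unknown algorithm"):
            run_algorithm(x, "dbscan", 2, seed=0)

    def test_fuzzy_membership_half_at_symmetric_midpoint(self):
        # symmetric 2-blob data plus one point equidistant from both centers
        base = np.array([[-5.0, 0.0]] * 10 + [[5.0, 0.0]] * 10 + [[0.0, 0.0]])
        u, labels = _fuzzy_cmeans(base, 2, np.random.default_rng(0))
        np.testing.assert_allclose(u[-1], [0.5, 0.5], atol=1e-3)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_row_permutation_invariance_up_to_relabeling(self, algorithm):
        x, _ = two_blobs(n_per=15, sep=4.0, sd=0.3, seed=3)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(x))
        a = run_algorithm(x, algorithm, 2, seed=9)
        b = run_algorithm(x[perm], algorithm, 2, seed=9)
        assert adjusted_rand(a.labels[perm], b.labels) == pytest.approx(1.0)

    def test_labels_canonical_and_clusters_nonempty(self):
        x, _ = three_blobs()
        for algorithm in ALGORITHMS:
            part = run_algorithm(x, algorithm, 3, seed=1)
            assert set(part.labels) == {1, 2, 3}
            assert part.labels[0] == 1  # first-appearance relabeling


class TestAlignment:
    def test_swapped_labels_are_unswapped(self):
        ref = Partition(np.array([1, 1, 2, 2]), 2)
        other = Partition(np.array([2, 2, 1, 1]), 2)
        assert align_labels(ref, other).labels.tolist() == [1, 1, 2, 2]

    def test_identical_partition_unchanged(self):
        ref = Partition(np.array([1, 2, 1, 2, 2]), 2)
        assert align_labels(ref, ref).labels.tolist() == ref.labels.tolist()

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="different numbers"):
            align_labels(Partition(np.array([1, 2]), 2), Partition(np.array([1, 2, 1]), 2))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 3), st.integers(4, 8))
    def test_matches_exhaustive_search(self, seed, k, n):
        rng = np.random.default_rng(seed)
        ref_l = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, n - k)])
        oth_l = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, n - k)])
        ref, oth = Partition(ref_l, k), Partition(oth_l, k)
        aligned = align_labels(ref, oth)
        _, best_agree = best_alignment_exhaustive(ref_l, oth_l)
        agree = (aligned.labels == ref_l).sum()
        assert agree == best_agree
        assert agree >= (oth_l == ref_l).sum()


class TestConsensus:
    def test_simple_majority(self):
        parts = [
            Partition(np.array([1, 1, 2, 2]), 2),
            Partition(np.array([1, 1, 2, 2]), 2),
            Partition(np.array([1, 1, 1, 2]), 2),
        ]
        res = final_consensus(parts)
        assert res.partition.labels.tolist() == [1, 1, 2, 2]

    def test_unanimity_reproduces_partition_with_full_votes(self):
        p = Partition(np.array([1, 2, 2, 1, 2]), 2)
        res = final_consensus([p, p, p])
        assert res.partition.labels.tolist() == p.labels.tolist()
        assert (res.vote_table.max(axis=1) == 3).all()

    def test_tie_goes_to_reference_label(self):
        ref = Partition(np.array([1, 2, 1, 2]), 2)
        other = Partition(np.array([2, 1, 1, 2]), 2)
        res = final_consensus([ref, other])
        assert res.partition.labels.tolist() == ref.labels.tolist()

    def test_consensus_is_idempotent(self):
        parts = [
            Partition(np.array([1, 1, 2, 2, 2]), 2),
            Partition(np.array([1, 2, 2, 2, 1]), 2),
            Partition(np.array([1, 1, 2, 1, 2]), 2),
        ]
        c1 = final_consensus(parts).partition
        c2 = final_consensus([c1, c1, c1]).partition
        assert c1.labels.tolist() == c2.labels.tolist()

    def test_k_mismatch_errors(self):
        with pytest.raises(ValueError, match="k="):
            final_consensus(
                [Partition(np.array([1, 2, 2]), 2), Partition(np.array([1, 2, 3]), 3)]
            )

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_independent_tally(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 10, 2
        parts = []
        for _ in range(9):
            labels = np.concatenate([[1, 2], rng.integers(1, k + 1, n - 2)])
            parts.append(Partition(labels, k))
        res = final_consensus(parts)
        for i in range(n):
            votes = [p.labels[i] for p in parts]
            counts = {lab: votes.count(lab) for lab in set(votes)}
            best = max(counts.values())
            winners = {lab for lab, c in counts.items() if c == best}
            assert res.partition.labels[i] in winners


class TestPCScoreClusters:
    def test_three_group_rule(self):
        scores = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        part = pc_score_clusters(scores, "3-group")
        assert part.labels.tolist() == [1, 2, 3, 3]

    def test_two_group_rule_and_zero_boundary(self):
        scores = np.array([[5.0, 0.0], [5.0, -0.1], [0.0, 0.0]])
        part = pc_score_clusters(scores, "2-group")
        assert part.labels.tolist() == [1, 2, 1]
        part3 = pc_score_clusters(np.array([[0.0, 0.0], [1.0, -1.0], [-1.0, 0.0]]), "3-group")
        assert part3.labels[0] == 1  # (0, 0) counts as positive/positive

    def test_wrong_score_width_errors(self, rng):
        with pytest.raises(ValueError):
            pc_score_clusters(rng.standard_normal((5, 3)))


class TestSelectK:
    def test_three_blobs_yield_k3(self):
        x, _ = three_blobs()
        sel = select_k(x, repeats=2, seed=0)
        assert sel.best_k == 3
        assert sum(sel.vote_counts.values()) + sel.n_abstentions > 0

    def test_structureless_data_still_reports_stability(self, rng):
        x = rng.random((30, 4))
        sel = select_k(x, algorithms=("kmeans", "hierarchical"), repeats=3, seed=1)
        assert len(sel.per_repeat_best) == 3
        assert 2 <= sel.best_k <= 10

    def test_k_range_validation(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.random((8, 3)), k_range=(2, 20))
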