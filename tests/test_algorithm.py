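"""Tests for the greedy k-AMH search driver."""

import numpy as np
import pytest

import oracles
from conftest import random_categorical_dataset
from kamh.algorithm import (
    CentroidSet,
    evaluate_candidate,
    fit_kamh,
    init_centroids,
    multi_restart,
)
from kamh.core import crisp_assign, distances_to_centroids, membership_matrix
from kamh.evaluation import accuracy
from kamh.synthetic import generate_surname_like
from kamh.ystr_io import HaplotypeDataset


def identical_class_dataset(k: int = 3, size: int = 4) -> HaplotypeDataset:
    """k classes, each a block of identical haplotypes, well separated."""
    rng = np.random.default_rng(99)
    rows, labels = [], []
    for c in range(k):
        hap = [str(100 * c + j) for j in range(5)]
        rows += [hap] * size
        labels += [f"G{c}"] * size
    return HaplotypeDataset(
        ids=tuple(f"o{i}" for i in range(k * size)),
        markers=tuple(f"M{j}" for j in range(5)),
        values=np.array(rows, dtype=object),
        labels=tuple(labels),
    )


class TestInitCentroids:
    def test_distinct_indices_in_range(self):
        ds = identical_class_dataset()
        cs = init_centroids(ds, 4, np.random.default_rng(0))
        assert len(set(cs.indices)) == 4
        assert all(0 <= i < ds.n_objects for i in cs.indices)
        for l, idx in enumerate(cs.indices):
            assert (cs.haplotypes[l] == ds.values[idx]).all()

    def test_k_equals_n_selects_everything(self):
        ds = identical_class_dataset(k=2, size=2)
        cs = init_centroids(ds, 4, np.random.default_rng(0))
        assert sorted(cs.indices) == [0, 1, 2, 3]

    def test_seeded_determinism(self):
        ds = identical_class_dataset()
        a = init_centroids(ds, 3, np.random.default_rng(7)).indices
        b = init_centroids(ds, 3, np.random.default_rng(7)).indices
        assert a == b

    @pytest.mark.parametrize("k", [0, -1, 13])
    def test_invalid_k_rejected(self, k):
        ds = identical_class_dataset()  # n = 12
        with pytest.raises(ValueError):
            init_centroids(ds, k, np.random.default_rng(0))

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError):
            CentroidSet(indices=(1, 1), haplotypes=np.empty((2, 3)))


class TestEvaluateCandidate:
    def test_current_centroid_rejected_as_candidate(self):
        ds = identical_class_dataset()
        cs = init_centroids(ds, 2, np.random.default_rng(1))
        with pytest.raises(ValueError):
            evaluate_candidate(ds, cs, 0, cs.indices[0])

    def test_identical_valued_candidate_gives_identical_cost(self):
        ds = identical_class_dataset()  # objects 0..3 identical
        cs = CentroidSet(indices=(0, 4), haplotypes=ds.values[[0, 4]])
        base = evaluate_candidate(ds, cs, 1, 5)   # 5 has 4's tokens
        same = evaluate_candidate(ds, cs, 1, 6)
        assert base == pytest.approx(same)

    def test_matches_scalar_set_cost_oracle(self):
        rng = np.random.default_rng(2)
        ds = random_categorical_dataset(rng, n=10, m=4)
        cs = CentroidSet(indices=(0, 3), haplotypes=ds.values[[0, 3]])
        for cand in (1, 2, 5, 9):
            got = evaluate_candidate(ds, cs, 1, cand, alpha=1.5)
            want = oracles.set_cost(
                ds.values, [ds.values[0], ds.values[cand]], 1.5)
            assert got == pytest.approx(want, abs=1e-12)

    def test_modal_object_of_tight_class_scores_best(self):
        # in a class of identical objects, its own member is an optimal
        # replacement: brute force over all candidates confirms
        ds = identical_class_dataset(k=3, size=4)
        cs = CentroidSet(indices=(0, 4, 8), haplotypes=ds.values[[0, 4, 8]])
        # replace cluster 0's center: any same-class duplicate ties the max
        costs = {cand: evaluate_candidate(ds, cs, 0, cand)
                 for cand in range(ds.n_objects) if cand not in cs.indices}
        best = max(costs.values())
        assert costs[1] == pytest.approx(best)

    def test_cost_invariant_under_object_order(self):
        rng = np.random.default_rng(3)
        ds = random_categorical_dataset(rng, n=9, m=4)
        perm = rng.permutation(9)
        permuted = ds.take(perm)
        inv = np.argsort(perm)
        cs = CentroidSet(indices=(0, 1), haplotypes=ds.values[[0, 1]])
        cs_p = CentroidSet(indices=(int(inv[0]), int(inv[1])),
                           haplotypes=permuted.values[[inv[0], inv[1]]])
        cand, cand_p = 5, int(inv[5])
        assert evaluate_candidate(ds, cs, 0, cand) == pytest.approx(
            evaluate_candidate(permuted, cs_p, 0, cand_p))


class TestFitKamh:
    def test_separable_duplicate_classes_recovered(self):
        ds = identical_class_dataset(k=3, size=4)
        result = fit_kamh(ds, 3, seed=5)
        assert accuracy(result.labels, ds.labels).r == 1.0

    def test_single_cluster_degenerate(self):
        ds = identical_class_dataset(k=2, size=3)
        result = fit_kamh(ds, 1, seed=0)
        # one cluster: every membership is 1, cost is n, nothing accepted
        assert result.final_cost == pytest.approx(ds.n_objects)
        assert result.replacements == 0
        assert (result.labels == 0).all()

    def test_accepted_costs_strictly_increase(self):
        ds = generate_surname_like(3, [10, 10, 10], m=10, seed=21)
        result = fit_kamh(ds, 3, seed=2)
        trace = result.cost_trace
        assert all(b > a for a, b in zip(trace, trace[1:]))
        assert result.final_cost >= result.initial_cost

    def test_self_consistency_of_result(self):
        ds = generate_surname_like(3, [8, 8, 8], m=10, seed=22)
        result = fit_kamh(ds, 3, seed=3)
        d = distances_to_centroids(ds.codes,
                                   ds.codes[list(result.centroid_indices)])
        w = membership_matrix(d, 1.5)
        np.testing.assert_allclose(result.membership, w)
        np.testing.assert_array_equal(result.labels, crisp_assign(w))

    def test_example_ii_best_of_20_recovers_skewed_split(self, example_ii):
        best, _ = multi_restart(example_ii, 2, n_restarts=20, seed=3)
        assert accuracy(best.labels, example_ii.labels).r == 1.0

    def test_no_replacement_sweep_count_is_k_times_n_minus_k(self):
        values = np.full((30, 5), "14", dtype=object)
        ds = HaplotypeDataset(ids=tuple(f"o{i}" for i in range(30)),
                              markers=tuple(f"M{j}" for j in range(5)),
                              values=values)
        result = fit_kamh(ds, 4, seed=0)
        assert result.replacements == 0
        assert result.candidate_evaluations == 4 * (30 - 4)

    def test_extra_sweeps_stop_after_quiet_sweep(self):
        ds = generate_surname_like(3, [10, 10, 10], m=10, seed=23)
        result = fit_kamh(ds, 3, seed=4, max_sweeps=10)
        assert result.sweeps_run <= 10
        single = fit_kamh(ds, 3, seed=4, max_sweeps=1)
        assert result.final_cost >= single.final_cost

    def test_fixed_centroid_values_give_permuted_labels(self):
        rng = np.random.default_rng(8)
        ds = random_categorical_dataset(rng, n=12, m=5)
        result = fit_kamh(ds, 3, seed=6)
        perm = rng.permutation(12)
        permuted = ds.take(perm)
        d = distances_to_centroids(permuted.codes,
                                   ds.codes[list(result.centroid_indices)])
        labels_p = crisp_assign(membership_matrix(d, 1.5))
        np.testing.assert_array_equal(labels_p, result.labels[perm])

    def test_never_beats_exhaustive_search(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n, k = int(rng.integers(6, 12)), int(rng.integers(2, 4))
            ds = random_categorical_dataset(rng, n=n, m=4)
            result = fit_kamh(ds, k, seed=int(rng.integers(1000)))
            best, _ = oracles.exhaustive_best(ds.values, k, 1.5)
            assert result.final_cost <= best + 1e-9


class TestMultiRestart:
    def test_single_restart_equals_single_run(self):
        ds = identical_class_dataset()
        best, runs = multi_restart(ds, 2, n_restarts=1, seed=10)
        assert len(runs) == 1
        assert best is runs[0]

    def test_best_dominates_all_runs(self):
        ds = generate_surname_like(3, [8, 8, 8], m=10, seed=24)
        best, runs = multi_restart(ds, 3, n_restarts=8, seed=11)
        assert all(best.final_cost >= r.final_cost for r in runs)

    def test_master_seed_reproducibility(self):
        ds = generate_surname_like(3, [8, 8, 8], m=10, seed=24)
        _, runs_a = multi_restart(ds, 3, n_restarts=5, seed=12)
        _, runs_b = multi_restart(ds, 3, n_restarts=5, seed=12)
        for a, b in zip(runs_a, runs_b):
            assert a.centroid_indices == b.centroid_indices
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_invalid_restart_count(self):
        ds = identical_class_dataset()
        with pytest.raises(ValueError):
            multi_restart(ds, 2, n_restarts=0, seed=0)
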