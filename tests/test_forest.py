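"""GWRF: split, subspace trees, evolution, weighted voting, metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gwrf.forest import (
    EvolutionConfig,
    GeneticWeightedForest,
    TreeSpec,
    WeightedForest,
    build_initial_forest,
    compute_weights,
    evaluate,
    evolve,
    fit_tree,
    forest_from_dict,
    forest_to_dict,
    predict_weighted,
    sample_feature_subset,
    select_champions,
    split_dataset,
    subset_size,
    tree_accuracy,
)
from gwrf.fusion import FusedDataset


def _dataset(n, n_features=6, seed=0, balanced=True):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n_features))
    labels = np.tile([1, -1], n // 2 + 1)[:n] if balanced else np.ones(n, dtype=int)
    x[:, 0] += labels * 2.5
    return FusedDataset(x, labels, np.arange(n).astype(str), np.ones(n))


class _StubTree:
    """Constant- or lookup-vote stand-in for oracle tests."""

    def __init__(self, votes):
        self.votes = np.asarray(votes, dtype=int)

    def predict(self, x):
        return self.votes[: len(np.atleast_2d(x))]


def _stub_forest(vote_rows, weights, num_features=3):
    trees = [
        TreeSpec(feature_subset=np.arange(subset_size(num_features)), model=_StubTree(v))
        for v in vote_rows
    ]
    return WeightedForest(
        trees=trees,
        weights=None if weights is None else np.asarray(weights, dtype=float),
        config=EvolutionConfig(n_trees=len(trees)),
        num_features=num_features,
    )


class TestSplit:
    def test_balanced_100_gives_60_20_20(self):
        s = split_dataset(_dataset(100), seed=1)
        assert (s.train.n, s.valid.n, s.test.n) == (60, 20, 20)

    def test_n10_gives_6_2_2(self):
        s = split_dataset(_dataset(10), seed=1)
        assert (s.train.n, s.valid.n, s.test.n) == (6, 2, 2)

    @pytest.mark.parametrize("n", [14, 26, 54, 102])
    def test_per_class_counts_within_one_of_exact_proportion(self, n):
        s = split_dataset(_dataset(n), seed=3)
        full = _dataset(n)
        for part, frac in zip((s.train, s.valid, s.test), (0.6, 0.2, 0.2)):
            for c in (-1, 1):
                exact = frac * (full.labels == c).sum()
                assert abs((part.labels == c).sum() - exact) < 1

    def test_partition_is_disjoint_and_complete(self):
        s = split_dataset(_dataset(37), seed=9)
        ids = np.concatenate([s.train.ids, s.valid.ids, s.test.ids])
        assert len(set(ids)) == 37

    def test_deterministic_given_seed(self):
        a = split_dataset(_dataset(50), seed=4)
        b = split_dataset(_dataset(50), seed=4)
        assert np.array_equal(a.train.ids, b.train.ids)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="label"):
            split_dataset(_dataset(20, balanced=False), seed=0)


class TestFeatureSubset:
    def test_full_scale_voxel_count_gives_209(self):
        assert len(sample_feature_subset(43851, seed=0)) == 209

    def test_perfect_square(self):
        assert len(sample_feature_subset(100, seed=0)) == 10

    @given(st.integers(1, 5000), st.integers(0, 100))
    def test_unique_in_range(self, num_features, seed):
        sub = sample_feature_subset(num_features, seed)
        assert len(sub) == subset_size(num_features)
        assert len(np.unique(sub)) == len(sub)
        assert sub.min() >= 0 and sub.max() < num_features


class TestFitTree:
    def test_separable_subset_trains_perfectly(self, separable_dataset):
        tree = fit_tree(separable_dataset, np.array([0, 1]), seed=0)
        assert tree_accuracy(tree, separable_dataset) == 1.0

    def test_constant_features_give_constant_tree(self):
        d = _dataset(20)
        d = FusedDataset(np.zeros((20, 3)), d.labels, d.ids, d.alpha_used)
        tree = fit_tree(d, np.array([0, 1]), seed=0)
        assert len(set(tree.predict(np.zeros((5, 3))))) == 1

    def test_same_seed_identical_predictions(self, fused_pair):
        probe = np.random.default_rng(0).standard_normal((10, fused_pair.n_features))
        t1 = fit_tree(fused_pair, np.arange(14), seed=3)
        t2 = fit_tree(fused_pair, np.arange(14), seed=3)
        assert np.array_equal(t1.predict(probe), t2.predict(probe))

    def test_invalid_subset_rejected(self, separable_dataset):
        with pytest.raises(ValueError, match="subset"):
            fit_tree(separable_dataset, np.array([0, 0]), seed=0)


class TestInitialForest:
    def test_forest_size(self, separable_dataset):
        f = build_initial_forest(separable_dataset, EvolutionConfig(n_trees=30, seed=0))
        assert f.n_trees == 30 and f.weights is None

    def test_singleton_forest(self, separable_dataset):
        f = build_initial_forest(separable_dataset, EvolutionConfig(n_trees=1, seed=0))
        assert f.n_trees == 1

    def test_subsets_differ_across_trees(self, fused_pair):
        f = build_initial_forest(fused_pair, EvolutionConfig(n_trees=25, seed=2))
        subsets = {tuple(t.feature_subset) for t in f.trees}
        assert len(subsets) > 20  # collisions vanishingly rare at C(200,14)


class TestTreeAccuracy:
    def test_fraction_correct(self):
        valid = FusedDataset(np.zeros((4, 3)), [1, 1, -1, -1],
                             np.arange(4).astype(str), np.ones(4))
        tree = TreeSpec(np.array([0]), _StubTree([1, 1, -1, 1]))
        assert tree_accuracy(tree, valid) == 0.75

    def test_constant_tree_on_balanced_set(self):
        valid = FusedDataset(np.zeros((10, 3)), [1] * 5 + [-1] * 5,
                             np.arange(10).astype(str), np.ones(10))
        tree = TreeSpec(np.array([0]), _StubTree([1] * 10))
        assert tree_accuracy(tree, valid) == 0.5

    def test_empty_valid_rejected(self, separable_dataset):
        tree = fit_tree(separable_dataset, np.array([0]), seed=0)
        empty = separable_dataset.take(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            tree_accuracy(tree, empty)


class TestEvolve:
    def test_zero_generations_identity(self, fused_pair):
        cfg = EvolutionConfig(n_trees=8, generations=0, seed=1)
        split = split_dataset(fused_pair, 1)
        f = build_initial_forest(split.train, cfg)
        assert evolve(f, split.train, split.valid, cfg).trees == f.trees

    @pytest.mark.parametrize("generations", [1, 3])
    def test_population_size_invariant(self, fused_pair, generations):
        cfg = EvolutionConfig(n_trees=11, group_size=4, generations=generations, seed=2)
        split = split_dataset(fused_pair, 2)
        f = build_initial_forest(split.train, cfg)
        assert evolve(f, split.train, split.valid, cfg).n_trees == 11

    def test_group_champions_match_brute_force(self, fused_pair):
        cfg = EvolutionConfig(n_trees=13, group_size=5, seed=3)
        split = split_dataset(fused_pair, 3)
        f = build_initial_forest(split.train, cfg)
        rng = np.random.default_rng(0)
        champions, groups = select_champions(f.trees, split.valid, 5, rng)
        accs = [tree_accuracy(t, split.valid) for t in f.trees]
        for champ, group in zip(champions, groups):
            best = max(accs[i] for i in group)
            assert accs[champ] == best
            assert champ == min(i for i in group if accs[i] == best)

    def test_oversized_group_rejected(self, fused_pair):
        cfg = EvolutionConfig(n_trees=3, group_size=5, generations=1, seed=0)
        split = split_dataset(fused_pair, 0)
        f = build_initial_forest(split.train, cfg)
        with pytest.raises(ValueError, match="group_size"):
            evolve(f, split.train, split.valid, cfg)

    def test_children_keep_subset_size(self, fused_pair):
        cfg = EvolutionConfig(n_trees=9, group_size=3, generations=2, seed=5)
        split = split_dataset(fused_pair, 5)
        f = evolve(build_initial_forest(split.train, cfg), split.train, split.valid, cfg)
        m = subset_size(fused_pair.n_features)
        for t in f.trees:
            assert len(t.feature_subset) == m
            assert len(np.unique(t.feature_subset)) == m


class TestWeights:
    def test_weights_equal_validation_accuracy(self, fused_pair):
        cfg = EvolutionConfig(n_trees=7, seed=4)
        split = split_dataset(fused_pair, 4)
        f = compute_weights(build_initial_forest(split.train, cfg), split.valid, cfg)
        recomputed = np.array([tree_accuracy(t, split.valid) for t in f.trees])
        assert np.array_equal(f.weights, recomputed)

    def test_ablation_forces_unit_weights(self, fused_pair):
        cfg = EvolutionConfig(n_trees=5, use_weights=False, seed=4)
        split = split_dataset(fused_pair, 4)
        f = compute_weights(build_initial_forest(split.train, cfg), split.valid, cfg)
        assert np.array_equal(f.weights, np.ones(5))


class TestPredictWeighted:
    def test_weighted_sum_beats_majority(self):
        # One 0.9-weight tree voting +1 outvotes two 0.4-weight trees voting -1.
        f = _stub_forest([[1], [-1], [-1]], [0.9, 0.4, 0.4])
        labels, scores = predict_weighted(f, np.zeros((1, 3)))
        assert labels[0] == 1 and scores[0] == pytest.approx(0.1)

    def test_equal_weights_is_majority_vote(self):
        f = _stub_forest([[1], [1], [-1]], [0.7, 0.7, 0.7])
        assert predict_weighted(f, np.zeros((1, 3)))[0][0] == 1

    def test_single_tree_forest(self):
        f = _stub_forest([[-1]], [0.6])
        assert predict_weighted(f, np.zeros((1, 3)))[0][0] == -1

    def test_tie_falls_back_to_highest_weight_tree(self):
        f = _stub_forest([[1], [-1]], [0.5, 0.5])
        # Score zero; first (lowest-index) max-weight tree decides: +1.
        assert predict_weighted(f, np.zeros((1, 3)))[0][0] == 1

    def test_all_zero_weights_fall_back_to_majority(self):
        f = _stub_forest([[-1], [-1], [1]], [0.0, 0.0, 0.0])
        assert predict_weighted(f, np.zeros((1, 3)))[0][0] == -1

    def test_unset_weights_rejected(self):
        f = _stub_forest([[1]], None)
        with pytest.raises(ValueError, match="weights"):
            predict_weighted(f, np.zeros((1, 3)))

    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        """Weighted committee equals brute-force vote summation (<=10 trees)."""
        n_trees = data.draw(st.integers(1, 10))
        n_rows = 4
        votes = [
            data.draw(st.lists(st.sampled_from([1, -1]), min_size=n_rows, max_size=n_rows))
            for _ in range(n_trees)
        ]
        weights = data.draw(
            st.lists(st.floats(0.05, 1.0), min_size=n_trees, max_size=n_trees)
        )
        f = _stub_forest(votes, weights)
        labels, scores = predict_weighted(f, np.zeros((n_rows, 3)))
        for r in range(n_rows):
            expected_score = sum(w * votes[t][r] for t, w in enumerate(weights))
            assert scores[r] == pytest.approx(expected_score)
            if expected_score != 0:
                assert labels[r] == (1 if expected_score > 0 else -1)


class TestEvaluate:
    def test_perfect_forest(self, separable_dataset):
        cfg = EvolutionConfig(n_trees=3, seed=0)
        trees = [fit_tree(separable_dataset, np.array([0, 1]), seed=s) for s in range(3)]
        f = WeightedForest(trees, np.ones(3), cfg, separable_dataset.n_features)
        m = evaluate(f, separable_dataset)
        assert m["accuracy"] == m["f1"] == m["auc"] == 1.0

    def test_constant_predictor_on_balanced_test(self):
        test = FusedDataset(np.zeros((8, 3)), [1] * 4 + [-1] * 4,
                            np.arange(8).astype(str), np.ones(8))
        f = _stub_forest([[1] * 8], [1.0])
        assert evaluate(f, test)["accuracy"] == 0.5

    def test_matches_confusion_matrix_hand_computation(self):
        test = FusedDataset(np.zeros((6, 3)), [1, 1, 1, -1, -1, -1],
                            np.arange(6).astype(str), np.ones(6))
        f = _stub_forest([[1, 1, -1, -1, -1, 1]], [1.0])
        m = evaluate(f, test)
        # TP=2 FN=1 TN=2 FP=1 for each class by symmetry.
        assert m["accuracy"] == pytest.approx(4 / 6)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_empty_test_rejected(self, separable_dataset):
        f = _stub_forest([[1]], [1.0])
        empty = separable_dataset.take(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            evaluate(f, empty)


class TestModelAPI:
    def test_fit_is_bit_reproducible(self, fused_pair):
        cfg = EvolutionConfig(n_trees=10, generations=2, seed=11)
        r1 = GeneticWeightedForest(fused_pair, cfg).fit()
        r2 = GeneticWeightedForest(fused_pair, cfg).fit()
        assert np.array_equal(r1.weights, r2.weights)
        assert np.array_equal(r1.predict(fused_pair.features),
                              r2.predict(fused_pair.features))
        for t1, t2 in zip(r1.forest.trees, r2.forest.trees):
            assert np.array_equal(t1.feature_subset, t2.feature_subset)

    def test_ablation_lattice_shares_trees_under_shared_seed(self, fused_pair):
        """Flags off reproduce plain / weighted / evolution-only variants."""
        results = {}
        for use_w, use_e in itertools.product([False, True], repeat=2):
            cfg = EvolutionConfig(n_trees=8, generations=2, seed=21,
                                  use_weights=use_w, use_evolution=use_e)
            results[(use_w, use_e)] = GeneticWeightedForest(fused_pair, cfg).fit()
        for use_e in (False, True):
            plain = results[(False, use_e)]
            weighted = results[(True, use_e)]
            # Same trees bit-for-bit; only the vote weights differ.
            for t1, t2 in zip(plain.forest.trees, weighted.forest.trees):
                assert np.array_equal(t1.feature_subset, t2.feature_subset)
            assert np.array_equal(plain.weights, np.ones(8))
            recomputed = [tree_accuracy(t, weighted.split.valid)
                          for t in weighted.forest.trees]
            assert np.array_equal(weighted.weights, recomputed)
        # Evolution changes the trees; no-evolution variants keep the
        # initial forest.
        sub_evo = [tuple(t.feature_subset) for t in results[(True, True)].forest.trees]
        sub_plain = [tuple(t.feature_subset) for t in results[(True, False)].forest.trees]
        assert sub_evo != sub_plain

    def test_from_dataframe_round_trip(self, fused_pair):
        df = fused_pair.to_frame()
        model = GeneticWeightedForest.from_dataframe(df, n_trees=5, generations=0, seed=2)
        res = model.fit()
        assert res.evaluate()["accuracy"] >= 0.5

    def test_summary_mentions_key_quantities(self, fitted_results):
        text = fitted_results.summary()
        assert "accuracy" in text and "trees" in text and "12" in text

    def test_serialization_round_trip_predictions(self, fitted_results, fused_pair):
        payload = forest_to_dict(fitted_results.forest)
        rebuilt = forest_from_dict(payload)
        l1, s1 = predict_weighted(fitted_results.forest, fused_pair.features)
        l2, s2 = predict_weighted(rebuilt, fused_pair.features)
        assert np.array_equal(l1, l2)
        np.testing.assert_allclose(s1, s2, atol=1e-9)
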