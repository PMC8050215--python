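"""Selection-engine unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import gazedecode as gd


class TestMakeFolds:
    def test_exact_stratification_when_divisible(self):
        y = np.array([0, 1] * 40)
        plan = gd.make_folds(y, n_folds=8, seed=0)
        for f in range(8):
            hold = y[plan.assignment == f]
            assert (hold == 0).sum() == 5 and (hold == 1).sum() == 5

    def test_fold_sizes_differ_by_at_most_one_per_class(self, rng):
        y = (rng.random(83) < 0.4).astype(int)
        plan = gd.make_folds(y, n_folds=8, seed=1)
        for cls in (0, 1):
            counts = [((plan.assignment == f) & (y == cls)).sum() for f in range(8)]
            assert max(counts) - min(counts) <= 1

    def test_temporal_interleaving(self):
        """Every consecutive block of 8 same-class trials covers all folds."""
        y = np.zeros(32, dtype=int); y[:16] = 1
        plan = gd.make_folds(y, n_folds=8, seed=2)
        idx = np.flatnonzero(y == 1)
        assert set(plan.assignment[idx[:8]]) == set(range(8))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gd.make_folds(np.ones(40), n_folds=8)

    def test_small_class_rejected(self):
        y = np.r_[np.zeros(40), np.ones(5)]
        with pytest.raises(ValueError):
            gd.make_folds(y, n_folds=8)


class TestBalancedSplit:
    def test_balanced_pool_splits_in_half(self):
        y = np.array([0] * 40 + [1] * 40)
        tr, va = gd.balanced_split(y, seed=0)
        assert len(tr) == 40 and len(va) == 40
        assert (y[tr] == 0).sum() == 20 and (y[tr] == 1).sum() == 20

    def test_minority_capping(self):
        y = np.array([0] * 40 + [1] * 10)
        tr, va = gd.balanced_split(y, seed=0)
        assert (y[tr] == 0).sum() == (y[tr] == 1).sum() == 10
        assert len(va) == 30

    def test_class_exhaustion_rejected(self):
        with pytest.raises(ValueError):
            gd.balanced_split(np.array([0, 0, 0, 0]), seed=0)

    def test_train_and_validation_disjoint_cover(self):
        y = np.array([0, 1] * 13)
        tr, va = gd.balanced_split(y, seed=3)
        assert len(np.intersect1d(tr, va)) == 0
        assert len(tr) + len(va) == len(y)


class TestKruskalWallis:
    def test_worked_example(self):
        """Two groups {1..4} vs {5..8}: H = 12/(N(N+1))·Σnᵢ(R̄ᵢ−(N+1)/2)² = 16/3."""
        X = np.array([[1], [2], [3], [4], [5], [6], [7], [8]], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rk = gd.rank_features_kw(X, y)
        assert rk.scores[0] == pytest.approx(16 / 3, abs=1e-12)

    def test_constant_feature_scores_zero(self, rng):
        X = np.c_[np.full(20, 3.0), rng.standard_normal(20)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        assert gd.rank_features_kw(X, y).scores[0] == 0.0

    def test_invariant_to_within_class_permutation(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        s1 = gd.rank_features_kw(X, y).scores
        perm = np.r_[rng.permutation(15), 15 + rng.permutation(15)]
        s2 = gd.rank_features_kw(X[perm], y[perm]).scores
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        X = rng.integers(0, 4, size=(24, 6)).astype(float)  # heavy ties
        y = np.r_[np.zeros(12), np.ones(12)].astype(int)
        ours = gd.rank_features_kw(X, y).scores
        for j in range(6):
            expected = stats.kruskal(X[y == 0, j], X[y == 1, j]).statistic
            assert ours[j] == pytest.approx(expected, abs=1e-9)

    def test_multigroup_matches_scipy(self, rng):
        X = rng.standard_normal((30, 5))
        y = np.repeat([0, 1, 2], 10)
        ours = gd.rank_features_kw(X, y).scores
        for j in range(5):
            expected = stats.kruskal(*(X[y == g, j] for g in range(3))).statistic
            assert ours[j] == pytest.approx(expected, abs=1e-9)

    def test_tie_broken_by_lower_index(self):
        X = np.c_[[1, 2, 5, 6], [1, 2, 5, 6]].astype(float)
        y = np.array([0, 0, 1, 1])
        rk = gd.rank_features_kw(X, y)
        assert rk.order[0] == 0 and rk.order[1] == 1

    def test_degenerate_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            gd.rank_features_kw(rng.standard_normal((10, 2)), np.zeros(10))


class TestSelectionBudget:
    @pytest.mark.parametrize("scores,expected_M", [
        ([10, 5, 3, 2], 1),          # top score alone holds >= 10% of 20
        ([1.0] * 100, 10),           # uniform mass -> 10% of the features
        ([7, 0, 0, 0], 1),           # one feature holds all mass
    ])
    def test_examples(self, scores, expected_M):
        assert gd.selection_budget(np.array(scores, float)).M == expected_M

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gd.selection_budget(np.zeros(5))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=2,
                    max_size=40).filter(lambda s: sum(s) > 0))
    def test_minimality_property(self, scores):
        """Top-M mass >= 10% of total, and M−1 top features fall short."""
        scores = np.asarray(scores, dtype=float)
        M = gd.selection_budget(scores).M
        top = np.sort(scores)[::-1]
        assert top[:M].sum() >= 0.10 * scores.sum() - 1e-9
        if M > 1:
            assert top[:M - 1].sum() < 0.10 * scores.sum() + 1e-9

    def test_max_budget_cap(self):
        assert gd.selection_budget(np.ones(100), max_budget=4).M == 4


def _planted_problem(rng, n=120, p=30, strong=(0,), noise=1e-3):
    """Binary problem with perfectly separating feature(s) `strong`."""
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    X = rng.standard_normal((n, p))
    for f in strong:
        X[:, f] = y * 2.0 - 1.0 + noise * rng.standard_normal(n)
    return X, y


class TestWrapper:
    def test_dominant_feature_included_first(self, rng):
        X, y = _planted_problem(rng, strong=(4,))
        ranking = gd.rank_features_kw(X, y)
        budget = gd.SelectionBudget(M=3)
        sel = gd.wrapper_selection(X, y, budget, ranking, seed=0)
        assert sel[0] == 4 and len(sel) == 3

    def test_pruning_removes_redundant_duplicate(self, rng):
        """A duplicated perfectly separating column adds nothing, so the
        checkpoint drops one copy (F1 unchanged without it)."""
        X, y = _planted_problem(rng, strong=(4,))
        X[:, 7] = X[:, 4]  # exact duplicate
        ranking = gd.rank_features_kw(X, y)
        budget = gd.SelectionBudget(M=8)
        sel = gd.wrapper_selection(X, y, budget, ranking, seed=1)
        assert not ({4, 7} <= set(sel))
        assert len(set(sel) & {4, 7}) == 1

    def test_returns_budget_size_on_noise(self, rng):
        X = rng.standard_normal((80, 20))
        y = np.r_[np.zeros(40), np.ones(40)].astype(int)
        ranking = gd.rank_features_kw(X, y)
        sel = gd.wrapper_selection(X, y, gd.SelectionBudget(M=5), ranking, seed=2)
        assert len(sel) == 5 and len(set(sel)) == 5

    def test_deterministic_given_seed(self, rng):
        X, y = _planted_problem(rng, strong=(0, 9))
        ranking = gd.rank_features_kw(X, y)
        a = gd.wrapper_selection(X, y, gd.SelectionBudget(M=4), ranking, seed=7)
        b = gd.wrapper_selection(X, y, gd.SelectionBudget(M=4), ranking, seed=7)
        np.testing.assert_array_equal(a, b)


class TestAssembleCandidates:
    def _setup(self, rng):
        X, y = _planted_problem(rng, n=160, p=40, strong=(3,))
        pool, hold = np.arange(120), np.arange(120, 160)
        ranking = gd.rank_features_kw(X[pool], y[pool])
        budget = gd.selection_budget(ranking.scores)
        cs = gd.assemble_candidates(X[pool], y[pool], X[hold], y[hold],
                                    budget, ranking, seed=0)
        return cs, ranking, budget

    def test_all_sets_have_budget_size(self, rng):
        cs, _, budget = self._setup(rng)
        for kind in ("filter", "wrapper", "random", "pseudo_random"):
            assert len(cs.sets[kind]) == budget.M

    def test_filter_is_top_ranked(self, rng):
        cs, ranking, budget = self._setup(rng)
        np.testing.assert_array_equal(cs.sets["filter"],
                                      ranking.order[:budget.M])

    def test_pseudo_random_disjoint_from_filter_and_wrapper(self, rng):
        cs, _, _ = self._setup(rng)
        used = set(cs.sets["filter"]) | set(cs.sets["wrapper"])
        assert not (set(cs.sets["pseudo_random"]) & used)

    def test_final_is_argmax(self, rng):
        cs, _, _ = self._setup(rng)
        assert cs.final_accuracy == max(cs.accuracies.values())

    def test_budget_mass_invariant(self, rng):
        """Filter set holds >=10% of the chi-squared mass; dropping its
        lowest-ranked member breaks that (minimality)."""
        cs, ranking, budget = self._setup(rng)
        total = ranking.scores.sum()
        filt = cs.sets["filter"]
        assert ranking.scores[filt].sum() >= 0.10 * total - 1e-9
        if budget.M > 1:
            assert ranking.scores[filt[:-1]].sum() < 0.10 * total


class TestRunParticipant:
    def test_all_zero_diffs_give_chance_accuracy(self, rng):
        X = np.zeros((160, 12))
        y = (rng.random(160) < 0.5).astype(int)
        res = gd.run_participant(X, y, config=gd.SelectionConfig(
            subsample_size=4), seed=0)
        assert abs(res.mean_fs_accuracy - 0.5) < 0.15
        assert abs(res.mean_full_accuracy - 0.5) < 0.15

    def test_end_to_end_determinism(self, small_experiment, fast_config):
        r1 = gd.run_participant(small_experiment.diffs, small_experiment.labels,
                                config=fast_config, seed=5)
        r2 = gd.run_participant(small_experiment.diffs, small_experiment.labels,
                                config=fast_config, seed=5)
        assert r1.mean_fs_accuracy == r2.mean_fs_accuracy
        for a, b in zip(r1.fold_results, r2.fold_results):
            assert a.final_kind == b.final_kind
            np.testing.assert_array_equal(a.final, b.final)

    def test_planted_signal_beats_chance(self, small_experiment, fast_config):
        """With a strong planted readout the selected model must decode far
        above the empirical chance of the same pipeline."""
        exp = small_experiment
        res = gd.run_participant(exp.diffs, exp.labels, config=fast_config, seed=5)
        ch = gd.empirical_chance(exp.diffs, exp.labels, config=fast_config,
                                 seed=5, foldplan=res.foldplan)
        assert res.mean_fs_accuracy > ch.mean + 0.05
        # one-sided binomial: pooled correct count vs chance mean
        n = len(exp.labels)
        correct = int(round(res.mean_fs_accuracy * n))
        p = stats.binomtest(correct, n, ch.mean, alternative="greater").pvalue
        assert p < 0.01

    def test_predictions_cover_every_trial_once(self, small_experiment, fast_config):
        res = gd.run_participant(small_experiment.diffs, small_experiment.labels,
                                 config=fast_config, seed=5)
        assert sorted(res.predictions.trial) == list(range(len(small_experiment.labels)))


def test_result_save_roundtrip(tmp_path, small_experiment, fast_config):
    import json
    res = gd.run_participant(small_experiment.diffs, small_experiment.labels,
                             config=fast_config, seed=5)
    res.save(tmp_path)
    d = json.loads((tmp_path / "decoding_result.json").read_text())
    assert d["n_features"] == 384 and len(d["folds"]) == 8
    assert d["folds"][0]["final_kind"] in ("filter", "wrapper", "random",
                                           "pseudo_random")
    import pandas as pd
    preds = pd.read_csv(tmp_path / "predictions.csv")
    assert len(preds) == len(small_experiment.labels)
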