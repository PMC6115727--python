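import numpy as np
import pytest

import subtypeflow as sf
from subtypeflow.defs_w import _decode


def planted_trio(seed, n=100, noise=50, shift=2.0):
    rng = np.random.default_rng(1000 + seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.standard_normal((n, noise + 3))
    informative = (noise, noise + 1, noise + 2)
    for f in informative:
        X[y == 1, f] += shift
    return X, y, set(informative)


class TestEvaluateSubset:
    def test_perfectly_separating_feature_scores_one(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]] * 5)
        y = np.array([0, 0, 1, 1] * 5)
        assert sf.evaluate_subset([0], X, y, folds=2, seed=0) == 1.0

    def test_pure_noise_sits_at_chance(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 3))
            y = np.array([0, 1] * 100)
            vals.append(sf.evaluate_subset([0, 1, 2], X, y, folds=5, seed=seed))
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_duplicated_feature_copy_keeps_confusion_identical(self):
        # balanced classes: doubling a feature's log-likelihood cannot
        # change the argmax when priors are equal
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20)
        y = np.array([0, 1] * 10)
        x[y == 1] += 1.0
        X = np.column_stack([x, x])
        a = sf.evaluate_subset([0], X, y, folds=5, seed=3)
        b = sf.evaluate_subset([0, 1], X, y, folds=5, seed=3)
        assert a == b

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            sf.evaluate_subset([], np.zeros((4, 1)), np.array([0, 0, 1, 1]))

    def test_folds_reduced_for_small_classes(self, caplog):
        X = np.zeros((6, 1))
        y = np.array([0, 0, 0, 1, 1, 1])
        # class size 3 < 5 folds: reduced, not an error
        val = sf.evaluate_subset([0], X, y, folds=5, seed=0)
        assert 0.0 <= val <= 1.0


class TestDecode:
    def test_floor_null_token_and_determinism(self):
        rel = np.ones(10)
        x = np.array([0.3, 0.9, 5.2, 10.7])   # 10 features: value >= 10 is null
        a = _decode(x, 10, rel, base_seed=1)
        b = _decode(x, 10, rel, base_seed=1)
        assert a == b                      # pure function of (x, seed)
        assert {0, 5} <= set(a)            # floored indices kept
        assert len(a) == 3                 # null dropped, duplicate repaired

    def test_duplicates_replaced_with_unused_features(self):
        rel = np.ones(6)
        x = np.array([1.1, 1.2, 1.3])
        out = _decode(x, 6, rel, base_seed=0)
        assert len(out) == 3 and len(set(out)) == 3 and 1 in out


class TestSelect:
    def test_recovers_planted_informative_features(self):
        X, y, informative = planted_trio(0)
        res = sf.defs_w_select(X, y, upper_limit=10, de=sf.DEParams(seed=0))
        assert informative <= set(res.selected)
        assert res.size <= 10

    def test_upper_limit_one_equals_exhaustive_search(self):
        X, y, _ = planted_trio(1)
        de = sf.DEParams(seed=2, n_generations=20)
        res = sf.defs_w_select(X, y, upper_limit=1, de=de)
        scores = [sf.evaluate_subset([f], X, y, folds=de.eval_cv_folds,
                                     seed=de.seed, repeats=de.eval_cv_repeats)
                  for f in range(X.shape[1])]
        best = max(range(X.shape[1]), key=lambda f: (scores[f], -f))
        assert res.selected == [best]
        assert res.wacc == pytest.approx(max(scores))

    def test_identical_copies_score_like_a_single_feature(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        y = np.array([0, 1] * 20)
        x[y == 1] += 1.5
        X = np.tile(x[:, None], (1, 8))
        de = sf.DEParams(seed=1, n_generations=10, population_size=10)
        res = sf.defs_w_select(X, y, upper_limit=4, de=de)
        single = sf.evaluate_subset([0], X, y, folds=de.eval_cv_folds,
                                    seed=de.seed, repeats=de.eval_cv_repeats)
        assert res.wacc == pytest.approx(single)

    def test_history_is_monotone_and_determinism_holds(self):
        X, y, _ = planted_trio(2)
        de = sf.DEParams(seed=5, n_generations=15, population_size=12)
        a = sf.defs_w_select(X, y, upper_limit=5, de=de)
        b = sf.defs_w_select(X, y, upper_limit=5, de=de)
        assert a.selected == b.selected and a.wacc == b.wacc
        assert np.all(np.diff(a.history) >= 0)

    def test_invalid_limits_rejected(self):
        X, y, _ = planted_trio(3)
        with pytest.raises(ValueError):
            sf.defs_w_select(X, y, upper_limit=0)
        with pytest.raises(ValueError):
            sf.defs_w_select(X, y, upper_limit=X.shape[1] + 1)


class TestSweep:
    def test_single_limit_equals_direct_selection(self):
        X, y, _ = planted_trio(4)
        de = sf.DEParams(seed=3, n_generations=10, population_size=10)
        direct = sf.defs_w_select(X, y, upper_limit=5, de=de)
        swept = sf.sweep_upper_limits(X, y, [5], de=de)
        assert swept.selected == direct.selected
        assert swept.wacc == direct.wacc

    def test_per_limit_table_has_one_row_per_limit(self):
        X, y, _ = planted_trio(5)
        de = sf.DEParams(seed=4, n_generations=8, population_size=8)
        res = sf.sweep_upper_limits(X, y, [6, 4, 2], de=de)
        assert list(res.per_limit["upper_limit"]) == [6, 4, 2]
        assert res.per_limit.shape == (3, 3)
        assert res.size <= 6

    def test_empty_limit_list_rejected(self):
        X, y, _ = planted_trio(6)
        with pytest.raises(ValueError):
            sf.sweep_upper_limits(X, y, [])
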