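"""Nested leave-one-mouse-out CV: splits, scaling, consensus, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beamwalk import (
    CVConfig,
    DesignError,
    ExperimentDataset,
    consensus_rank,
    inner_select_and_tune,
    lomo_splits,
    make_feature_experiment,
    mode_hyperparams,
    run_nested_lomo,
    transfer_predict,
    wilcoxon_vs_chance,
    zscore_fit_apply,
)
from conftest import FAST_CV


def small_dataset(effect=3.0, n_mice=4, n_features=24, n_informative=5, seed=0):
    return make_feature_experiment(
        n_mice_per_group=n_mice, n_features=n_features,
        n_informative=n_informative, effect_size=effect, seed=seed,
    )


class TestSplits:
    def test_one_split_per_mouse_partition(self):
        ds, _ = small_dataset()
        splits = lomo_splits(ds)
        assert len(splits) == 8
        seen = []
        for train, test in splits:
            assert set(ds.mouse_ids[train]) & set(ds.mouse_ids[test]) == set()
            seen.extend(test.tolist())
        assert sorted(seen) == list(range(len(ds.X)))

    def test_too_few_mice(self):
        ds, _ = small_dataset()
        keep = np.isin(ds.mouse_ids, np.unique(ds.mouse_ids)[:2])
        tiny = ExperimentDataset(
            X=ds.X[keep].reset_index(drop=True), y=ds.y[keep],
            mouse_ids=ds.mouse_ids[keep],
        )
        with pytest.raises(DesignError):
            lomo_splits(tiny)

    def test_single_label_per_mouse_enforced(self):
        X = pd.DataFrame(np.zeros((4, 3)), columns=list("abc"))
        with pytest.raises(DesignError, match="labels"):
            ExperimentDataset(X=X, y=np.array(["A", "B", "A", "A"]),
                              mouse_ids=np.array(["m1", "m1", "m2", "m2"]))


class TestZscore:
    def test_hand_computed_n_minus_one(self):
        train = np.array([[1.0], [3.0]])
        (z,) = zscore_fit_apply(train)
        np.testing.assert_allclose(z[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_column_maps_to_zero(self):
        train = np.array([[5.0, 1.0], [5.0, 3.0]])
        test = np.array([[9.0, 2.0]])
        z_train, z_test = zscore_fit_apply(train, test)
        assert (z_train[:, 0] == 0).all() and z_test[0, 0] == 0.0

    def test_test_row_at_train_mean(self):
        train = np.array([[1.0, 10.0], [3.0, 30.0]])
        _, z = zscore_fit_apply(train, np.array([[2.0, 20.0]]))
        np.testing.assert_allclose(z, 0.0)

    def test_skip_mask_passes_through(self):
        train = np.array([[0.0, 1.0], [1.0, 3.0]])
        skip = np.array([True, False])
        z_train, = zscore_fit_apply(train, skip=skip)
        np.testing.assert_array_equal(z_train[:, 0], train[:, 0])


class TestConsensus:
    def test_identical_lists(self):
        lists = [[f"f{i}" for i in range(60)]] * 4
        assert consensus_rank(lists, 50) == lists[0][:50]

    def test_rank_one_everywhere_is_first(self):
        lists = [["top", "a", "b"], ["top", "b", "c"], ["top", "c", "a"]]
        assert consensus_rank(lists, 2)[0] == "top"

    def test_occurrence_dominates_rank(self):
        # f_a: 3/4 lists at rank 2; f_b: 4/4 lists at rank 40
        lists = []
        for i in range(4):
            lst = [f"x{i}_{r}" for r in range(50)]
            lst[39] = "f_b"
            if i < 3:
                lst[1] = "f_a"
            lists.append(lst)
        out = consensus_rank(lists, 50)
        assert out.index("f_b") < out.index("f_a")

    def test_name_breaks_full_ties(self):
        lists = [["b", "a"], ["a", "b"]]
        assert consensus_rank(lists, 2) == ["a", "b"]


class TestModeHyperparams:
    GRID = {"max_depth": [4, 8, None]}

    def test_identical_sets(self):
        final, tie = mode_hyperparams([{"max_depth": 8}] * 3, self.GRID)
        assert final == {"max_depth": 8} and not tie

    def test_majority(self):
        sets = [{"max_depth": 4}, {"max_depth": 4}, {"max_depth": 8}]
        final, tie = mode_hyperparams(sets, self.GRID)
        assert final == {"max_depth": 4} and not tie

    def test_tie_breaks_to_declared_order(self):
        sets = [{"max_depth": 8}, {"max_depth": 4}]
        final, tie = mode_hyperparams(sets, self.GRID)
        assert final == {"max_depth": 4} and tie

    def test_inconsistent_keys(self):
        with pytest.raises(ValueError):
            mode_hyperparams([{"a": 1}, {"b": 2}], {})


class TestNestedCV:
    def test_determinism(self):
        ds, _ = small_dataset()
        cfg = CVConfig(n_select=8, seed=7, **FAST_CV)
        r1 = run_nested_lomo(ds, cfg)
        r2 = run_nested_lomo(ds, cfg)
        assert r1.accuracies == r2.accuracies
        assert r1.consensus_features == r2.consensus_features
        assert r1.final_hyperparams == r2.final_hyperparams

    def test_accuracy_support(self):
        ds, _ = small_dataset(effect=0.5, seed=3)
        cfg = CVConfig(n_select=8, seed=1, **FAST_CV)
        res = run_nested_lomo(ds, cfg)
        assert set(res.accuracies.values()) <= {0.0, 0.5, 1.0}
        assert len(res.accuracies) == 8
        assert len(res.consensus_features) == 8

    def test_planted_signal_dominates_inner_lists(self):
        # every planted feature recurs across the inner lists and the
        # consensus recovers the full set (redundant planted features can
        # drop from a single forest's splits, but not from the aggregate)
        ds, informative = small_dataset(effect=4.0, n_mice=4, seed=5)
        cfg = CVConfig(n_select=12, rfe_step=0.5, seed=2,
                       hyper_grid={"n_estimators": [25]},
                       rfe_params={"n_estimators": 25})
        ranked_lists, _ = inner_select_and_tune(ds, np.arange(len(ds.X)), cfg)
        assert len(ranked_lists) == 8
        for feat in informative:
            occurrence = sum(feat in lst for lst in ranked_lists)
            assert occurrence >= len(ranked_lists) // 2, feat
        assert set(informative) <= set(consensus_rank(ranked_lists, 12))

    def test_strong_effect_classifies_well(self):
        ds, _ = small_dataset(effect=4.0, n_mice=6, seed=4)
        cfg = CVConfig(n_select=8, seed=0, **FAST_CV)
        res = run_nested_lomo(ds, cfg)
        assert res.mean_accuracy >= 0.9

    def test_no_leakage_from_held_out_mouse(self):
        """Perturbing a held-out mouse's rows must not change the features
        or hyperparameters selected for its own outer split."""
        ds, _ = small_dataset(effect=1.0, n_mice=4, seed=6)
        cfg = CVConfig(n_select=8, seed=9, **FAST_CV)
        res0 = run_nested_lomo(ds, cfg)
        target = res0.splits[2].mouse
        X2 = ds.X.copy()
        X2.loc[np.flatnonzero(ds.mouse_ids == target)] += 250.0
        ds2 = ExperimentDataset(X=X2, y=ds.y, mouse_ids=ds.mouse_ids)
        res1 = run_nested_lomo(ds2, cfg)
        s0 = res0.splits[2]
        s1 = res1.splits[2]
        assert s0.mouse == s1.mouse == target
        assert s0.consensus_features == s1.consensus_features
        assert s0.hyperparams == s1.hyperparams

    def test_n_select_must_be_below_feature_count(self):
        ds, _ = small_dataset(n_features=8)
        cfg = CVConfig(n_select=8, seed=0, **FAST_CV)
        with pytest.raises(DesignError):
            run_nested_lomo(ds, cfg)


class TestWilcoxon:
    def test_all_perfect_accuracies(self):
        W, p, flag = wilcoxon_vs_chance([1.0] * 16)
        assert W == 136.0  # 16 * 17 / 2
        assert p == pytest.approx(2 / 2**16)
        assert p < 0.001 and not flag

    def test_all_at_chance_degenerate(self):
        W, p, flag = wilcoxon_vs_chance([0.5] * 8)
        assert (W, p, flag) == (0.0, 1.0, True)

    def test_symmetric_accuracies_not_significant(self):
        acc = [0.0] * 5 + [1.0] * 5
        _, p, _ = wilcoxon_vs_chance(acc)
        assert p > 0.5

    def test_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(12)
        acc = 0.5 + rng.normal(0.08, 0.21, size=12)
        acc = acc[acc != 0.5]
        W, p, _ = wilcoxon_vs_chance(acc)
        ref = stats.wilcoxon(acc - 0.5, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_few_animals(self):
        with pytest.raises(DesignError):
            wilcoxon_vs_chance([1.0] * 5)


class TestTransfer:
    def test_planted_effect_transfers(self):
        cfg = CVConfig(n_select=12, rfe_step=0.5, seed=0,
                       hyper_grid={"n_estimators": [25]},
                       rfe_params={"n_estimators": 25})
        a, _ = make_feature_experiment(n_mice_per_group=5, n_features=24,
                                       n_informative=5, effect_size=4.0, seed=21)
        b, _ = make_feature_experiment(n_mice_per_group=5, n_features=24,
                                       n_informative=5, effect_size=4.0, seed=22)
        acc, consensus, params = transfer_predict(a, b, cfg)
        assert len(acc) == 10
        assert np.mean(list(acc.values())) >= 0.8
        assert len(consensus) == 12

    def test_manifest_mismatch(self):
        cfg = CVConfig(n_select=4, seed=0, **FAST_CV)
        a, _ = small_dataset()
        b, _ = make_feature_experiment(n_features=10, n_informative=2, seed=1)
        with pytest.raises(DesignError):
            transfer_predict(a, b, cfg)
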