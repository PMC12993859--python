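"""Tank-permutation cross-validation, pseudolabels, feature selection, RF-AE."""

import numpy as np
import pandas as pd
import pytest

from nutrimon.rf import (
    FeatureSelectionConfig,
    RFConfig,
    TankPermutationForest,
    assign_pseudolabels,
    enumerate_folds,
    estimate_trajectories,
    select_features,
)


def roster_3x3():
    return pd.DataFrame([
        {"tank_id": f"{t}-K{k}", "treatment": t}
        for t in ("T1", "T2", "T3") for k in (1, 2, 3)
    ])


class TestFoldEnumeration:
    def test_27_distinct_folds(self):
        folds = enumerate_folds(roster_3x3())
        assert len(folds) == 27
        assert len({f.test_tanks for f in folds}) == 27

    def test_each_tank_tests_in_18_folds(self):
        folds = enumerate_folds(roster_3x3())
        for tank in roster_3x3()["tank_id"]:
            n_test = sum(tank in f.test_tanks for f in folds)
            n_train = sum(tank in f.train_tanks for f in folds)
            assert (n_test, n_train) == (18, 9)

    def test_each_pair_occurs_in_9_folds(self):
        folds = enumerate_folds(roster_3x3())
        pair = ("T1-K1", "T1-K2")
        count = sum(set(pair) <= set(f.test_tanks) for f in folds)
        assert count == 9

    def test_brute_force_structure(self):
        """Every fold takes exactly 2 test + 1 train tank per treatment."""
        for f in enumerate_folds(roster_3x3()):
            for t in ("T1", "T2", "T3"):
                assert sum(tk.startswith(t) for tk in f.test_tanks) == 2
                assert sum(tk.startswith(t) for tk in f.train_tanks) == 1
            assert not set(f.test_tanks) & set(f.train_tanks)

    def test_incomplete_roster_rejected(self):
        with pytest.raises(ValueError, match="3 treatments x 3 tanks"):
            enumerate_folds(roster_3x3().iloc[:-1])


def tiny_records(days, tank="T1-K1"):
    return pd.DataFrame([
        {"plant_id": f"p{d}", "tank_id": tank, "treatment": "T1", "DAT": d, "f1": 0.1}
        for d in days
    ])


class TestPseudolabels:
    def gt(self, fws, dat=14, tank="T1-K1"):
        return pd.DataFrame([
            {"plant_id": f"g{i}", "tank_id": tank, "treatment": "T1", "DAT": dat,
             "FW_g": fw, "DM_g": fw * 0.05, "N_pct": 5.0, "P_pct": 0.6,
             "K_pct": 7.0, "Ca_pct": 1.2, "Mg_pct": 0.35, "S_pct": 0.25}
            for i, fw in enumerate(fws)
        ])

    def test_sampling_day_gets_five_sample_mean(self):
        labeled = assign_pseudolabels(tiny_records([14]), self.gt([10, 12, 14, 16, 18]))
        assert labeled["label_FW"].iloc[0] == pytest.approx(14.0)
        assert labeled["is_sampling_day"].iloc[0]

    def test_single_ground_truth_row_is_its_own_label(self):
        labeled = assign_pseudolabels(tiny_records([14]), self.gt([42.0]))
        assert labeled["label_FW"].iloc[0] == pytest.approx(42.0)

    def test_nearest_day_earlier_wins_ties(self):
        gt = pd.concat([self.gt([10.0], dat=11), self.gt([20.0], dat=15)])
        labeled = assign_pseudolabels(tiny_records([12, 13]), gt)
        # DAT 12 -> 11 (nearest); DAT 13 -> tie between 11 and 15 -> earlier
        assert labeled.set_index("DAT")["label_day"].to_dict() == {12: 11, 13: 11}
        assert (labeled["label_FW"] == 10.0).all()

    def test_tank_without_ground_truth_excluded_with_warning(self):
        records = pd.concat([tiny_records([14]), tiny_records([14], tank="T1-K2")])
        with pytest.warns(UserWarning, match="T1-K2"):
            labeled = assign_pseudolabels(records, self.gt([5.0]))
        assert set(labeled["tank_id"]) == {"T1-K1"}

    def test_no_ground_truth_at_all_raises(self):
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            assign_pseudolabels(tiny_records([14], tank="T9-K9"), self.gt([5.0]))


class TestFeatureSelection:
    def build_table(self, rng, n=200):
        y = rng.uniform(0, 1, n)
        table = pd.DataFrame({
            "plant_id": [f"p{i}" for i in range(n)],
            "tank_id": rng.choice([f"{t}-K{k}" for t in ("T1", "T2", "T3")
                                   for k in (1, 2, 3)], n),
            "treatment": "T1", "DAT": 10,
            "label_FW": y,
        })
        table["exact"] = y  # noise-free copy of the target
        for i in range(20):
            table[f"noise{i}"] = rng.normal(size=n)
        table["dup_of_exact"] = y  # |r| = 1 with 'exact'
        table["constant"] = 1.0
        return table

    def test_perfect_feature_ranked_first_and_constant_dropped(self, rng):
        table = self.build_table(rng).drop(columns=["dup_of_exact"])
        feats = [c for c in table.columns if c not in
                 ("plant_id", "tank_id", "treatment", "DAT", "label_FW")]
        folds = enumerate_folds(roster_3x3())[:3]
        cfg = FeatureSelectionConfig(rfe_floor=15, top_k=10, n_estimators=30)
        selected = select_features(table, "FW", feats, folds, cfg)
        assert selected[0] == "exact"  # noise-free predictor leads the ranking
        assert "constant" not in selected  # zero importance
        assert len(selected) == 10

    def test_exact_duplicate_features_are_correlation_pruned(self, rng):
        table = self.build_table(rng)
        feats = [c for c in table.columns if c not in
                 ("plant_id", "tank_id", "treatment", "DAT", "label_FW")]
        folds = enumerate_folds(roster_3x3())[:3]
        cfg = FeatureSelectionConfig(rfe_floor=15, top_k=10, n_estimators=30)
        selected = select_features(table, "FW", feats, folds, cfg)
        # |r| = 1 pair: at most one twin can survive the pruning stages
        assert len({"exact", "dup_of_exact"} & set(selected)) <= 1
        assert len(selected) == 10

    def test_fewer_survivors_than_requested_warns(self, rng):
        table = self.build_table(rng)
        folds = enumerate_folds(roster_3x3())[:1]
        cfg = FeatureSelectionConfig(rfe_floor=3, top_k=20, n_estimators=20)
        with pytest.warns(UserWarning, match="survived"):
            selected = select_features(table, "FW", ["exact", "noise0", "noise1",
                                                     "dup_of_exact"], folds, cfg)
        assert len(selected) < 20


@pytest.fixture(scope="module")
def forest(feature_tables, small_experiment, small_rf_config):
    single, _ = feature_tables
    _, gt = small_experiment
    return TankPermutationForest(single, gt, small_rf_config)


@pytest.fixture(scope="module")
def results(forest):
    return forest.cross_validate(rvs=["FW"])


class TestCrossValidation:
    def test_no_train_test_plant_overlap_in_any_fold(self, forest):
        for fold in forest.folds:
            trainval, test = forest.fold_split(fold, "FW")
            assert not set(trainval["plant_id"]) & set(test["plant_id"])

    def test_strong_signal_recovers_fresh_weight(self, results):
        assert (results.per_fold["r2"] >= 0.9).all()

    def test_metrics_recomputable_from_per_fold_values(self, results):
        m = results.metrics().loc["FW"]
        per = results.per_fold[results.per_fold["rv"] == "FW"]
        assert m["r2_mean"] == pytest.approx(per["r2"].mean())
        assert m["rmse_sd"] == pytest.approx(per["rmse"].std(ddof=1))

    def test_oof_predictions_cover_labeled_test_records(self, results, small_experiment):
        _, gt = small_experiment
        oof = results.oof_predictions
        # every labeled (plant, DAT) appears once per fold in which its tank tests
        assert set(zip(oof["plant_id"], oof["DAT"])) <= set(zip(gt["plant_id"], gt["DAT"]))
        assert oof.groupby(["plant_id", "DAT"]).size().max() == 18

    def test_shuffled_labels_destroy_signal(self, feature_tables, small_experiment,
                                            small_rf_config):
        single, _ = feature_tables
        _, gt = small_experiment
        shuffled = gt.copy()
        rng = np.random.default_rng(0)
        cols = ["FW_g", "DM_g", "N_pct", "P_pct", "K_pct", "Ca_pct", "Mg_pct", "S_pct"]
        shuffled[cols] = shuffled[cols].to_numpy()[rng.permutation(len(shuffled))]
        forest = TankPermutationForest(single, shuffled, small_rf_config)
        res = forest.cross_validate(rvs=["FW"], folds=forest.folds[:6])
        assert res.per_fold["r2"].mean() <= 0.1

    def test_summary_mentions_folds_and_rvs(self, results):
        text = results.summary()
        assert "27" in text and "FW" in text


class TestEstimatedTrajectories:
    def test_constant_features_give_constant_trajectory(self, feature_tables,
                                                        small_experiment, small_rf_config):
        single, daily = feature_tables
        _, gt = small_experiment
        forest = TankPermutationForest(single, gt, small_rf_config)
        frozen = daily.copy()
        feat_cols = forest.feature_columns
        frozen[feat_cols] = frozen[feat_cols].iloc[0].to_numpy()  # same input every row
        est = estimate_trajectories(forest, frozen, rvs=["FW"])
        for pid in list(est.series)[:3]:
            vals = est.series[pid]["FW"].to_numpy()
            np.testing.assert_allclose(vals, vals[0])

    def test_truncated_plant_gives_truncated_trajectory(self, feature_tables,
                                                        small_experiment, small_rf_config):
        single, daily = feature_tables
        _, gt = small_experiment
        forest = TankPermutationForest(single, gt, small_rf_config)
        est = estimate_trajectories(forest, daily, rvs=["FW"])
        early = gt[gt["DAT"] == 11]["plant_id"].iloc[0]
        assert est.series[early].index.max() == 11


def test_default_config_uses_tuned_hyperparameters():
    est = RFConfig().estimator("P")
    assert est.n_estimators == 1300 and est.max_depth == 12
    assert est.bootstrap is False and est.max_features == "sqrt"
    est = RFConfig(n_estimators=50).estimator("FW")
    assert est.n_estimators == 50 and est.max_depth == 14
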